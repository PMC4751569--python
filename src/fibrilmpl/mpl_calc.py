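"""Mass-per-unit-length computation and aggregation.

A calibration is built by pooling the background-corrected slice sums of all
standard selections; each fibril slice is then converted to kDa/nm as

    mpl = (I - (B_left + B_right)/2) * K / C_std

where ``C_std`` is the mean corrected standard slice sum and ``K`` the known
mass per unit length of the standard (default 131 kDa/nm for TMV).  The
ratio cancels both intensity units and the nm-per-px factor, so no pixel
size is required.  Negative per-slice values on noisy data are retained:
clipping them would bias the mean upward.

Two levels of summary statistics are emitted side by side — pooled over all
slices (the headline number) and over per-fibril means — because published
"mean ± x (n fibrils, m measurements)" summaries are ambiguous between the
two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .band_sampler import LineProfile, SliceMeasurement
from .errors import AnalysisError, CalibrationError

#: Literature mass per unit length of the TMV calibration rod, kDa/nm.
DEFAULT_K = 131.0


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


@dataclass(frozen=True)
class StandardCalibration:
    """Averaged corrected intensity of the in-image standard, plus its K."""

    K: float
    C_std: float
    n_std_lines: int
    n_std_slices: int
    sd_std: float


@dataclass
class MplMeasurement:
    """Per-slice MPL values and summary statistics for one fibril selection."""

    label: str
    slice_mpls: List[float]
    mean_mpl: float
    sd_mpl: float
    sem_mpl: float
    n_slices: int


@dataclass
class MplSummary:
    """Pooled (all-slice) and fibril-level statistics for a measurement run."""

    per_fibril: List[MplMeasurement]
    pooled_mean: float
    pooled_sd: float
    fibril_mean: float
    fibril_sd: float
    fibril_sem: float
    n_fibrils: int
    n_measurements: int


@dataclass
class FluctuationReport:
    """Spread of consecutive-slice differences, background vs fibril.

    ``sd_bg_diff`` is the SD of B(s) - B(s+1) over consecutive retained
    slices (B = mean of the two flanking band sums); ``sd_fibril_diff`` is
    the same statistic on background-corrected signal sums.  An excess of
    the fibril SD over the background SD signals real along-axis mass
    heterogeneity.  About-mean SDs of the undifferenced series are included
    as secondary columns.
    """

    sd_bg_diff: float
    sd_fibril_diff: float
    n_pairs_bg: int
    n_pairs_fibril: int
    sd_bg_about_mean: float
    sd_fibril_about_mean: float


def calibrate(
    standard_profiles: Sequence[LineProfile],
    K: float = DEFAULT_K,
    per_standard_mean: bool = False,
) -> StandardCalibration:
    """Pool corrected slice sums of all standard profiles into a calibration.

    By default every slice weighs equally, so longer standards contribute
    more; ``per_standard_mean=True`` averages per-standard means instead,
    giving each standard molecule equal weight.

    Raises
    ------
    CalibrationError
        If no slices are available, K <= 0, or the pooled corrected
        intensity is non-positive.
    """
    if K <= 0:
        raise CalibrationError(f"calibration constant K must be > 0, got {K}")
    per_profile = [p.corrected_intensities() for p in standard_profiles]
    if not per_profile or sum(arr.size for arr in per_profile) == 0:
        raise CalibrationError("no standard slices available for calibration")
    pooled = np.concatenate(per_profile)
    if per_standard_mean:
        c_std = float(np.mean([arr.mean() for arr in per_profile]))
    else:
        c_std = float(pooled.mean())
    if c_std <= 0:
        raise CalibrationError(
            "standard darker than background — check beam tilt/selections"
        )
    return StandardCalibration(
        K=float(K),
        C_std=c_std,
        n_std_lines=len(per_profile),
        n_std_slices=int(pooled.size),
        sd_std=_sd(pooled),
    )


def mpl_per_slice(slc: SliceMeasurement, cal: StandardCalibration) -> float:
    """Convert one slice to kDa/nm; negative outputs are legal on noise."""
    return slc.corrected * cal.K / cal.C_std


def measure_fibril(profile: LineProfile, cal: StandardCalibration) -> MplMeasurement:
    """Apply the MPL formula to every retained slice of one fibril selection."""
    mpls = np.array([mpl_per_slice(s, cal) for s in profile.slices])
    n = mpls.size
    sd = _sd(mpls)
    return MplMeasurement(
        label=profile.selection.label,
        slice_mpls=[float(v) for v in mpls],
        mean_mpl=float(mpls.mean()),
        sd_mpl=sd,
        sem_mpl=sd / math.sqrt(n) if n > 0 else 0.0,
        n_slices=int(n),
    )


def summarize(measurements: Sequence[MplMeasurement]) -> MplSummary:
    """Combine per-fibril measurements into pooled and fibril-level statistics."""
    if not measurements:
        raise AnalysisError("no fibril measurements to summarize")
    all_slices = np.concatenate([np.asarray(m.slice_mpls) for m in measurements])
    fibril_means = np.array([m.mean_mpl for m in measurements])
    n_fib = fibril_means.size
    fib_sd = _sd(fibril_means)
    return MplSummary(
        per_fibril=list(measurements),
        pooled_mean=float(all_slices.mean()),
        pooled_sd=_sd(all_slices),
        fibril_mean=float(fibril_means.mean()),
        fibril_sd=fib_sd,
        fibril_sem=fib_sd / math.sqrt(n_fib),
        n_fibrils=int(n_fib),
        n_measurements=int(all_slices.size),
    )


def _consecutive_diffs(profile: LineProfile) -> Tuple[np.ndarray, np.ndarray]:
    """Differences between slices whose indices are exactly 1 apart."""
    bg, fib = [], []
    for a, b in zip(profile.slices, profile.slices[1:]):
        if b.slice_index - a.slice_index != 1:
            continue  # a dropped slice breaks the pair chain
        bg.append(a.background - b.background)
        fib.append(a.corrected - b.corrected)
    return np.asarray(bg), np.asarray(fib)


def fluctuation_analysis(profiles: Sequence[LineProfile]) -> FluctuationReport:
    """SD of consecutive background and corrected-signal differences.

    Pairs are formed only between consecutive slice indices within one
    selection; dropped slices break the chain and selections are never
    paired with each other.

    Raises
    ------
    AnalysisError
        With fewer than 2 usable pairs.
    """
    bg_parts, fib_parts = [], []
    bg_series, fib_series = [], []
    for p in profiles:
        bg_d, fib_d = _consecutive_diffs(p)
        bg_parts.append(bg_d)
        fib_parts.append(fib_d)
        bg_series.append(np.array([s.background for s in p.slices]))
        fib_series.append(np.array([s.corrected for s in p.slices]))
    bg = np.concatenate(bg_parts) if bg_parts else np.empty(0)
    fib = np.concatenate(fib_parts) if fib_parts else np.empty(0)
    if bg.size < 2:
        raise AnalysisError(
            f"fluctuation analysis needs >= 2 consecutive-slice pairs, got {bg.size}"
        )
    return FluctuationReport(
        sd_bg_diff=_sd(bg),
        sd_fibril_diff=_sd(fib),
        n_pairs_bg=int(bg.size),
        n_pairs_fibril=int(fib.size),
        sd_bg_about_mean=_sd(np.concatenate(bg_series)),
        sd_fibril_about_mean=_sd(np.concatenate(fib_series)),
    )


def mpl_histogram(
    values: Sequence[float], bin_width: float = 5.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of slice MPLs with edges aligned to multiples of bin_width.

    Returns (edges, counts) with ``len(edges) == len(counts) + 1``.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(values, dtype=np.float64)
    lo = math.floor(arr.min() / bin_width) * bin_width
    hi = math.ceil(arr.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    counts, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    return edges, counts


def write_histogram_tsv(values: Sequence[float], path, bin_width: float = 5.0) -> None:
    edges, counts = mpl_histogram(values, bin_width)
    rows = ["\t".join(["bin_left", "bin_right", "count"])]
    for left, right, count in zip(edges[:-1], edges[1:], counts):
        rows.append(f"{left:g}\t{right:g}\t{int(count)}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_summary_tsv(
    summary: MplSummary,
    cal: StandardCalibration,
    path,
    fluct: Optional[FluctuationReport] = None,
) -> None:
    """Per-fibril table plus a commented footer with pooled statistics.

    All three candidate "±" statistics are emitted under explicit names
    (pooled SD, fibril-mean SD, fibril-mean SEM) rather than a single
    ambiguous value.
    """
    rows = ["\t".join(["label", "n_slices", "mean_mpl", "sd_mpl", "sem_mpl"])]
    for m in summary.per_fibril:
        rows.append(
            f"{m.label}\t{m.n_slices}\t{m.mean_mpl!r}\t{m.sd_mpl!r}\t{m.sem_mpl!r}"
        )
    rows += [
        f"# pooled_mean_mpl\t{summary.pooled_mean!r}",
        f"# pooled_sd_mpl\t{summary.pooled_sd!r}",
        f"# fibril_mean_mpl\t{summary.fibril_mean!r}",
        f"# fibril_sd_mpl\t{summary.fibril_sd!r}",
        f"# fibril_sem_mpl\t{summary.fibril_sem!r}",
        f"# n_fibrils\t{summary.n_fibrils}",
        f"# n_measurements\t{summary.n_measurements}",
        f"# K_kda_per_nm\t{cal.K!r}",
        f"# C_std\t{cal.C_std!r}",
        f"# n_std_lines\t{cal.n_std_lines}",
        f"# n_std_slices\t{cal.n_std_slices}",
        f"# sd_std\t{cal.sd_std!r}",
    ]
    if fluct is not None:
        rows += [
            f"# sd_bg_diff\t{fluct.sd_bg_diff!r}",
            f"# sd_fibril_diff\t{fluct.sd_fibril_diff!r}",
            f"# n_pairs_bg\t{fluct.n_pairs_bg}",
            f"# n_pairs_fibril\t{fluct.n_pairs_fibril}",
            f"# sd_bg_about_mean\t{fluct.sd_bg_about_mean!r}",
            f"# sd_fibril_about_mean\t{fluct.sd_fibril_about_mean!r}",
        ]
    Path(path).write_text("\n".join(rows) + "\n")


def write_fluctuation_tsv(fluct: FluctuationReport, path) -> None:
    rows = [
        "\t".join(
            [
                "sd_bg_diff",
                "sd_fibril_diff",
                "n_pairs_bg",
                "n_pairs_fibril",
                "sd_bg_about_mean",
                "sd_fibril_about_mean",
            ]
        ),
        "\t".join(
            [
                repr(fluct.sd_bg_diff),
                repr(fluct.sd_fibril_diff),
                str(fluct.n_pairs_bg),
                str(fluct.n_pairs_fibril),
                repr(fluct.sd_bg_about_mean),
                repr(fluct.sd_fibril_about_mean),
            ]
        ),
    ]
    Path(path).write_text("\n".join(rows) + "\n")
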