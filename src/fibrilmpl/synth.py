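"""Synthetic validation phantoms.

The default phantom mirrors the published validation image: three vertical
bars of true width 25 px on a black background — one at intensity 131
standing in for the calibration standard, plus test bars at 100 and 200 —
with i.i.d. Gaussian noise of SD 25 added in floating point.  Noise is NOT
clipped by default: clipping at zero truncates the noise floor and biases
background estimation; set ``clip_to_8bit`` to reproduce the bias of a real
8-bit export.

With zero noise and integer-aligned geometry the whole pipeline is exact, so
these phantoms double as analytic oracles for the measurement code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .band_sampler import DEFAULT_GAP, extract_profile, extract_profiles
from .errors import PhantomSpecError
from .image_io import Image
from .mpl_calc import DEFAULT_K, calibrate, measure_fibril
from .selections import SelectionLine, SelectionSet


@dataclass(frozen=True)
class BarSpec:
    """One vertical bar: center column, true width, value, label, kind."""

    center_x: float
    width: int
    intensity: float
    label: str
    kind: str


def default_bars() -> List[BarSpec]:
    return [
        BarSpec(100.0, 25, 131.0, "STD", "standard"),
        BarSpec(256.0, 25, 100.0, "A", "fibril"),
        BarSpec(412.0, 25, 200.0, "B", "fibril"),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a straight-bar phantom.

    ``selection_width`` is the measurement band width written into the
    generated selections (one full-height selection per bar, endpoints inset
    ``selection_inset`` px from the top and bottom edges).
    """

    image_size: Tuple[int, int] = (512, 512)  # (height, width)
    bars: Tuple[BarSpec, ...] = field(default_factory=lambda: tuple(default_bars()))
    background_level: float = 0.0
    noise_sd: float = 25.0
    seed: int = 0
    clip_to_8bit: bool = False
    selection_width: float = 30.0
    selection_inset: float = 5.0
    margin_gap: float = DEFAULT_GAP


def _validate_spec(spec: PhantomSpec) -> None:
    if spec.noise_sd < 0:
        raise PhantomSpecError(f"noise_sd must be >= 0, got {spec.noise_sd}")
    for bar in spec.bars:
        if bar.width < 1:
            raise PhantomSpecError(f"bar {bar.label!r}: width must be >= 1")
    # background bands of one bar must never touch another bar
    margin = 2.0 * (spec.selection_width + spec.margin_gap)
    ordered = sorted(spec.bars, key=lambda b: b.center_x)
    for a, b in zip(ordered, ordered[1:]):
        min_sep = a.width / 2.0 + b.width / 2.0 + margin
        if b.center_x - a.center_x < min_sep:
            raise PhantomSpecError(
                f"bars {a.label!r} and {b.label!r} overlap within the "
                f"background-band margin (need {min_sep:g} px separation)"
            )


def _bar_columns(center_x: float, width: int) -> Tuple[int, int]:
    """Integer column range [start, stop) of a bar, centered for odd widths."""
    start = int(round(center_x - (width - 1) / 2.0))
    return start, start + width


def _paint_bar(pixels: np.ndarray, bar: BarSpec) -> None:
    start, stop = _bar_columns(bar.center_x, bar.width)
    start = max(start, 0)
    stop = min(stop, pixels.shape[1])
    if stop <= start:
        raise PhantomSpecError(f"bar {bar.label!r} lies outside the image")
    pixels[:, start:stop] += bar.intensity


def generate_phantom(spec: PhantomSpec) -> Tuple[Image, SelectionSet]:
    """Render a straight-bar phantom and its matching selection set.

    Bars are exact integer-width vertical stripes on a uniform background;
    seeded Gaussian noise is added in float64, so a fixed seed gives a
    bit-identical image.  Values are clipped to [0, 255] only when
    ``clip_to_8bit`` is set.
    """
    _validate_spec(spec)
    height, width = spec.image_size
    pixels = np.full((height, width), spec.background_level, dtype=np.float64)
    for bar in spec.bars:
        _paint_bar(pixels, bar)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pixels += rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    if spec.clip_to_8bit:
        pixels = np.clip(pixels, 0.0, 255.0)
    img = Image(pixels=pixels, source_bit_depth="float")

    y0 = spec.selection_inset
    y1 = height - 1 - spec.selection_inset
    lines = [
        SelectionLine(bar.kind, bar.label, bar.center_x, y0, bar.center_x, y1,
                      spec.selection_width)
        for bar in spec.bars
    ]
    return img, SelectionSet(lines=lines)


@dataclass(frozen=True)
class SweepPoint:
    width: float
    mean_mpl: float
    sem: float
    n_slices: int


def width_sweep(
    spec: PhantomSpec,
    target_label: str,
    widths: Sequence[float],
    replicates: int = 1,
    center_offset: float = 0.0,
    gap: float = DEFAULT_GAP,
    K: float = DEFAULT_K,
) -> List[SweepPoint]:
    """Re-measure one phantom bar with a range of band widths.

    For each replicate the phantom is regenerated with seed
    ``spec.seed + replicate`` and the target bar is measured at every width
    (the standard keeps ``spec.selection_width``); ``center_offset`` shifts
    the target selection laterally to probe centering robustness.

    Returns one row per width: mean MPL, its SEM (across replicates when
    ``replicates > 1``, else the within-run SEM), and the total slice count.
    """
    if not widths:
        raise ValueError("widths must be non-empty")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    targets = [b for b in spec.bars if b.label == target_label]
    if not targets:
        raise ValueError(f"no bar labelled {target_label!r} in the phantom spec")
    target = targets[0]

    per_width_means: dict = {w: [] for w in widths}
    per_width_sems: dict = {w: [] for w in widths}
    per_width_n: dict = {w: 0 for w in widths}
    for rep in range(replicates):
        rep_spec = replace(spec, seed=spec.seed + rep)
        img, sels = generate_phantom(rep_spec)
        cal = calibrate(
            extract_profiles(img, sels.standards, gap=gap), K=K
        )
        y0 = rep_spec.selection_inset
        y1 = rep_spec.image_size[0] - 1 - rep_spec.selection_inset
        cx = target.center_x + center_offset
        for w in widths:
            sel = SelectionLine("fibril", target.label, cx, y0, cx, y1, w)
            m = measure_fibril(extract_profile(img, sel, gap=gap), cal)
            per_width_means[w].append(m.mean_mpl)
            per_width_sems[w].append(m.sem_mpl)
            per_width_n[w] += m.n_slices

    points = []
    for w in widths:
        means = np.asarray(per_width_means[w])
        if replicates > 1:
            sem = float(np.std(means, ddof=1) / math.sqrt(replicates))
        else:
            sem = float(per_width_sems[w][0])
        points.append(
            SweepPoint(width=float(w), mean_mpl=float(means.mean()), sem=sem,
                       n_slices=per_width_n[w])
        )
    return points


def write_sweep_tsv(points: Sequence[SweepPoint], path) -> None:
    from pathlib import Path

    rows = ["\t".join(["width", "mean_mpl", "sem", "n"])]
    for p in points:
        rows.append(f"{p.width:g}\t{p.mean_mpl!r}\t{p.sem!r}\t{p.n_slices}")
    Path(path).write_text("\n".join(rows) + "\n")


def generate_curved_phantom(
    amplitude: float,
    period: float,
    image_size: Tuple[int, int] = (512, 512),
    center_x: float = 300.0,
    true_width: int = 25,
    intensity: float = 100.0,
    std_center_x: float = 100.0,
    std_width: int = 25,
    std_intensity: float = 131.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    segment_step: float = 16.0,
    selection_width: float = 30.0,
    inset: float = 5.0,
    fibril_label: str = "F",
) -> Tuple[Image, SelectionSet]:
    """Render a sinusoidal-axis ribbon plus a straight calibration bar.

    The ribbon's axis is ``x(y) = center_x + amplitude * sin(2*pi*y/period)``;
    each row is drawn with exact fractional pixel coverage and its value is
    scaled by ``sec(theta)`` of the local axis slope so the *perpendicular*
    integrated cross-section stays constant at ``true_width * intensity``.
    Selections follow the axis as chained straight segments sharing the
    fibril label with suffixed segment ids, spaced ``segment_step`` px in y.

    With ``amplitude == 0`` the output is identical to a straight-bar
    phantom drawn the same way.

    Raises
    ------
    PhantomSpecError
        If the ribbon plus its background bands would leave the image.
    """
    if period <= 0:
        raise PhantomSpecError(f"period must be > 0, got {period}")
    height, width = image_size
    reach = amplitude + true_width / 2.0 + 1.5 * selection_width + DEFAULT_GAP
    if center_x - reach < 0 or center_x + reach > width - 1:
        raise PhantomSpecError(
            "curved ribbon background bands would leave the image; "
            "reduce amplitude or widths"
        )

    pixels = np.zeros((height, width), dtype=np.float64)
    ys = np.arange(height, dtype=np.float64)
    centers = center_x + amplitude * np.sin(2.0 * np.pi * ys / period)
    slopes = amplitude * (2.0 * np.pi / period) * np.cos(2.0 * np.pi * ys / period)
    sec = np.sqrt(1.0 + slopes**2)  # 1/cos(theta) of the local axis
    half = true_width / 2.0
    cols = np.arange(width, dtype=np.float64)
    # fractional coverage of pixel [c-0.5, c+0.5] by the band [center-half, center+half]
    left = np.maximum(cols[None, :] - 0.5, (centers - half)[:, None])
    right = np.minimum(cols[None, :] + 0.5, (centers + half)[:, None])
    coverage = np.clip(right - left, 0.0, 1.0)
    pixels += coverage * (intensity * sec)[:, None]

    _paint_bar(pixels, BarSpec(std_center_x, std_width, std_intensity, "STD", "standard"))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels += rng.normal(0.0, noise_sd, size=pixels.shape)
    img = Image(pixels=pixels, source_bit_depth="float")

    y_lo, y_hi = inset, height - 1 - inset
    lines = [
        SelectionLine("standard", "STD", std_center_x, y_lo, std_center_x, y_hi,
                      selection_width)
    ]
    knots = [float(k) for k in np.arange(y_lo, y_hi, segment_step)]
    if y_hi - knots[-1] < 2.0:
        knots[-1] = float(y_hi)  # avoid a degenerate (<2 px) trailing segment
    else:
        knots.append(float(y_hi))
    axis_x = lambda y: center_x + amplitude * math.sin(2.0 * math.pi * y / period)
    for i, (ya, yb) in enumerate(zip(knots, knots[1:])):
        lines.append(
            SelectionLine(
                "fibril", f"{fibril_label}_s{i}",
                axis_x(ya), float(ya), axis_x(yb), float(yb),
                selection_width,
            )
        )
    return img, SelectionSet(lines=lines)
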