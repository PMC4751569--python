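"""Independent oracles used by the test suite.

These are deliberately naive implementations (direct pixel sums, hand
bilinear formula, Monte-Carlo band simulation) kept separate from the
package code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_band_sums(pixels: np.ndarray, xc: int, y: int, w: int, gap: int):
    """Direct pixel sums for one slice of a vertical selection.

    Valid only for integer-aligned geometry (integer center column, integer
    row, odd integer width, integer gap), where bilinear sampling must hit
    pixel centers exactly.  Returns (I, B_left, B_right).
    """
    assert w % 2 == 1, "oracle requires odd width"
    hw = (w - 1) // 2
    shift = w + gap

    def band(center_col: int) -> float:
        return float(pixels[y, center_col - hw : center_col + hw + 1].sum())

    return band(xc), band(xc - shift), band(xc + shift)


def bilinear_by_hand(pixels: np.ndarray, x: float, y: float) -> float:
    """Textbook bilinear interpolation, written independently."""
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, pixels.shape[1] - 1), min(y0 + 1, pixels.shape[0] - 1)
    fx, fy = x - x0, y - y0
    top = pixels[y0, x0] * (1 - fx) + pixels[y0, x1] * fx
    bot = pixels[y1, x0] * (1 - fx) + pixels[y1, x1] * fx
    return float(top * (1 - fy) + bot * fy)


def mc_background_diff_sd(sigma: float, w: int, n_pairs: int, seed: int = 0) -> float:
    """Monte-Carlo SD of consecutive background differences.

    Simulates the band-mean convention directly: each slice's background is
    the mean of two sums of ``w`` i.i.d. N(0, sigma) samples; consecutive
    slices are independent (non-overlapping 1-px rows).
    """
    rng = np.random.default_rng(seed)

    def bg() -> np.ndarray:
        left = rng.normal(0.0, sigma, size=(n_pairs, w)).sum(axis=1)
        right = rng.normal(0.0, sigma, size=(n_pairs, w)).sum(axis=1)
        return 0.5 * (left + right)

    return float(np.std(bg() - bg(), ddof=1))
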