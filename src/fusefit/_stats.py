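"""Small statistical utilities shared across the pipeline stages."""

from __future__ import annotations

import math

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["round_half_away", "percent", "bh_fdr", "plus_one_pvalue"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` uses banker's rounding; reported percentages
    in the catalog summaries use the conventional half-away rule instead.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / scale


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage of ``numerator`` over ``denominator``, half-away rounded.

    With ``ndigits=0`` the result is an integer-valued float, e.g.
    ``percent(431, 7430) == 6.0``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def plus_one_pvalue(n_exceed: int, n_perm: int) -> float:
    """Empirical permutation p with plus-one smoothing: (1 + b) / (1 + R).

    Never returns 0; the smallest attainable value is 1 / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    return (1.0 + n_exceed) / (1.0 + n_perm)
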