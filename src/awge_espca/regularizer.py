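"""Adaptive noise-elimination regularizer (LAR).

Gene probes with excessive expression magnitude produce loading entries that
dwarf the signal; the LAR step treats the current loading vector as a sample,
computes Tukey-style quantile fences on it, and zeroes entries outside the
fences.  The quantile level ``lq`` in (0, 0.5) sets how deep into the sorted
vector the "quartiles" sit: Q1 is the ``round(m*lq)``-th smallest value and
Q3 the ``round(m*(1-lq))``-th, with half-up rounding.

Fences are computed on entry magnitudes by default (``mode="absolute"``):
outlyingness here means excessive expression scale, which is sign-blind.  The
literal signed variant (fences on the raw values, so both tails of the signed
distribution are trimmed) is available with ``mode="signed"``.

A caveat that matters in practice: the upper quantile rank must clear the
outlier block.  With ``m`` probes of which a fraction ``f`` are one-sided
outliers, ``round(m*(1-lq)) <= m*(1-f)`` is required for uncontaminated
fences; ``lq >= f`` guarantees it.  The package default ``lq = 0.30`` keeps
the fences robust up to a one-third outlier fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_LQ = 0.30


@dataclass(frozen=True)
class FenceParams:
    """Quantile fences for one loading vector."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    lq: float

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("IQR must be non-negative")
        if self.lower > self.upper:
            raise ValueError("lower fence exceeds upper fence")


def _check_lq(lq: float) -> None:
    if not 0.0 < lq < 0.5:
        raise ValueError(f"lq must lie in (0, 0.5), got {lq}")


def quartile_index(m: int, fraction: float) -> int:
    """1-based rank of the ``fraction`` quantile in a sorted length-``m`` vector.

    Half-up rounding of ``m * fraction`` (decimal part >= 0.5 rounds up),
    clamped to ``[1, m]``.
    """
    if m < 2:
        raise ValueError(f"need m >= 2, got {m}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    k = math.floor(m * fraction + 0.5)
    return min(max(k, 1), m)


def compute_fences(u: np.ndarray, lq: float = DEFAULT_LQ, mode: str = "absolute") -> FenceParams:
    """Tukey fences ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` of a loading vector.

    The vector is sorted internally (ascending); the result is invariant to
    the input order.  ``mode`` selects whether quantiles are taken over the
    magnitudes (default) or the signed values.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("u must be a 1-D vector with at least 2 entries")
    _check_lq(lq)
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    base = np.abs(u) if mode == "absolute" else u
    s = np.sort(base)
    m = len(s)
    q1 = float(s[quartile_index(m, lq) - 1])
    q3 = float(s[quartile_index(m, 1.0 - lq) - 1])
    iqr = q3 - q1
    return FenceParams(q1=q1, q3=q3, iqr=iqr, lower=q1 - 1.5 * iqr, upper=q3 + 1.5 * iqr, lq=lq)


def lar_regularize(
    u: np.ndarray, lq: float = DEFAULT_LQ, mode: str = "absolute"
) -> np.ndarray:
    """Zero the entries of ``u`` outside the Tukey fences.

    Entry ``i`` is kept unchanged iff its fence statistic (``|u_i|`` or
    ``u_i`` depending on ``mode``) lies inside ``[LB, UB]`` inclusive;
    otherwise it is set to 0.  The output is in the original probe order;
    the sort is internal to the fence computation only.
    """
    u = np.asarray(u, dtype=float)
    fences = compute_fences(u, lq, mode)
    base = np.abs(u) if mode == "absolute" else u
    out = np.where((base >= fences.lower) & (base <= fences.upper), u, 0.0)
    return out


def outlier_mask(u: np.ndarray, lq: float = DEFAULT_LQ, mode: str = "absolute") -> np.ndarray:
    """Boolean mask of entries the fences flag as outliers (True = outlier)."""
    u = np.asarray(u, dtype=float)
    fences = compute_fences(u, lq, mode)
    base = np.abs(u) if mode == "absolute" else u
    return (base < fences.lower) | (base > fences.upper)
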