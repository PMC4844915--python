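"""Surrogate-based significance for PAC comodulograms.

Null distributions come from the cut-swap family: the low-frequency phase
series is cut at a random point and the two segments exchanged, which
preserves the series' marginal dynamics while destroying its alignment
with the high-frequency envelope phase.  Per-cell one-sided empirical
p-values are corrected across the comodulogram's cells with the
Benjamini-Hochberg step-up rule, and the prominent mode of a window is
the strongest surviving cell.

Two p-value conventions are provided.  ``"proportion"`` is the plain
fraction of surrogates at or above the observed value; it can return 0
and is the convention under which the step-up rule retains detections at
realistic surrogate counts.  ``"add_one"`` (Davison-Hinkley) is strictly
positive and conservative; with m cells it can only reject when at least
``m / (q * (n_surrogates + 1))`` cells are simultaneously at the floor,
so at typical settings it bounds the false-positive rate at the price of
sensitivity.  See the methods note for the resolution arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .pac import Comodulogram
from .bands import Band

__all__ = [
    "SurrogateConfig", "cut_swap_surrogate", "empirical_pvalue", "bh_fdr",
    "SignificanceMask", "prominent_mode",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Settings for the surrogate test.

    n_surrogates : surrogate count (default 1000; at least 20 required).
    q : Benjamini-Hochberg false-discovery level (default 0.01).
    cut_margin : fraction of the series length excluded at both ends when
        drawing the cut point.
    p_convention : "proportion" (default, permits p = 0) or "add_one".
    """

    n_surrogates: int = 1000
    q: float = 0.01
    cut_margin: float = 0.1
    seed: int | None = None
    p_convention: str = "proportion"

    def __post_init__(self):
        if self.n_surrogates < 20:
            raise ValueError("n_surrogates must be at least 20")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if not 0 <= self.cut_margin < 0.5:
            raise ValueError("cut_margin must lie in [0, 0.5)")
        if self.p_convention not in ("proportion", "add_one"):
            raise ValueError("p_convention must be 'proportion' or 'add_one'")


def cut_swap_surrogate(phase_series: np.ndarray, rng: np.random.Generator,
                       margin: float = 0.1) -> np.ndarray:
    """Cut the series at one random interior point and exchange the parts.

    The output is a two-block rotation: same values, same length.  The cut
    index is uniform on ``[margin*T, (1-margin)*T]``.
    """
    x = np.asarray(phase_series)
    T = x.size
    if T < 10:
        raise ValueError("series too short for a cut-swap surrogate")
    lo = int(np.ceil(margin * T))
    hi = int(np.floor((1 - margin) * T))
    c = int(rng.integers(max(lo, 1), max(hi, lo + 1) + 1))
    return np.concatenate([x[c:], x[:c]])


def empirical_pvalue(observed: float, surrogate_values: np.ndarray,
                     convention: str = "add_one") -> float:
    """One-sided empirical p-value of the observed statistic.

    ``add_one``: (1 + #{s >= obs}) / (1 + n), strictly positive.
    ``proportion``: #{s >= obs} / n, the plain exceedance fraction.
    """
    s = np.asarray(surrogate_values, float)
    if s.size < 20:
        raise ValueError("need at least 20 surrogate values")
    k = int((s >= observed).sum())
    if convention == "add_one":
        return (1 + k) / (1 + s.size)
    if convention == "proportion":
        return k / s.size
    raise ValueError("convention must be 'add_one' or 'proportion'")


@dataclass
class SignificanceMask:
    """Boolean mask plus p-values aligned with a comodulogram's cells."""

    significant: np.ndarray
    p_values: np.ndarray


def bh_fdr(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over a family of p-values.

    NaN entries (ineligible cells) are never rejected.
    """
    p = np.asarray(p_values, float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    reject = np.zeros(flat.shape, bool)
    if ok.any():
        reject[ok] = multipletests(flat[ok], alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def prominent_mode(com: Comodulogram, mask: SignificanceMask
                   ) -> tuple[Band, int, float] | None:
    """The window's characteristic coupling mode.

    Exactly one significant cell -> that cell; several -> the one with the
    highest coupling value; none -> None (a strength of zero is recorded
    downstream).  Cells must also pass the power-separation mask.
    """
    if mask.significant.shape != com.values.shape:
        raise ValueError("mask shape does not match comodulogram")
    cand = np.where(mask.significant & com.power_ok & ~np.isnan(com.values),
                    com.values, -np.inf)
    if not np.isfinite(cand).any():
        return None
    r, c = np.unravel_index(np.argmax(cand), cand.shape)
    return com.grid.phase_bands[r], int(c + com.grid.amp_lo), float(com.values[r, c])
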