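"""Genome-scale multiplicity control for vectors of per-gene p-values.

Missing p-values (genes whose statistic could not be formed, e.g. ratio
statistics on genes with zero channels) are carried through as NaN: they are
excluded from the multiplicity count and are never significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

METHODS = ("none", "bonferroni", "bh")


@dataclass(frozen=True)
class AdjustedResults:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    method: str
    alpha: float
    threshold: float
    significant: np.ndarray = field(init=False)

    def __post_init__(self):
        # strict inequality: reproduces "p-values less than alpha" accounting
        with np.errstate(invalid="ignore"):
            sig = self.adjusted_p < self.alpha
        sig &= ~np.isnan(self.raw_p)
        object.__setattr__(self, "significant", sig)


def bonferroni_threshold(alpha: float, K: int) -> float:
    """Per-test cutoff alpha / K controlling the familywise error over K tests.

    E.g. a genomewide rate of 0.05 over 32,000 sequences gives 1.5625e-6 per
    gene; a raw p-value is significant iff strictly below the threshold.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if K < 1:
        raise ValueError("K must be at least 1")
    return alpha / K


def benjamini_hochberg(raw_p, alpha: float = 0.05) -> AdjustedResults:
    """Step-up FDR adjustment over the non-missing p-values.

    Returns adjusted p-values with monotonicity enforced; NaN entries pass
    through untouched and do not enter the multiplicity count m.
    """
    raw = np.asarray(raw_p, dtype=float)
    _check(raw)
    adjusted = np.full(raw.shape, np.nan)
    mask = ~np.isnan(raw)
    if mask.any():
        adjusted[mask] = multipletests(raw[mask], method="fdr_bh")[1]
    return AdjustedResults(raw, adjusted, "bh", alpha, threshold=alpha)


def bonferroni(raw_p, alpha: float = 0.05) -> AdjustedResults:
    """Bonferroni adjustment: p * m clipped at 1, m counting non-missing tests."""
    raw = np.asarray(raw_p, dtype=float)
    _check(raw)
    mask = ~np.isnan(raw)
    m = int(mask.sum())
    adjusted = np.full(raw.shape, np.nan)
    if m:
        adjusted[mask] = np.minimum(raw[mask] * m, 1.0)
    threshold = bonferroni_threshold(alpha, m) if m else alpha
    return AdjustedResults(raw, adjusted, "bonferroni", alpha, threshold=threshold)


def adjust_pvalues(raw_p, method: str = "none", alpha: float = 0.05) -> AdjustedResults:
    """Dispatch on adjustment method: none, bonferroni, or bh."""
    if method == "none":
        raw = np.asarray(raw_p, dtype=float)
        _check(raw)
        return AdjustedResults(raw, raw.copy(), "none", alpha, threshold=alpha)
    if method == "bonferroni":
        return bonferroni(raw_p, alpha)
    if method == "bh":
        return benjamini_hochberg(raw_p, alpha)
    raise ValueError(f"unknown adjustment method: {method!r} (expected one of {METHODS})")


def _check(raw: np.ndarray) -> None:
    finite = raw[~np.isnan(raw)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p-values must lie in [0, 1] or be NaN")
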