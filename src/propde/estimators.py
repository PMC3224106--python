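"""Per-gene point estimators for paired two-channel expression data.

A gene is observed as ``n`` paired measurements ``(G_i, R_i)`` of test-channel
and reference-channel signal (intensities or counts, both non-negative).  Two
summaries of relative expression are provided:

* the **proportion** ``p = G / (G + R)`` — the fraction of total signal
  attributable to the test sample, with null value 0.5;
* the classical **log2-ratio** ``log2(G / R)`` — with null value 0, optionally
  stabilised by a symmetric pseudocount shift.

Undefined-value semantics are explicit and deliberately asymmetric between the
two scales: a per-pair proportion is undefined only at 0/0, whereas a per-pair
unshifted log-ratio is undefined whenever either channel is zero.  Undefined
values are represented as NaN throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class MissingPolicy(enum.Enum):
    """How a gene-level summary treats undefined per-pair values.

    GENE_MISSING
        Any undefined pair makes the whole gene-level summary undefined.
        Default for ratio statistics: a gene with a zero channel yields no
        test and is counted as non-significant downstream.
    DROP_PAIRS
        Undefined pairs are dropped and the summary is formed from the
        remaining pairs.  Default for proportion statistics: a gene is
        untestable only if every pair is 0/0.
    """

    GENE_MISSING = "gene-missing"
    DROP_PAIRS = "drop-pairs"


@dataclass(frozen=True)
class GeneEstimates:
    """Per-gene point estimates and bookkeeping for one gene.

    ``s`` and ``n_used`` refer to the per-pair values of the *chosen* scale
    (proportions for the proportion t-test, log-ratios for the ratio t-test);
    ``shift`` records the pseudocount applied to ratios (0 means none).
    """

    p_bar: float
    p_hat: float
    r_hat: float
    s: float
    n_used: int
    Y_total: float
    M_total: float
    shift: float = 0.0


def _as_channels(g, r) -> tuple[np.ndarray, np.ndarray]:
    g = np.atleast_1d(np.asarray(g, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if g.shape != r.shape:
        raise ValueError(f"channel shapes differ: {g.shape} vs {r.shape}")
    if g.ndim != 1:
        raise ValueError("expected 1-D per-gene channel vectors")
    if g.size == 0:
        raise ValueError("need at least one pair")
    for name, x in (("g", g), ("r", r)):
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite value in channel {name!r}")
        if (x < 0).any():
            raise ValueError(f"negative value in channel {name!r}")
    return g, r


def pair_proportion(g: float, r: float) -> float:
    """Proportion ``g / (g + r)`` for a single pair; NaN at the 0/0 pair.

    Zeros in one channel are legitimate extremes: ``(5, 0) -> 1.0`` means all
    observed signal came from the test sample, ``(0, 7) -> 0.0`` the reverse.
    """
    if not (math.isfinite(g) and math.isfinite(r)):
        raise ValueError("non-finite input")
    if g < 0 or r < 0:
        raise ValueError("negative input")
    total = g + r
    return g / total if total > 0 else math.nan


def pair_proportions(g, r) -> np.ndarray:
    """Vector of per-pair proportions, NaN where both channels are zero."""
    g, r = _as_channels(g, r)
    total = g + r
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, g / np.where(total > 0, total, 1.0), np.nan)
    return p


def _aggregate(values: np.ndarray, policy: MissingPolicy) -> tuple[float, float, int]:
    defined = ~np.isnan(values)
    if policy is MissingPolicy.GENE_MISSING and not defined.all():
        return math.nan, math.nan, 0
    used = values[defined]
    n_used = used.size
    if n_used == 0:
        return math.nan, math.nan, 0
    center = float(used.mean())
    s = float(used.std(ddof=1)) if n_used >= 2 else math.nan
    return center, s, n_used


def mean_proportion(
    g, r, policy: MissingPolicy = MissingPolicy.DROP_PAIRS
) -> tuple[float, float, int]:
    """Average of per-pair proportions.

    Returns ``(p_bar, s, n_used)`` where ``s`` is the sample standard
    deviation (ddof=1) of the contributing proportions, NaN when fewer than
    two pairs contribute.  All-0/0 genes yield ``(nan, nan, 0)``, never an
    exception.
    """
    return _aggregate(pair_proportions(g, r), policy)


def pooled_proportion(g, r) -> tuple[float, float, float]:
    """Pooled (maximum-likelihood) proportion ``sum(g) / sum(g + r)``.

    Under the competitive-hybridization model the test-channel signal for a
    pair is Binomial(M, p) out of a pair total M = g + r; pooling totals over
    pairs gives the ML estimate of p.  Returns ``(p_hat, Y_total, M_total)``;
    ``p_hat`` is NaN when the summed signal ``M_total`` is zero.
    """
    g, r = _as_channels(g, r)
    y_total = float(g.sum())
    m_total = float(g.sum() + r.sum())
    p_hat = y_total / m_total if m_total > 0 else math.nan
    return p_hat, y_total, m_total


def log_ratios(g, r, shift: float = 0.0) -> np.ndarray:
    """Per-pair ``log2((g + shift) / (r + shift))``; NaN where either shifted
    channel is zero."""
    if shift < 0:
        raise ValueError("shift must be non-negative")
    g, r = _as_channels(g, r)
    gs, rs = g + shift, r + shift
    ok = (gs > 0) & (rs > 0)
    out = np.full(g.shape, np.nan)
    out[ok] = np.log2(gs[ok] / rs[ok])
    return out


def log_ratio(
    g, r, shift: float = 0.0, policy: MissingPolicy = MissingPolicy.GENE_MISSING
) -> tuple[float, float, int]:
    """Mean log2-ratio over pairs with optional pseudocount shift.

    Returns ``(r_hat, s, n_used)`` with the same aggregation semantics as
    :func:`mean_proportion`.  Under the default GENE_MISSING policy a single
    zero channel anywhere makes the gene's ratio statistic undefined — the
    missing-data disadvantage of ratio statistics that proportion statistics
    avoid.
    """
    return _aggregate(log_ratios(g, r, shift), policy)


def ratio_to_proportion(r):
    """Map a log2-ratio to the equivalent proportion: ``p = 2^r / (1 + 2^r)``.

    The two scales are linked by a logistic curve; r = 0 maps to p = 0.5,
    r = 1 (two-fold up) to p = 2/3, r = 2 (four-fold) to p = 0.8.
    """
    r = np.asarray(r, dtype=float)
    # 1 / (1 + 2^-r) avoids overflow for large positive r
    p = 1.0 / (1.0 + np.exp2(-r))
    return float(p) if p.ndim == 0 else p


def proportion_to_ratio(p):
    """Inverse logistic map ``r = log2(p / (1 - p))``, defined on 0 < p < 1.

    The boundary proportions 0 and 1 correspond to infinite fold change and
    are rejected as out of domain.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("proportion_to_ratio requires 0 < p < 1")
    r = np.log2(p / (1.0 - p))
    return float(r) if r.ndim == 0 else r


def gene_estimates(
    g,
    r,
    *,
    shift: float = 0.0,
    spread_scale: str = "proportion",
    policy: MissingPolicy | None = None,
) -> GeneEstimates:
    """All point estimates for one gene.

    ``spread_scale`` selects which per-pair values ``s``/``n_used`` describe:
    ``"proportion"`` (policy default DROP_PAIRS) or ``"ratio"`` (policy
    default GENE_MISSING).
    """
    if spread_scale == "proportion":
        center, s, n_used = mean_proportion(g, r, policy or MissingPolicy.DROP_PAIRS)
        p_bar = center
        r_hat, _, _ = log_ratio(g, r, shift, policy or MissingPolicy.GENE_MISSING)
    elif spread_scale == "ratio":
        r_hat, s, n_used = log_ratio(g, r, shift, policy or MissingPolicy.GENE_MISSING)
        p_bar, _, _ = mean_proportion(g, r, MissingPolicy.DROP_PAIRS)
    else:
        raise ValueError(f"unknown spread_scale: {spread_scale!r}")
    p_hat, y_total, m_total = pooled_proportion(g, r)
    return GeneEstimates(
        p_bar=p_bar,
        p_hat=p_hat,
        r_hat=r_hat,
        s=s,
        n_used=n_used,
        Y_total=y_total,
        M_total=m_total,
        shift=shift,
    )
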