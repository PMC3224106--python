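"""Monte-Carlo engine comparing proportion and log-ratio test statistics.

Four data-generating families emulate the main expression platforms:

* ``exponential`` — two-colour cDNA intensities; reference Exp(rate 1/4000),
  test c x Exp(rate 1/4000) where c is the fold change.
* ``poisson`` — sequencing-style counts; reference Poisson(lam), test
  c x Poisson(lam) (the fold change scales the draws, analogously to the
  exponential family, so the test mean is c*lam while zeros stay exactly as
  frequent as under the null).  Small rates (the default lam = 3) produce
  frequent zeros, the regime where ratio statistics lose genes.
* ``binomial`` — competitive hybridization with a fixed pair total M:
  G ~ Binomial(M, p_c) and R = M - G with p_c = c/(c+1), so fold changes
  2, 3, 4, 5 correspond to test probabilities 2/3, 3/4, 4/5, 5/6.
* ``normal`` — Gaussian intensities; reference Normal(mu, sigma), test
  Normal(c*mu, sigma), negatives redrawn (negligible at the mu = 5,
  sigma = 1 default).

The rejection engine draws one gene per replicate, applies every requested
test at the working level, and reports the fraction of replicates rejected.
A replicate whose statistic cannot be formed (an unshifted ratio hitting a
zero count, say) counts as a non-rejection in the denominator — the same
accounting used for genes "classified as missing" in real analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import MissingPolicy, log_ratio, mean_proportion, pooled_proportion
from .inference import binomial_z_test, proportion_t_test, ratio_t_test

FAMILIES = ("exponential", "poisson", "binomial", "normal")

DEFAULT_PARAMS = {
    "exponential": {"rate": 1.0 / 4000.0},
    "poisson": {"lam": 3.0},
    "binomial": {"size": 10000},
    "normal": {"mu": 5.0, "sigma": 1.0},
}

DEFAULT_METHODS = ("ratio", "ratio+0.05", "ratio+0.5", "zprop", "tprop")


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design."""

    family: str
    fold_change: float = 1.0
    n: int = 20
    reps: int = 1000
    alpha: float = 0.05
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r} (expected one of {FAMILIES})")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1 (use the reciprocal convention)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        merged = {**DEFAULT_PARAMS[self.family], **self.params}
        if any(v <= 0 for v in merged.values()):
            raise ValueError("family parameters must be strictly positive")
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class MethodRejection:
    """Per-method tally from a rejection study."""

    rejections: int
    missing: int
    reps: int

    @property
    def proportion(self) -> float:
        return self.rejections / self.reps

    @property
    def mc_se(self) -> float:
        p = self.proportion
        return math.sqrt(p * (1.0 - p) / self.reps)


@dataclass(frozen=True)
class RejectionSummary:
    scenario: SimulationScenario
    methods: dict  # method label -> MethodRejection

    def to_frame(self) -> pd.DataFrame:
        sc = self.scenario
        rows = [
            {
                "family": sc.family,
                "fc": sc.fold_change,
                "n": sc.n,
                "method": label,
                "rejections": mr.rejections,
                "reps": mr.reps,
                "proportion": mr.proportion,
                "mc_se": mr.mc_se,
                "missing": mr.missing,
            }
            for label, mr in self.methods.items()
        ]
        return pd.DataFrame(rows)


def fold_change_params(family: str, params: dict, c: float) -> tuple[dict, dict]:
    """Reference- and test-channel sampling parameters at fold change c.

    The fold change acts multiplicatively on the test channel's mean: the
    exponential scale is multiplied by c; Poisson draws are multiplied by c
    (``multiplier`` key — the test mean is c*lam but the zero probability is
    unchanged, unlike a Poisson(c*lam) draw); the normal mean becomes c*mu;
    and the coupled binomial maps c to success probability p_c = c/(c+1)
    (the reference takes the complement).
    """
    if c < 1:
        raise ValueError("fold change must be >= 1")
    params = {**DEFAULT_PARAMS.get(family, {}), **params}
    if family == "exponential":
        return {"rate": params["rate"]}, {"rate": params["rate"] / c}
    if family == "poisson":
        return {"lam": params["lam"]}, {"lam": params["lam"], "multiplier": c}
    if family == "normal":
        ref = {"mu": params["mu"], "sigma": params["sigma"]}
        return ref, {"mu": c * params["mu"], "sigma": params["sigma"]}
    if family == "binomial":
        p_c = c / (c + 1.0)
        return {"size": params["size"], "prob": 1.0 - p_c}, {"size": params["size"], "prob": p_c}
    raise ValueError(f"unknown family: {family!r}")


def _truncated_normal(rng, mu, sigma, shape):
    x = rng.normal(mu, sigma, shape)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = x < 0
    return x


def _sample_block(scenario: SimulationScenario, rng, reps: int):
    """Draw (g, r) arrays of shape (reps, n) for the scenario."""
    n, c = scenario.n, scenario.fold_change
    ref, test = fold_change_params(scenario.family, scenario.params, c)
    shape = (reps, n)
    if scenario.family == "exponential":
        r = rng.exponential(1.0 / ref["rate"], shape)
        g = rng.exponential(1.0 / test["rate"], shape)
    elif scenario.family == "poisson":
        r = rng.poisson(ref["lam"], shape).astype(float)
        g = test.get("multiplier", 1.0) * rng.poisson(test["lam"], shape).astype(float)
    elif scenario.family == "binomial":
        g = rng.binomial(int(test["size"]), test["prob"], shape).astype(float)
        r = float(test["size"]) - g  # competitive coupling: g + r = M exactly
    elif scenario.family == "normal":
        r = _truncated_normal(rng, ref["mu"], ref["sigma"], shape)
        g = _truncated_normal(rng, test["mu"], test["sigma"], shape)
    else:  # pragma: no cover - guarded by the scenario validator
        raise ValueError(scenario.family)
    return g, r


def sample_gene(scenario: SimulationScenario, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gene: paired (g, r) vectors of length scenario.n."""
    g, r = _sample_block(scenario, rng, 1)
    return g[0], r[0]


def parse_method(label: str) -> tuple[str, dict]:
    """Decode a method label into a test kind and its options.

    Labels: ``tprop``; ``zprop`` / ``zprop-plugin``; ``ratio`` (unshifted) or
    ``ratio+<const>`` for a symmetric pseudocount, e.g. ``ratio+0.5``.
    """
    if label == "tprop":
        return "tprop", {}
    if label in ("zprop", "zprop-null"):
        return "zprop", {"variance": "null"}
    if label == "zprop-plugin":
        return "zprop", {"variance": "plug_in"}
    if label == "ratio":
        return "ratio", {"shift": 0.0}
    if label.startswith("ratio+"):
        shift = float(label[len("ratio+"):])
        if shift < 0:
            raise ValueError("shift must be non-negative")
        return "ratio", {"shift": shift}
    raise ValueError(f"unknown method label: {label!r}")


def run_method(g, r, label: str, alpha: float, policy: MissingPolicy | None = None):
    """Apply one labelled test to one gene's paired data."""
    kind, opts = parse_method(label)
    if kind == "tprop":
        p_bar, s, n_used = mean_proportion(g, r, policy or MissingPolicy.DROP_PAIRS)
        return proportion_t_test(p_bar, s, n_used, alpha)
    if kind == "zprop":
        p_hat, _, m_total = pooled_proportion(g, r)
        return binomial_z_test(p_hat, m_total, opts["variance"], alpha)
    r_hat, s, n_used = log_ratio(g, r, opts["shift"], policy or MissingPolicy.GENE_MISSING)
    return ratio_t_test(r_hat, s, n_used, alpha)


def rejection_study(
    scenario: SimulationScenario,
    methods: Sequence[str] = DEFAULT_METHODS,
    policy: MissingPolicy | None = None,
) -> RejectionSummary:
    """Empirical rejection rate of each method under the scenario.

    All methods see the same simulated data within a replicate (paired
    comparison, reducing between-method Monte-Carlo noise).  Missing
    statistics count as non-rejections; at fold change 1 the proportion
    estimates the type-I error, otherwise the power.
    """
    if not methods:
        raise ValueError("need at least one method")
    rng = np.random.default_rng(scenario.seed)
    g_all, r_all = _sample_block(scenario, rng, scenario.reps)
    rejections = {m: 0 for m in methods}
    missing = {m: 0 for m in methods}
    for i in range(scenario.reps):
        g, r = g_all[i], r_all[i]
        for m in methods:
            out = run_method(g, r, m, scenario.alpha, policy)
            if out.missing:
                missing[m] += 1
            elif out.significant:
                rejections[m] += 1
    return RejectionSummary(
        scenario,
        {m: MethodRejection(rejections[m], missing[m], scenario.reps) for m in methods},
    )


def table1_grid(
    families: Iterable[str] = FAMILIES,
    fold_changes: Iterable[float] = (1.0, 3.0),
    ns: Iterable[int] = (20,),
    methods: Sequence[str] = DEFAULT_METHODS,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    params: dict | None = None,
    policy: MissingPolicy | None = MissingPolicy.GENE_MISSING,
) -> pd.DataFrame:
    """Full factorial rejection study over families x fold changes x n.

    Returns a long-format frame (family, fc, n, method, rejections, reps,
    proportion, mc_se, missing); each cell gets a seed derived
    deterministically from the base seed, so identical inputs give a
    byte-identical serialized report.

    The default GENE_MISSING policy classifies a simulated dataset containing
    any undefined pair as missing for every per-pair statistic, the
    accounting of the original benchmark; pass ``policy=None`` for the
    per-method defaults used on real data (proportion statistics then drop
    undefined pairs instead of losing the gene).
    """
    frames = []
    cell = 0
    for family in families:
        for c in fold_changes:
            for n in ns:
                scenario = SimulationScenario(
                    family=family,
                    fold_change=c,
                    n=n,
                    reps=reps,
                    alpha=alpha,
                    seed=_cell_seed(seed, cell),
                    params=(params or {}).get(family, {}) if params else {},
                )
                frames.append(rejection_study(scenario, methods, policy).to_frame())
                cell += 1
    return pd.concat(frames, ignore_index=True)


def _cell_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def write_report(report: pd.DataFrame, path) -> None:
    """Serialize a simulation report as TSV (deterministic formatting)."""
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def make_fixture(
    K: int,
    n: int,
    de_fraction: float = 0.1,
    family: str = "exponential",
    c_de: float = 3.0,
    zero_inflation: float = 0.0,
    seed: int = 0,
    params: dict | None = None,
):
    """Labelled synthetic expression matrix for end-to-end testing.

    A ``de_fraction`` of the K genes is sampled at fold change ``c_de``, the
    rest at fold change 1; ``zero_inflation`` then zeroes that fraction of
    individual cells uniformly at random (emulating dropouts / unexpressed
    probes).  Returns ``(model, labels)`` where ``model`` is a
    :class:`~propde.model.PairedExpression` and ``labels`` a boolean array
    marking the truly differentially expressed genes.
    """
    from .model import PairedExpression  # local import: avoid cycle

    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_de = int(round(K * de_fraction))
    labels = np.zeros(K, dtype=bool)
    labels[:n_de] = True
    G = np.empty((K, n))
    R = np.empty((K, n))
    for is_de, rows in ((True, np.flatnonzero(labels)), (False, np.flatnonzero(~labels))):
        if rows.size == 0:
            continue
        scenario = SimulationScenario(
            family=family,
            fold_change=c_de if is_de else 1.0,
            n=n,
            reps=1,
            seed=0,
            params=params or {},
        )
        g, r = _sample_block(scenario, rng, rows.size)
        G[rows] = g
        R[rows] = r
    if zero_inflation > 0:
        G[rng.random((K, n)) < zero_inflation] = 0.0
        R[rng.random((K, n)) < zero_inflation] = 0.0
    gene_ids = [f"gene{i + 1:05d}" for i in range(K)]
    return PairedExpression(R, G, gene_ids=gene_ids), labels
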