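"""Model/Results interface for paired differential-expression testing.

:class:`PairedExpression` wraps a K-gene x n-pair matrix of reference (R) and
test (G) channel values; :meth:`PairedExpression.fit` runs one of the
per-gene tests and returns a :class:`DEResults` carrying estimates, test
statistics, raw and multiplicity-adjusted p-values, and a ``summary()``
table.  :func:`two_group_fit` compares two such matrices (e.g. knockout vs
control arrays) gene-by-gene with Welch's t-test on per-array statistics.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as pio
from .estimators import (
    MissingPolicy,
    log_ratio,
    log_ratios,
    mean_proportion,
    pair_proportions,
    pooled_proportion,
)
from .inference import (
    TestOutcome,
    binomial_z_test,
    proportion_t_test,
    ratio_t_test,
    welch_two_group_test,
)
from .multitest import adjust_pvalues

_POLICY_ALIASES = {
    "gene-missing": MissingPolicy.GENE_MISSING,
    "drop-pairs": MissingPolicy.DROP_PAIRS,
}

METHODS = ("tprop", "zprop", "ratio")


class PairedExpression:
    """Paired two-channel expression data for K genes across n experiments.

    Parameters
    ----------
    R, G : array-like, shape (K, n)
        Reference- and test-channel summary expression values; non-negative,
        zeros allowed (they are data, not missing).
    gene_ids : sequence of str, optional
        Unique identifiers; defaults to ``gene00001``-style labels.
    """

    def __init__(self, R, G, gene_ids=None):
        R = np.atleast_2d(np.asarray(R, dtype=float))
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if R.shape != G.shape:
            raise ValueError(f"R and G shapes differ: {R.shape} vs {G.shape}")
        if R.ndim != 2 or R.shape[0] < 1 or R.shape[1] < 1:
            raise ValueError("expected K x n matrices with K >= 1, n >= 1")
        for name, x in (("R", R), ("G", G)):
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite value in {name}")
            if (x < 0).any():
                raise ValueError(f"negative value in {name}")
        K, n = R.shape
        if gene_ids is None:
            gene_ids = [f"gene{i + 1:05d}" for i in range(K)]
        gene_ids = [str(g) for g in gene_ids]
        if len(gene_ids) != K:
            raise ValueError("gene_ids length does not match number of genes")
        if len(set(gene_ids)) != K:
            raise ValueError("duplicate gene_ids")
        self.R = R
        self.G = G
        self.gene_ids = gene_ids

    @property
    def K(self) -> int:
        return self.R.shape[0]

    @property
    def n(self) -> int:
        return self.R.shape[1]

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_tsv(cls, path) -> "PairedExpression":
        """Load from the native TSV layout (gene_id, R block, G block)."""
        gene_ids, R, G = pio.read_paired_matrix(path)
        return cls(R, G, gene_ids=gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedExpression":
        """Build from a frame whose first column holds gene ids and whose
        remaining 2n columns are the R block followed by the G block."""
        if df.shape[1] < 3 or (df.shape[1] - 1) % 2 != 0:
            raise ValueError("expected gene_id column plus an even number of value columns")
        n = (df.shape[1] - 1) // 2
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(values[:, :n], values[:, n:], gene_ids=gene_ids)

    def to_tsv(self, path) -> None:
        pio.write_paired_matrix(path, self.gene_ids, self.R, self.G)

    def swap_channels(self) -> "PairedExpression":
        """Exchange test and reference channels (dye-swap view)."""
        return PairedExpression(self.G, self.R, gene_ids=list(self.gene_ids))

    # ---------------------------------------------------------------- fit

    def fit(
        self,
        method: str = "tprop",
        *,
        shift: float = 0.0,
        variance: str = "null",
        policy: str | MissingPolicy | None = None,
        alpha: float = 0.05,
        adjust: str = "none",
    ) -> "DEResults":
        """Test every gene for differential expression.

        Parameters
        ----------
        method : {"tprop", "zprop", "ratio"}
            ``tprop`` — t-test of the mean per-pair proportion against 0.5
            (the recommended robust statistic); ``zprop`` — z-test of the
            pooled proportion under the binomial hybridization model;
            ``ratio`` — one-sample t-test of per-pair log2-ratios against 0.
        shift : float
            Symmetric pseudocount added to both channels before log-ratios
            (ratio method only); 0 means none.
        variance : {"null", "plug_in"}
            z-test denominator: null variance 0.25 or plug-in p(1-p).
        policy : {"gene-missing", "drop-pairs"}, optional
            Undefined-pair handling; defaults to gene-missing for ratios and
            drop-pairs for proportions.
        alpha : float
            Working significance level.
        adjust : {"none", "bonferroni", "bh"}
            Multiplicity adjustment across genes; missing genes are excluded
            from the multiplicity count.
        """
        if method not in METHODS:
            raise ValueError(f"unknown method: {method!r} (expected one of {METHODS})")
        if isinstance(policy, str):
            try:
                policy = _POLICY_ALIASES[policy]
            except KeyError:
                raise ValueError(f"unknown policy: {policy!r}") from None

        rows = []
        for i in range(self.K):
            g, r = self.G[i], self.R[i]
            p_bar, s_p, n_used_p = mean_proportion(g, r, policy or MissingPolicy.DROP_PAIRS)
            p_hat, _, m_total = pooled_proportion(g, r)
            r_hat, s_r, n_used_r = log_ratio(g, r, shift, policy or MissingPolicy.GENE_MISSING)
            if method == "tprop":
                out = proportion_t_test(p_bar, s_p, n_used_p, alpha)
            elif method == "zprop":
                out = binomial_z_test(p_hat, m_total, variance, alpha)
            else:
                out = ratio_t_test(r_hat, s_r, n_used_r, alpha)
            rows.append(_row(self.gene_ids[i], p_bar, p_hat, r_hat, out))
        return _assemble(rows, self, method, alpha, adjust, shift=shift)


def two_group_fit(
    trt: PairedExpression,
    cont: PairedExpression,
    statistic: str = "proportion",
    *,
    shift: float = 0.0,
    alpha: float = 0.05,
    adjust: str = "none",
) -> "DEResults":
    """Welch two-group comparison of per-array gene statistics.

    For each gene, every array contributes one value — its per-pair
    proportion (``statistic="proportion"``) or log2-ratio
    (``statistic="ratio"``, optionally shifted) — and the treatment and
    control groups of values are compared with Welch's unequal-variance
    t-test.  Arrays where the statistic is undefined are dropped; a gene is
    missing when either group retains fewer than two arrays.
    """
    if statistic not in ("proportion", "ratio"):
        raise ValueError("statistic must be 'proportion' or 'ratio'")
    if trt.gene_ids != cont.gene_ids:
        raise ValueError("treatment and control matrices must carry identical gene_ids")
    rows = []
    for i in range(trt.K):
        if statistic == "proportion":
            x = pair_proportions(trt.G[i], trt.R[i])
            y = pair_proportions(cont.G[i], cont.R[i])
        else:
            x = log_ratios(trt.G[i], trt.R[i], shift)
            y = log_ratios(cont.G[i], cont.R[i], shift)
        out = welch_two_group_test(x, y, alpha)
        p_bar, _, _ = mean_proportion(trt.G[i], trt.R[i])
        p_hat, _, _ = pooled_proportion(trt.G[i], trt.R[i])
        r_hat, _, _ = log_ratio(trt.G[i], trt.R[i], shift)
        rows.append(_row(trt.gene_ids[i], p_bar, p_hat, r_hat, out))
    return _assemble(rows, trt, f"welch-{statistic}", alpha, adjust, shift=shift)


def _row(gene_id, p_bar, p_hat, r_hat, out: TestOutcome) -> dict:
    return {
        "gene_id": gene_id,
        "p_bar": p_bar,
        "p_hat": p_hat,
        "r_hat": r_hat,
        "statistic": out.statistic,
        "df": out.df if out.df is not None else np.nan,
        "p_value": out.p_value,
        "missing": out.missing,
        "method": out.method,
    }


def _assemble(rows, model, method, alpha, adjust, shift=0.0) -> "DEResults":
    table = pd.DataFrame(rows)
    adj = adjust_pvalues(table["p_value"].to_numpy(), method=adjust, alpha=alpha)
    table["p_adjusted"] = adj.adjusted_p
    table["significant"] = adj.significant
    table = table[pio.RESULT_COLUMNS]
    return DEResults(
        model=model, table=table, method=method, alpha=alpha, adjust=adjust, shift=shift
    )


@dataclass
class DEResults:
    """Per-gene differential-expression results.

    ``table`` holds one row per input gene, in input order, with columns
    gene_id, p_bar, p_hat, r_hat, statistic, df, p_value, p_adjusted,
    significant, missing, method.
    """

    model: PairedExpression
    table: pd.DataFrame
    method: str
    alpha: float
    adjust: str
    shift: float = 0.0

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_missing(self) -> int:
        return int(self.table["missing"].sum())

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene_id"].tolist()

    def to_tsv(self, path) -> None:
        pio.write_results(self.table, path)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary: design, counts, and the top genes by
        p-value."""
        buf = _io.StringIO()
        m = self.model
        buf.write("Paired differential-expression results\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"genes (K):            {m.K}\n")
        buf.write(f"paired samples (n):   {m.n}\n")
        buf.write(f"method:               {self.method}")
        if self.method == "ratio" and self.shift:
            buf.write(f" (shift {self.shift:g})")
        buf.write("\n")
        buf.write(f"alpha:                {self.alpha:g}  (adjust: {self.adjust})\n")
        buf.write(f"missing genes:        {self.n_missing}\n")
        buf.write(f"significant genes:    {self.n_significant}\n")
        shown = self.table.sort_values("p_value").head(top)
        buf.write("-" * 54 + "\n")
        buf.write(f"top {len(shown)} genes by p-value:\n")
        sub = shown[["gene_id", "p_bar", "r_hat", "statistic", "p_value", "p_adjusted"]]
        buf.write(sub.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        buf.write("\n")
        return buf.getvalue()

    def plot_pvalues(self, ax=None, bins: int = 20):
        """Histogram of raw p-values (uniform under the global null)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.p_values
        ax.hist(p[~np.isnan(p)], bins=bins, range=(0, 1), edgecolor="black")
        ax.set_xlabel("raw p-value")
        ax.set_ylabel("genes")
        ax.set_title(f"{self.method}: p-value distribution")
        return ax
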