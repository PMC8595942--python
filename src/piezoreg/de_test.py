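"""Negative-binomial differential expression between condition pairs.

The model treats counts for gene *i* in sample *j* as
NB(mean = s_j * q_ic, dispersion alpha_i) with per-sample size factors s_j
(median-of-ratios) and a per-condition expression level q_ic.  Dispersions are
estimated by method of moments on normalized counts, pooled within
conditions, then shrunk halfway toward a fitted mean-dispersion trend
alpha_trend(mu) = a0 + a1/mu.  The two-group contrast is a Wald test on
log(q_B) - log(q_A) with a delta-method standard error; p-values are
Benjamini-Hochberg adjusted and genes are called at adjusted p < alpha
(default 1%).

The entry point mirrors the modelling-object convention of statsmodels: build
an :class:`NBDEModel` from a :class:`~piezoreg.expression_norm.CountMatrix`
and a condition pair, call :meth:`~NBDEModel.fit`, and read estimates,
p-values and calls off the returned :class:`NBDEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list
from statsmodels.stats.multitest import multipletests

from .expression_norm import CountMatrix, NormalizedMatrix, rle_size_factors

DISPERSION_FLOOR = 1e-8


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersions with the trend and shrinkage used to get them."""

    alpha: pd.Series          # final shrunk dispersions (>= floor)
    genewise: pd.Series       # raw method-of-moments estimates
    trend_params: tuple[float, float]  # (a0, a1) of a0 + a1/mu
    shrinkage: float
    mean: pd.Series           # overall mean of normalized counts

    def trend(self, mu: np.ndarray | pd.Series) -> np.ndarray:
        a0, a1 = self.trend_params
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-300), 0.0)


def estimate_dispersion(
    matrix: CountMatrix,
    size_factors: pd.Series | None = None,
    shrinkage: float = 0.5,
) -> DispersionEstimate:
    """Method-of-moments dispersions shrunk toward a 1/mu trend.

    Per gene and condition, alpha_hat = max(0, (s^2 - mu)/mu^2) on
    size-factor-normalized counts; condition estimates are averaged.  The
    trend a0 + a1/mu is fit by least squares on genes with alpha_hat > 0, and
    the final dispersion is ``shrinkage * trend + (1 - shrinkage) * alpha_hat``
    floored at 1e-8.  Requires >= 2 replicates in every condition.
    """
    if size_factors is None:
        size_factors = rle_size_factors(matrix)
    for cond in matrix.conditions:
        if len(matrix.condition_samples(cond)) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    norm = matrix.counts / size_factors
    n_genes = norm.shape[0]
    alpha_sum = np.zeros(n_genes)
    alpha_n = np.zeros(n_genes)
    for cond in matrix.conditions:
        sub = norm[matrix.condition_samples(cond)].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        a = np.zeros(n_genes)
        a[ok] = np.maximum(0.0, (var[ok] - mu[ok]) / mu[ok] ** 2)
        alpha_sum[ok] += a[ok]
        alpha_n[ok] += 1
    genewise = np.where(alpha_n > 0, alpha_sum / np.maximum(alpha_n, 1), 0.0)
    overall_mu = norm.to_numpy(dtype=float).mean(axis=1)

    fit_mask = (genewise > 0) & (overall_mu > 0)
    if fit_mask.sum() >= 2:
        X = np.column_stack(
            [np.ones(fit_mask.sum()), 1.0 / overall_mu[fit_mask]]
        )
        coef, *_ = np.linalg.lstsq(X, genewise[fit_mask], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:  # degenerate input (e.g. all-constant genes): flat zero trend
        a0, a1 = 0.0, 0.0

    with np.errstate(divide="ignore"):
        trend = np.where(overall_mu > 0, a0 + a1 / np.maximum(overall_mu, 1e-300), 0.0)
    final = shrinkage * trend + (1.0 - shrinkage) * genewise
    final = np.maximum(final, DISPERSION_FLOOR)
    idx = matrix.counts.index
    return DispersionEstimate(
        alpha=pd.Series(final, index=idx, name="alpha"),
        genewise=pd.Series(genewise, index=idx, name="alpha_mom"),
        trend_params=(a0, a1),
        shrinkage=shrinkage,
        mean=pd.Series(overall_mu, index=idx, name="mean"),
    )


@dataclass(frozen=True)
class DEResult:
    """Per-gene result of one pairwise contrast."""

    locus_tag: str
    comparison: tuple[str, str]
    base_mean_a: float
    base_mean_b: float
    log2fc: float
    p_value: float
    p_adj: float
    call: str  # "over_in_B", "over_in_A" or "ns"


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class NBDEModel:
    """Two-group negative-binomial Wald model for one condition pair.

    Parameters
    ----------
    matrix
        Filtered count matrix with design.
    comparison
        Ordered condition pair ``(A, B)``; positive log2 fold-changes mean
        higher expression in B.
    size_factors
        Optional per-sample factors; median-of-ratios on ``matrix`` if absent.
    dispersion
        Optional precomputed :class:`DispersionEstimate` (shared across the
        three pairwise contrasts of a study); estimated from ``matrix``
        otherwise.
    """

    def __init__(
        self,
        matrix: CountMatrix,
        comparison: tuple[str, str],
        size_factors: pd.Series | None = None,
        dispersion: DispersionEstimate | None = None,
    ) -> None:
        cond_a, cond_b = comparison
        for c in (cond_a, cond_b):
            if c not in matrix.conditions:
                raise ValueError(f"condition {c!r} not present in design")
        self.matrix = matrix
        self.comparison = (cond_a, cond_b)
        self.size_factors = (
            rle_size_factors(matrix) if size_factors is None else size_factors
        )
        self.dispersion = dispersion

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        comparison: tuple[str, str],
        gene_lengths: pd.Series | None = None,
        **kwargs,
    ) -> "NBDEModel":
        """Build from plain DataFrames; lengths default to 1 kb placeholders
        (they do not enter the test, only TPM needs real lengths)."""
        if gene_lengths is None:
            gene_lengths = pd.Series(1000, index=counts.index)
        matrix = CountMatrix(counts=counts, gene_lengths=gene_lengths, design=design)
        return cls(matrix, comparison, **kwargs)

    def fit(self, alpha: float = 0.01, pseudocount: float = 0.5) -> "NBDEResults":
        """Run the Wald test for every gene and return results.

        Per gene: condition levels ``q = mean(normalized counts) + pseudocount``;
        ``log2fc = log2(q_B / q_A)``; Var(ln q_c) by the delta method is
        ``sum_j (1/(s_j q_c) + alpha_i) / n_c^2`` over the samples of
        condition c; the Wald z is the ln-scale fold-change over its standard
        error with a two-sided normal p-value.
        """
        matrix = self.matrix
        cond_a, cond_b = self.comparison
        for c in (cond_a, cond_b):
            if len(matrix.condition_samples(c)) < 2:
                raise ValueError(f"condition {c!r} has fewer than 2 replicates")
        dispersion = self.dispersion
        if dispersion is None:
            dispersion = estimate_dispersion(matrix, self.size_factors)
        alpha_i = dispersion.alpha.to_numpy(dtype=float)

        norm = matrix.counts / self.size_factors

        def condition_stats(cond: str) -> tuple[np.ndarray, np.ndarray]:
            samples = matrix.condition_samples(cond)
            q = norm[samples].mean(axis=1).to_numpy(dtype=float) + pseudocount
            s = self.size_factors[samples].to_numpy(dtype=float)
            n = len(samples)
            var_ln = (1.0 / (s[None, :] * q[:, None]) + alpha_i[:, None]).sum(axis=1)
            return q, var_ln / n**2

        q_a, var_a = condition_stats(cond_a)
        q_b, var_b = condition_stats(cond_b)
        ln_fc = np.log(q_b) - np.log(q_a)
        se = np.sqrt(var_a + var_b)
        z = np.where(ln_fc == 0.0, 0.0, ln_fc / se)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.minimum(p, 1.0)
        p_adj = bh_adjust(p)
        log2fc = ln_fc / np.log(2.0)
        call = np.where(
            (p_adj < alpha) & (log2fc > 0),
            "over_in_B",
            np.where((p_adj < alpha) & (log2fc < 0), "over_in_A", "ns"),
        )
        frame = pd.DataFrame(
            {
                "baseMeanA": q_a - pseudocount,
                "baseMeanB": q_b - pseudocount,
                "log2fc": log2fc,
                "se_ln": se,
                "p_value": p,
                "p_adj": p_adj,
                "call": call,
            },
            index=matrix.counts.index,
        )
        return NBDEResults(
            frame=frame,
            comparison=self.comparison,
            alpha=alpha,
            dispersion=dispersion,
            size_factors=self.size_factors,
        )


class NBDEResults:
    """Results of :meth:`NBDEModel.fit`: estimates, p-values and calls."""

    def __init__(
        self,
        frame: pd.DataFrame,
        comparison: tuple[str, str],
        alpha: float,
        dispersion: DispersionEstimate,
        size_factors: pd.Series,
    ) -> None:
        self.frame = frame
        self.comparison = comparison
        self.alpha = alpha
        self.dispersion = dispersion
        self.size_factors = size_factors

    def deg_sets(self) -> dict[str, set[str]]:
        """Locus tags overexpressed in each condition of the pair."""
        f = self.frame
        return {
            "over_in_A": set(f.index[f["call"] == "over_in_A"]),
            "over_in_B": set(f.index[f["call"] == "over_in_B"]),
        }

    def to_records(self) -> list[DEResult]:
        return [
            DEResult(
                locus_tag=tag,
                comparison=self.comparison,
                base_mean_a=row.baseMeanA,
                base_mean_b=row.baseMeanB,
                log2fc=row.log2fc,
                p_value=row.p_value,
                p_adj=row.p_adj,
                call=row.call,
            )
            for tag, row in self.frame.iterrows()
        ]

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "comparison", f"{self.comparison[0]}:{self.comparison[1]}")
        out.to_csv(path, sep="\t", index_label="locus_tag")

    def summary(self) -> str:
        """Text summary: contrast, call counts, dispersion trend, top genes."""
        f = self.frame
        a, b = self.comparison
        n_a = int((f["call"] == "over_in_A").sum())
        n_b = int((f["call"] == "over_in_B").sum())
        a0, a1 = self.dispersion.trend_params
        lines = [
            "NB Wald differential expression",
            "=" * 47,
            f"contrast:        {a} vs {b}",
            f"genes tested:    {len(f)}",
            f"adjusted p <     {self.alpha:g}",
            f"over in {a}: {n_a}",
            f"over in {b}: {n_b}",
            f"dispersion trend a0 + a1/mu: a0={a0:.4g}, a1={a1:.4g}",
            "-" * 47,
            "top genes by adjusted p-value:",
        ]
        top = f.sort_values(["p_adj", "p_value"]).head(10)
        lines.append(f"{'locus_tag':<18}{'log2fc':>8}{'p_adj':>12}  call")
        for tag, row in top.iterrows():
            lines.append(
                f"{tag:<18}{row.log2fc:>8.2f}{row.p_adj:>12.3g}  {row.call}"
            )
        return "\n".join(lines)


def nb_wald_test(
    matrix: CountMatrix,
    size_factors: pd.Series | None,
    dispersion: DispersionEstimate | None,
    comparison: tuple[str, str],
    alpha: float = 0.01,
) -> list[DEResult]:
    """Functional wrapper: fit :class:`NBDEModel` and return per-gene records."""
    model = NBDEModel(matrix, comparison, size_factors, dispersion)
    return model.fit(alpha=alpha).to_records()


def call_deg(
    results: Iterable[DEResult] | pd.DataFrame, alpha: float = 0.01
) -> dict[str, set[str]]:
    """Partition genes into over_in_A / over_in_B at adjusted p < alpha."""
    if isinstance(results, pd.DataFrame):
        f = results
        return {
            "over_in_A": set(f.index[(f["p_adj"] < alpha) & (f["log2fc"] < 0)]),
            "over_in_B": set(f.index[(f["p_adj"] < alpha) & (f["log2fc"] > 0)]),
        }
    over_a, over_b = set(), set()
    for r in results:
        if r.p_adj < alpha and r.log2fc > 0:
            over_b.add(r.locus_tag)
        elif r.p_adj < alpha and r.log2fc < 0:
            over_a.add(r.locus_tag)
    return {"over_in_A": over_a, "over_in_B": over_b}


@dataclass
class ClusteringResult:
    """Z-score matrix plus average-linkage clustering of the samples."""

    zscores: pd.DataFrame
    linkage_matrix: np.ndarray
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def zscore_cluster(normalized: NormalizedMatrix) -> ClusteringResult:
    """Per-gene z-scores and hierarchical clustering of samples.

    Genes with zero variance across samples are dropped.  Samples are sorted
    by id before clustering so leaf order is deterministic under ties;
    distances are Euclidean, linkage is average.
    """
    values = normalized.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    values = values[sorted(values.columns)]
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=0, keepdims=True)
    zdf = pd.DataFrame(z, index=values.index[keep], columns=values.columns)
    Z = linkage(z.T, method="average", metric="euclidean")
    order = [values.columns[i] for i in leaves_list(Z)]
    return ClusteringResult(zscores=zdf, linkage_matrix=Z, leaf_order=order)
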