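"""Count-matrix containers, TPM and median-of-ratios normalization, filtering.

Two normalizations are exposed: transcripts-per-million (length-corrected,
every sample column sums to 1e6 — used for visualization) and relative log
expression / median-of-ratios size factors (used by the differential
expression test).  Weak-expression filtering keeps genes with a minimum
counts-per-million in a minimum number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample raw read counts with gene lengths and a sample design.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = locus tags, columns = sample
        ids.
    gene_lengths
        CDS length in bp per gene, aligned to ``counts.index``.
    design
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``, aligned to ``counts.columns``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.counts.index[self.gene_lengths.isna()][:5].tolist()
            raise ValueError(f"genes without lengths: {missing}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if set(self.design.index) != set(self.counts.columns):
            raise ValueError("design samples do not match count matrix columns")
        self.design = self.design.reindex(self.counts.columns)
        if "condition" not in self.design.columns:
            raise ValueError("design must have a 'condition' column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        if len(sel) == 0:
            raise ValueError(f"condition {condition!r} not in design")
        return list(sel)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        design_path: str | Path,
        lengths_path: str | Path | None = None,
        lengths: pd.Series | None = None,
    ) -> "CountMatrix":
        """Load counts (genes x samples TSV), design TSV and gene lengths.

        The design TSV needs columns sample_id, condition, replicate.  Lengths
        come from a two-column TSV (locus_tag, length) or a provided Series.
        """
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        if lengths is None:
            if lengths_path is None:
                raise ValueError("need lengths_path or lengths")
            ltab = pd.read_csv(lengths_path, sep="\t", index_col=0)
            lengths = ltab.iloc[:, 0]
        return cls(counts=counts, gene_lengths=lengths, design=design)

    def to_tsv(self, counts_path: str | Path, design_path: str | Path | None = None,
               lengths_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="locus_tag")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index_label="sample_id")
        if lengths_path is not None:
            self.gene_lengths.rename("length").to_csv(
                lengths_path, sep="\t", index_label="locus_tag"
            )


@dataclass
class NormalizedMatrix:
    """Normalized expression values (``kind`` = "tpm" or "size_factor_scaled")."""

    values: pd.DataFrame
    kind: str
    size_factors: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("tpm", "size_factor_scaled"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.kind == "size_factor_scaled":
            if self.size_factors is None or (self.size_factors <= 0).any():
                raise ValueError("size_factor_scaled requires positive size factors")


def tpm(matrix: CountMatrix) -> NormalizedMatrix:
    """Transcripts per kilobase million: length-rate normalized, column sum 1e6."""
    kb = matrix.gene_lengths.to_numpy(dtype=float) / 1000.0
    rates = matrix.counts.to_numpy(dtype=float) / kb[:, None]
    colsum = rates.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample column: {matrix.samples[zero[0]]!r}")
    values = pd.DataFrame(
        rates / colsum * 1e6, index=matrix.counts.index, columns=matrix.counts.columns
    )
    return NormalizedMatrix(values=values, kind="tpm")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million on raw library sizes."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"all-zero sample column: {bad!r}")
    return counts / lib * 1e6


def rle_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios (relative log expression) per-sample size factors.

    Genes with any zero count are excluded from the per-gene geometric means;
    factors are rescaled so their geometric mean is 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts; cannot compute RLE factors")
    sub = counts[allpos]
    log_gm = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_gm[:, None]
    log_s = np.median(ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=matrix.counts.columns, name="size_factor")


def rle_normalize(matrix: CountMatrix, size_factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts divided by RLE size factors."""
    s = rle_size_factors(matrix) if size_factors is None else size_factors
    values = matrix.counts / s
    return NormalizedMatrix(values=values, kind="size_factor_scaled", size_factors=s)


def filter_low_expression(
    matrix: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_samples > len(matrix.samples):
        raise ValueError("min_samples exceeds number of samples")
    keep = (cpm(matrix.counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    return CountMatrix(
        counts=matrix.counts.loc[keep].copy(),
        gene_lengths=matrix.gene_lengths.loc[keep].copy(),
        design=matrix.design.copy(),
    )
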