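"""End-to-end orchestration: promoters -> motif scan -> normalization -> DE
-> regulon summaries, with a manifest recording everything needed to
reproduce the outputs bit-for-bit."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de_test import NBDEModel, estimate_dispersion
from .expression_norm import CountMatrix, filter_low_expression, rle_size_factors, tpm
from .motif_scan import (
    compile_pattern,
    promoters_with_motif,
    scan_promoters,
    write_hits_bed,
    write_hits_tsv,
)
from .regulon_analysis import (
    cluster_summary,
    overlap_stats,
    read_clusters_tsv,
    render_cluster_summary,
    venn_counts,
)
from .sequence_io import (
    extract_promoters,
    read_annotation,
    read_fasta,
    write_promoters_bed,
    write_promoters_fasta,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.

    ``patterns`` maps pattern ids to pattern strings in the block/gap grammar
    (e.g. ``{"surr_short": "GTTn{3}AAC"}``).
    """

    genome: str
    annotation: str
    counts: str
    design: str
    outdir: str
    lengths: str | None = None
    clusters: str | None = None
    annotation_dialect: str = "gff3"
    promoter_length: int = 200
    patterns: dict[str, str] = field(
        default_factory=lambda: {
            "surr_short": "GTTn{3}AAC",
            "surr_long": "GTTn{3}AACn{5}GTT",
        }
    )
    max_mismatch: int = 0
    distance_from: str = "5prime"
    min_cpm: float = 1.0
    min_samples: int = 3
    alpha: float = 0.01
    tag_step: int = 5
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``config.outdir``.

    Returns a dict with the in-memory results (promoters, hits, DE results per
    contrast, overlap stats, summary tables) and the manifest.  Any stage
    error is re-raised as :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("genome", "annotation", "counts", "design"):
        path = getattr(config, name)
        if not Path(path).is_file():
            raise FileNotFoundError(f"{name} file not found: {path}")

    results: dict = {}
    stage = "promoters"
    try:
        genomes = read_fasta(config.genome)
        genes = read_annotation(config.annotation, config.annotation_dialect)
        promoters = extract_promoters(genes, genomes, config.promoter_length)
        write_promoters_fasta(promoters, outdir / "promoters.fasta")
        write_promoters_bed(promoters, outdir / "promoters.bed")
        results["genes"] = genes
        results["promoters"] = promoters

        stage = "scan"
        patterns = [
            compile_pattern(spec, pid, config.max_mismatch)
            for pid, spec in config.patterns.items()
        ]
        hits = scan_promoters(
            promoters, patterns, distance_from=config.distance_from
        )
        write_hits_tsv(hits, outdir / "motif_hits.tsv")
        write_hits_bed(hits, promoters, patterns, outdir / "motif_hits.bed")
        motif_tags = promoters_with_motif(hits)
        results["hits"] = hits
        results["motif_tags"] = motif_tags

        stage = "normalize"
        lengths = None
        if config.lengths is None:
            lengths = pd.Series(
                {g.locus_tag: g.length for g in genes}, name="length"
            )
        matrix = CountMatrix.from_tsv(
            config.counts, config.design, config.lengths, lengths
        )
        tpm_matrix = tpm(matrix)
        tpm_matrix.values.to_csv(outdir / "tpm.tsv", sep="\t", index_label="locus_tag")
        filtered = filter_low_expression(matrix, config.min_cpm, config.min_samples)
        size_factors = rle_size_factors(filtered)
        size_factors.to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample_id")
        filtered.counts.to_csv(
            outdir / "filtered_counts.tsv", sep="\t", index_label="locus_tag"
        )
        results["matrix"] = matrix
        results["filtered"] = filtered
        results["size_factors"] = size_factors

        stage = "de"
        dispersion = estimate_dispersion(filtered, size_factors)
        conditions = filtered.conditions
        de_results = {}
        de_calls = {}
        for cond_a, cond_b in combinations(conditions, 2):
            model = NBDEModel(filtered, (cond_a, cond_b), size_factors, dispersion)
            res = model.fit(alpha=config.alpha)
            res.to_tsv(outdir / f"de_{cond_a}_vs_{cond_b}.tsv")
            de_results[(cond_a, cond_b)] = res
            de_calls[(cond_a, cond_b)] = res.deg_sets()
        results["de"] = de_results

        stage = "overlap"
        universe = [g.locus_tag for g in genes]
        regulated = set()
        deg_per_comparison = {}
        for pair, sets in de_calls.items():
            degs = sets["over_in_A"] | sets["over_in_B"]
            deg_per_comparison[f"{pair[0]}:{pair[1]}"] = degs
            regulated |= degs
        # genes absent from the filtered universe can never be called;
        # overlap universe is the full annotation
        stats = overlap_stats(universe, motif_tags & set(universe), regulated)
        clusters = read_clusters_tsv(config.clusters, config.tag_step)
        summary = cluster_summary(de_calls, clusters, universe=universe)
        render_cluster_summary(summary).to_csv(
            outdir / "cluster_summary.tsv", sep="\t", index=False
        )
        venn = venn_counts(deg_per_comparison)
        (outdir / "venn_counts.json").write_text(json.dumps(venn, indent=1))
        overlap_payload = {
            "n_universe": stats.n_universe,
            "n_motif_promoters": stats.n_set_a,
            "n_regulated": stats.n_set_b,
            "n_overlap": stats.n_overlap,
            "pct_of_universe": stats.pct_of_universe,
            "pct_of_motif_set": stats.pct_of_a,
            "pct_of_regulated": stats.pct_of_b,
        }
        (outdir / "overlap.json").write_text(json.dumps(overlap_payload, indent=1))
        results["overlap"] = stats
        results["cluster_summary"] = summary
        results["venn"] = venn

        if config.make_plots:
            stage = "plots"
            from .plotting import pca_plot, zscore_heatmap

            pca_plot(tpm_matrix, filtered.design, outdir / "pca.png")
            zscore_heatmap(tpm_matrix, outdir / "heatmap.png")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    manifest = {
        "piezoreg_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("genome", "annotation", "counts", "design", "lengths",
                         "clusters", "outdir")
        },
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("genome", "annotation", "counts", "design")
            if getattr(config, name) is not None
        },
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
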