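"""Gapped-motif compilation and scanning against brute-force oracles."""

import numpy as np
import pytest

from piezoreg.motif_scan import (
    MotifPattern,
    SURR_LONG,
    SURR_SHORT,
    compile_pattern,
    mutated_motif_report,
    promoters_with_motif,
    scan_promoters,
    scan_sequence,
    write_hits_bed,
)
from piezoreg.sequence_io import GenomeRecord, PromoterRegion, reverse_complement
from piezoreg.synthetic_data import SimulationConfig, generate_genome
from piezoreg.sequence_io import extract_promoters


def brute_force_offsets(seq, pattern, max_mismatch=None):
    """Position-by-position sliding-window comparison (forward strand)."""
    budget = pattern.max_mismatch if max_mismatch is None else max_mismatch
    conserved = pattern.conserved_positions()
    out = []
    for off in range(len(seq) - pattern.span + 1):
        mm = sum(seq[off + pos] != ch for pos, ch in conserved)
        if mm <= budget:
            out.append(off)
    return out


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_promoter(tag, seq):
    return PromoterRegion(tag, "c1", seq, 1, len(seq), "+", False)


class TestCompilePattern:
    @pytest.mark.parametrize(
        "spec,n_blocks,span",
        [("GTTn{3}AAC", 2, 9), ("GTTn{3}AACn{5}GTT", 3, 17), ("GTT", 1, 3)],
    )
    def test_examples(self, spec, n_blocks, span):
        pattern = compile_pattern(spec)
        assert len(pattern.blocks) == n_blocks
        assert pattern.span == span

    @pytest.mark.parametrize(
        "spec", ["GTTn{3}", "n{3}AAC", "GTTn{3}n{2}AAC", "GTTxAAC", "gtt"]
    )
    def test_malformed_specs_rejected(self, spec):
        with pytest.raises(ValueError):
            compile_pattern(spec)

    def test_error_names_offending_token(self):
        with pytest.raises(ValueError, match="xAAC"):
            compile_pattern("GTTxAAC")


class TestScanSequence:
    def test_literal_short_match(self):
        hits = scan_sequence("GTTAAAAAC", SURR_SHORT)
        assert len(hits) == 1
        assert hits[0].offset == 0
        assert hits[0].mismatches == 0

    def test_long_contains_short(self):
        seq = "GTTAAAAACTTTTTGTT"
        (long_hit,) = scan_sequence(seq, SURR_LONG)
        (short_hit,) = scan_sequence(seq, SURR_SHORT)
        assert long_hit.offset == 0 and short_hit.offset == 0

    def test_empty_and_too_short_sequences(self):
        assert scan_sequence("", SURR_SHORT) == []
        assert scan_sequence("GTTAAAA", SURR_SHORT) == []

    def test_n_never_matches_conserved_positions(self):
        assert scan_sequence("GTTAAAAAN", SURR_SHORT) == []
        # N in the gap is fine
        assert len(scan_sequence("GTTNNNAAC", SURR_SHORT)) == 1

    def test_matches_brute_force_on_random_200mers(self, rng):
        for _ in range(40):
            seq = random_dna(rng, 200)
            got = [h.offset for h in scan_sequence(seq, SURR_SHORT, both_strands=False)]
            assert got == brute_force_offsets(seq, SURR_SHORT)

    def test_short_pattern_both_strands_equals_forward_only(self, rng):
        """GTTn3AAC is its own reverse complement, so both-strand scanning
        must not change the hit offsets."""
        for _ in range(40):
            seq = random_dna(rng, 200)
            fwd = [h.offset for h in scan_sequence(seq, SURR_SHORT, both_strands=False)]
            both = [h.offset for h in scan_sequence(seq, SURR_SHORT, both_strands=True)]
            assert fwd == both
            assert all(
                h.strand == "promoter" for h in scan_sequence(seq, SURR_SHORT)
            )

    def test_revcomp_closure_on_random_50mers(self, rng):
        """Offsets on a sequence and its reverse complement are mirror images:
        off' = len - span - off."""
        span = SURR_SHORT.span
        for _ in range(40):
            seq = random_dna(rng, 50)
            fwd = set(brute_force_offsets(seq, SURR_SHORT))
            rc = set(brute_force_offsets(reverse_complement(seq), SURR_SHORT))
            assert fwd == {len(seq) - span - o for o in rc}

    def test_mismatch_budget_monotonicity(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 100)
            offsets = {}
            for k in (0, 1, 2):
                pattern = MotifPattern("p", SURR_SHORT.blocks, SURR_SHORT.gaps, k)
                offsets[k] = {h.offset for h in scan_sequence(seq, pattern)}
            assert offsets[0] <= offsets[1] <= offsets[2]

    def test_opposite_strand_hit_reports_revcomp_window(self):
        # plant the revcomp of a non-palindromic pattern
        pattern = compile_pattern("GGTn{2}ACC", "p")  # revcomp = GGTnnACC? no:
        # revcomp(GGTxxACC) = GGTyyACC -> palindromic too; use an asymmetric one
        pattern = compile_pattern("AAAn{1}CCC", "p")
        seq = "T" * 5 + reverse_complement("AAATCCC") + "T" * 5
        hits = scan_sequence(seq, pattern)
        assert len(hits) == 1
        assert hits[0].strand == "opposite"
        assert hits[0].matched_seq.startswith("AAA")


class TestScanPromoters:
    def test_distance_convention_5prime(self):
        # motif occupying the last span bases has distance = span
        seq = "T" * 191 + "GTTAAAAAC"
        hits = scan_promoters([make_promoter("G1", seq)], [SURR_SHORT])
        assert [h.distance for h in hits] == [SURR_SHORT.span]

    def test_distance_convention_3prime(self):
        seq = "T" * 191 + "GTTAAAAAC"
        hits = scan_promoters(
            [make_promoter("G1", seq)], [SURR_SHORT], distance_from="3prime"
        )
        assert [h.distance for h in hits] == [0]

    def test_hits_sorted_by_tag_then_distance(self):
        seq = "GTTAAAAAC" + "T" * 50 + "GTTCCCAAC" + "T" * 50
        proms = [make_promoter("B", seq), make_promoter("A", seq)]
        hits = scan_promoters(proms, [SURR_SHORT])
        assert [h.locus_tag for h in hits] == ["A", "A", "B", "B"]
        assert hits[0].distance < hits[1].distance

    def test_duplicate_locus_tags_rejected(self):
        proms = [make_promoter("A", "ACGT" * 20), make_promoter("A", "ACGT" * 20)]
        with pytest.raises(ValueError, match="duplicate"):
            scan_promoters(proms, [SURR_SHORT])

    def test_promoter_without_motif_gives_no_hits(self):
        assert scan_promoters([make_promoter("A", "T" * 200)], [SURR_SHORT]) == []

    def test_nested_short_reported_under_both_patterns(self):
        seq = "T" * 100 + "GTTAAAAACTTTTTGTT" + "T" * 83
        hits = scan_promoters([make_promoter("G", seq)], [SURR_SHORT, SURR_LONG])
        ids = {h.pattern_id for h in hits}
        assert ids == {"surr_short", "surr_long"}


class TestPromoterSets:
    def test_empty_hits_empty_set(self):
        assert promoters_with_motif([]) == set()

    def test_multiple_hits_one_promoter(self):
        seq = "GTTAAAAAC" + "T" * 20 + "GTTCCCAAC" + "T" * 20 + "GTTGGGAAC"
        hits = scan_promoters([make_promoter("A", seq)], [SURR_SHORT])
        assert len(hits) == 3
        assert promoters_with_motif(hits) == {"A"}

    def test_mutated_hits_excluded_by_default(self):
        seq = "T" * 100 + "GTTAAAAAT" + "T" * 91  # one mismatch in AAC block
        proms = [make_promoter("A", seq)]
        report = mutated_motif_report(proms, [SURR_SHORT])
        assert [h.mismatches for h in report] == [1]
        assert promoters_with_motif(report) == set()
        assert promoters_with_motif(report, include_mutated=True) == {"A"}


class TestGenomicBed:
    def test_bed_intervals_recover_match_from_genome(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_genes=120, motif_fraction=0.3)
        genome, genes, truth = generate_genome(cfg)
        proms = extract_promoters(genes, genome)
        hits = scan_promoters(proms, [SURR_SHORT, SURR_LONG])
        path = tmp_path / "hits.bed"
        write_hits_bed(hits, proms, [SURR_SHORT, SURR_LONG], path)
        strands = {p.locus_tag: p.strand for p in proms}
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == len(hits)
        for row, hit in zip(rows, hits):
            start, end = int(row[1]), int(row[2])
            window = genome.sequence[start:end]
            if row[5] == "+":
                assert window == hit.matched_seq
            else:
                assert reverse_complement(window) == hit.matched_seq
            # sanity: promoter-strand hits keep the gene strand
            if hit.strand == "promoter":
                assert row[5] == strands[hit.locus_tag]
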