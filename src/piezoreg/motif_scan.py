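"""Gapped degenerate motif compilation and promoter scanning.

The SurR regulator of Thermococcales binds a short palindromic element
GTTn{3}AAC and an extended element GTTn{3}AACn{5}GTT.  Patterns here are
ordered conserved blocks separated by fixed-length unconstrained gaps, with an
optional mismatch budget counted over conserved-block positions only.

Hit positions are reported as a distance from the start codon.  The default
convention ("5prime") is the 1-based position of the motif's 5'-most base
counting backwards from the base immediately preceding the start codon, so a
motif occupying the last ``span`` bases of the promoter has distance = span.
The alternative ("3prime") anchors on the motif's 3'-most base instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import PromoterRegion, reverse_complement

_TOKEN = re.compile(r"([ACGT]+)|(n\{(\d+)\})")


@dataclass(frozen=True)
class MotifPattern:
    """Ordered conserved DNA blocks with fixed inter-block gap lengths."""

    pattern_id: str
    blocks: tuple[str, ...]
    gaps: tuple[int, ...]
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.blocks or any(not b for b in self.blocks):
            raise ValueError(f"{self.pattern_id}: blocks must be non-empty")
        if any(set(b) - set("ACGT") for b in self.blocks):
            raise ValueError(f"{self.pattern_id}: blocks must be over ACGT")
        if len(self.gaps) != len(self.blocks) - 1:
            raise ValueError(f"{self.pattern_id}: need |blocks|-1 gaps")
        if any(g < 0 for g in self.gaps):
            raise ValueError(f"{self.pattern_id}: negative gap length")
        if self.max_mismatch < 0:
            raise ValueError(f"{self.pattern_id}: negative mismatch budget")

    @property
    def span(self) -> int:
        """Total window length covered by the pattern."""
        return sum(len(b) for b in self.blocks) + sum(self.gaps)

    def conserved_positions(self) -> list[tuple[int, str]]:
        """(offset within span, expected base) for every conserved position."""
        out = []
        pos = 0
        for i, block in enumerate(self.blocks):
            for ch in block:
                out.append((pos, ch))
                pos += 1
            if i < len(self.gaps):
                pos += self.gaps[i]
        return out


def compile_pattern(
    spec: str, pattern_id: str | None = None, max_mismatch: int = 0
) -> MotifPattern:
    """Parse a pattern string such as ``"GTTn{3}AACn{5}GTT"``.

    Grammar: uppercase ACGT runs are conserved blocks; ``n{k}`` is a fixed gap
    of k unconstrained bases.  Blocks and gaps must alternate, starting and
    ending with a block.
    """
    blocks: list[str] = []
    gaps: list[int] = []
    pos = 0
    expect_block = True
    while pos < len(spec):
        m = _TOKEN.match(spec, pos)
        if m is None:
            raise ValueError(f"pattern {spec!r}: unrecognized token at {spec[pos:]!r}")
        if m.group(1):
            if not expect_block:
                raise ValueError(f"pattern {spec!r}: two adjacent blocks at {m.group(1)!r}")
            blocks.append(m.group(1))
            expect_block = False
        else:
            if expect_block:
                raise ValueError(f"pattern {spec!r}: gap {m.group(2)!r} not between blocks")
            gaps.append(int(m.group(3)))
            expect_block = True
        pos = m.end()
    if expect_block:
        raise ValueError(f"pattern {spec!r}: must end with a conserved block")
    return MotifPattern(
        pattern_id=pattern_id or spec, blocks=tuple(blocks), gaps=tuple(gaps),
        max_mismatch=max_mismatch,
    )


#: The two SurR binding elements screened in promoters.
SURR_SHORT = compile_pattern("GTTn{3}AAC", "surr_short")
SURR_LONG = compile_pattern("GTTn{3}AACn{5}GTT", "surr_long")


@dataclass(frozen=True)
class RawHit:
    """A match within a single sequence (before distance annotation)."""

    offset: int
    strand: str  # "promoter" or "opposite"
    matched_seq: str
    mismatches: int


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a promoter."""

    locus_tag: str
    pattern_id: str
    distance: int
    promoter_offset: int
    strand: str  # "promoter" or "opposite"
    matched_seq: str
    mismatches: int


def _mismatch_counts(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Conserved-position mismatch count for every window start offset."""
    span = pattern.span
    n_win = len(seq) - span + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mm = np.zeros(n_win, dtype=np.int64)
    for pos, ch in pattern.conserved_positions():
        mm += arr[pos : pos + n_win] != ord(ch)
    return mm


def scan_sequence(
    seq: str, pattern: MotifPattern, both_strands: bool = True
) -> list[RawHit]:
    """Report every window matching ``pattern`` within the mismatch budget.

    Gap positions match anything; N never matches a conserved position.  With
    ``both_strands`` the reverse complement is scanned too and hits are mapped
    back to forward offsets; a window matching on both strands (palindromic
    pattern) is reported once with strand ``"promoter"``.
    """
    span = pattern.span
    budget = pattern.max_mismatch
    fwd = _mismatch_counts(seq, pattern)
    hits: dict[int, RawHit] = {}
    for off in np.nonzero(fwd <= budget)[0]:
        off = int(off)
        hits[off] = RawHit(off, "promoter", seq[off : off + span], int(fwd[off]))
    if both_strands:
        rc = reverse_complement(seq)
        rev = _mismatch_counts(rc, pattern)
        n_win = len(rev)
        for off_rc in np.nonzero(rev <= budget)[0]:
            off_rc = int(off_rc)
            off = n_win - 1 - off_rc  # forward offset of the same window
            mm = int(rev[off_rc])
            if off in hits:
                if mm < hits[off].mismatches:
                    hits[off] = RawHit(off, "promoter", rc[off_rc : off_rc + span], mm)
            else:
                hits[off] = RawHit(off, "opposite", rc[off_rc : off_rc + span], mm)
    return [hits[o] for o in sorted(hits)]


def scan_promoters(
    promoters: Sequence[PromoterRegion],
    patterns: Sequence[MotifPattern],
    both_strands: bool = True,
    distance_from: str = "5prime",
) -> list[MotifHit]:
    """Scan every promoter with every pattern, annotating start-codon distances.

    Hits are sorted by locus tag then distance ascending.  Duplicate locus
    tags among the promoters are a hard error.
    """
    if distance_from not in ("5prime", "3prime"):
        raise ValueError(f"unknown distance convention {distance_from!r}")
    tags = [p.locus_tag for p in promoters]
    if len(tags) != len(set(tags)):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise ValueError(f"duplicate locus tags among promoters: {dup[:5]}")
    out: list[MotifHit] = []
    for prom in promoters:
        for pattern in patterns:
            for hit in scan_sequence(prom.sequence, pattern, both_strands):
                if distance_from == "5prime":
                    distance = len(prom) - hit.offset
                else:
                    distance = len(prom) - hit.offset - pattern.span
                out.append(
                    MotifHit(
                        locus_tag=prom.locus_tag,
                        pattern_id=pattern.pattern_id,
                        distance=distance,
                        promoter_offset=hit.offset,
                        strand=hit.strand,
                        matched_seq=hit.matched_seq,
                        mismatches=hit.mismatches,
                    )
                )
    out.sort(key=lambda h: (h.locus_tag, h.distance, h.pattern_id))
    return out


def promoters_with_motif(
    hits: Iterable[MotifHit],
    pattern_ids: Iterable[str] | None = None,
    include_mutated: bool = False,
) -> set[str]:
    """Distinct locus tags with at least one hit among the selected patterns.

    Hits carrying mismatches (mutated motifs) are excluded unless
    ``include_mutated`` is set.
    """
    wanted = None if pattern_ids is None else set(pattern_ids)
    out = set()
    for h in hits:
        if wanted is not None and h.pattern_id not in wanted:
            continue
        if h.mismatches > 0 and not include_mutated:
            continue
        out.add(h.locus_tag)
    return out


def mutated_motif_report(
    promoters: Sequence[PromoterRegion],
    patterns: Sequence[MotifPattern],
    both_strands: bool = True,
    distance_from: str = "5prime",
) -> list[MotifHit]:
    """Hits with exactly one conserved-block mismatch (candidate mutated motifs)."""
    relaxed = [
        MotifPattern(p.pattern_id, p.blocks, p.gaps, max_mismatch=1) for p in patterns
    ]
    hits = scan_promoters(promoters, relaxed, both_strands, distance_from)
    return [h for h in hits if h.mismatches == 1]


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_tag\tpattern_id\tdistance\tpromoter_offset\tstrand\t"
            "matched_seq\tmismatches\n"
        )
        for h in hits:
            fh.write(
                f"{h.locus_tag}\t{h.pattern_id}\t{h.distance}\t{h.promoter_offset}\t"
                f"{h.strand}\t{h.matched_seq}\t{h.mismatches}\n"
            )


def write_hits_bed(
    hits: Iterable[MotifHit],
    promoters: Sequence[PromoterRegion],
    patterns: Sequence[MotifPattern],
    path: str | Path,
) -> None:
    """Write hits as BED6 in genomic coordinates (0-based half-open).

    The BED strand is the genomic strand of the match: the promoter's gene
    strand for strand="promoter" hits, the opposite for strand="opposite".
    """
    proms: Mapping[str, PromoterRegion] = {p.locus_tag: p for p in promoters}
    spans = {p.pattern_id: p.span for p in patterns}
    flip = {"+": "-", "-": "+"}
    with open(path, "w") as fh:
        for h in hits:
            prom = proms[h.locus_tag]
            span = spans[h.pattern_id]
            if prom.strand == "+":
                bed_start = prom.genomic_start - 1 + h.promoter_offset
            else:
                bed_start = prom.genomic_end - h.promoter_offset - span
            strand = prom.strand if h.strand == "promoter" else flip[prom.strand]
            fh.write(
                f"{prom.contig_id}\t{bed_start}\t{bed_start + span}\t"
                f"{h.locus_tag}|{h.pattern_id}\t0\t{strand}\n"
            )
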