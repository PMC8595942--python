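"""Regulon / DEG overlap statistics, cluster tables, Venn counts and EASE.

Utilities that combine motif-screen output with differential-expression calls:
expansion of compact locus-tag ranges ("A7C91_RS04230-04165") into member
lists, overlap counts with percentage reporting, per-gene-cluster
overexpression tables across directional condition pairs, 2/3-set Venn region
counts, and the conservative one-tailed Fisher enrichment statistic (EASE,
which removes one gene from the overlap cell before testing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_RANGE = re.compile(r"^(?P<prefix>.*?)(?P<first>\d+)(?:-(?P<second>\d+))?$")


def expand_locus_range(range_text: str, step: int = 5) -> list[str]:
    """Expand "PREFIX_A-SUFFIX_B" into the inclusive locus-tag sequence.

    The second endpoint repeats only the numeric suffix and may be shorter
    (zero-padding follows the first endpoint's width); descending ranges are
    allowed.  A span that is not a multiple of ``step`` is a hard error, which
    usually signals the wrong tag increment.
    A bare tag without "-" expands to itself.
    """
    m = _RANGE.match(range_text.strip())
    if m is None:
        raise ValueError(f"unparseable locus range {range_text!r}")
    prefix = m.group("prefix")
    first = m.group("first")
    second = m.group("second")
    width = len(first)
    a = int(first)
    if second is None:
        return [f"{prefix}{first}"]
    b = int(second)
    span = b - a
    if span % step != 0:
        raise ValueError(
            f"range {range_text!r}: span {abs(span)} not a multiple of step {step}"
        )
    direction = step if span >= 0 else -step
    return [f"{prefix}{n:0{width}d}" for n in range(a, b + direction, direction)]


def detect_tag_step(locus_tags: Iterable[str]) -> int:
    """Most common positive difference between consecutive numeric suffixes."""
    nums = []
    for tag in locus_tags:
        m = _RANGE.match(tag)
        if m and m.group("second") is None:
            nums.append(int(m.group("first")))
    nums.sort()
    diffs = [b - a for a, b in zip(nums, nums[1:]) if b > a]
    if not diffs:
        raise ValueError("cannot detect locus-tag step from fewer than 2 tags")
    return int(pd.Series(diffs).mode().iloc[0])


@dataclass(frozen=True)
class ClusterDefinition:
    """A named gene cluster given by a compact locus-tag range."""

    name: str
    locus_range: str
    member_tags: tuple[str, ...]

    @classmethod
    def from_range(cls, name: str, locus_range: str, step: int = 5) -> "ClusterDefinition":
        return cls(name, locus_range, tuple(expand_locus_range(locus_range, step)))

    @property
    def size(self) -> int:
        return len(self.member_tags)


def read_clusters_tsv(path: str | Path | None = None, step: int = 5) -> list[ClusterDefinition]:
    """Read cluster definitions (columns name, locus_range) from TSV.

    With no path, loads the bundled table of hydrogen/sulfur-metabolism
    clusters of the *T. piezophilus* study genome.
    """
    if path is None:
        ref = resources.files("piezoreg").joinpath("data/hydrogenase_clusters.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    for col in ("name", "locus_range"):
        if col not in table.columns:
            raise ValueError(f"cluster table missing column {col!r}")
    return [
        ClusterDefinition.from_range(row["name"], row["locus_range"], step)
        for _, row in table.iterrows()
    ]


def _round1(x: float) -> float:
    """Percentage rounded half-up to one decimal."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_pct(pct: float) -> str:
    """Render a 1-decimal percentage, dropping the decimal when integral."""
    return f"{pct:g}" if float(pct).is_integer() else f"{pct:.1f}"


@dataclass(frozen=True)
class OverlapStats:
    """Counts and percentages for two gene sets within a universe."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    pct_of_universe: float  # |A| / |universe|
    pct_of_a: float         # |A n B| / |A|
    pct_of_b: float         # |A n B| / |B|


def overlap_stats(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapStats:
    """Overlap of two subsets of a gene universe, with 1-decimal percentages.

    ``pct_of_universe`` is set A's share of the universe; ``pct_of_a`` /
    ``pct_of_b`` are the overlap's share of each set.  Membership outside the
    universe is a hard error.
    """
    uni, a, b = set(universe), set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        stray = sorted((a | b) - uni)
        raise ValueError(f"set members outside universe: {stray[:5]}")
    inter = a & b
    return OverlapStats(
        n_universe=len(uni),
        n_set_a=len(a),
        n_set_b=len(b),
        n_overlap=len(inter),
        pct_of_universe=_round1(100.0 * len(a) / len(uni)) if uni else 0.0,
        pct_of_a=_round1(100.0 * len(inter) / len(a)) if a else 0.0,
        pct_of_b=_round1(100.0 * len(inter) / len(b)) if b else 0.0,
    )


def cluster_summary(
    de_calls: Mapping[tuple[str, str], Mapping[str, set[str]]],
    clusters: Sequence[ClusterDefinition],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster overexpressed-CDS counts for every directional contrast.

    ``de_calls`` maps an ordered condition pair (A, B) to the over_in_A /
    over_in_B locus-tag sets of its test.  Each pair yields two directional
    columns "A>B" (genes over in A) and "B>A".  Cells are counts of cluster
    members in the set; :func:`render_cluster_summary` prints zeros as "nd".
    """
    universe_set = None if universe is None else set(universe)
    columns: dict[str, set[str]] = {}
    for (cond_a, cond_b), sets in de_calls.items():
        columns[f"{cond_a}>{cond_b}"] = set(sets["over_in_A"])
        columns[f"{cond_b}>{cond_a}"] = set(sets["over_in_B"])
    rows = []
    for cluster in clusters:
        members = set(cluster.member_tags)
        if universe_set is not None:
            missing = members - universe_set
            if missing:
                import warnings

                warnings.warn(
                    f"cluster {cluster.name}: {len(missing)} members absent "
                    "from the DE universe; counted as not-called",
                    stacklevel=2,
                )
        row: dict[str, object] = {
            "name": cluster.name,
            "locus_range": cluster.locus_range,
            "total_cds": cluster.size,
        }
        for col, called in columns.items():
            row[col] = len(members & called)
        rows.append(row)
    return pd.DataFrame(rows)


def render_cluster_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Copy of the summary with zero cells rendered as "nd"."""
    out = table.copy()
    for col in out.columns:
        if col in ("name", "locus_range", "total_cds"):
            continue
        out[col] = out[col].map(lambda v: "nd" if v == 0 else str(int(v)))
    return out


def venn_counts(deg_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Pairwise shared counts plus exclusive Venn regions for 2 or 3 sets.

    Keys: ``"A&B"`` for each pairwise intersection size, ``"only:A"`` for
    elements exclusive to A, and for three sets ``"A&B&C"`` plus pairwise
    exclusive regions ``"only:A&B"``.
    """
    names = list(deg_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    out: dict[str, int] = {}
    for a, b in combinations(names, 2):
        out[f"{a}&{b}"] = len(deg_sets[a] & deg_sets[b])
    if len(names) == 2:
        a, b = names
        out[f"only:{a}"] = len(deg_sets[a] - deg_sets[b])
        out[f"only:{b}"] = len(deg_sets[b] - deg_sets[a])
    elif len(names) == 3:
        a, b, c = names
        inter_all = deg_sets[a] & deg_sets[b] & deg_sets[c]
        out[f"{a}&{b}&{c}"] = len(inter_all)
        out[f"only:{a}"] = len(deg_sets[a] - deg_sets[b] - deg_sets[c])
        out[f"only:{b}"] = len(deg_sets[b] - deg_sets[a] - deg_sets[c])
        out[f"only:{c}"] = len(deg_sets[c] - deg_sets[a] - deg_sets[b])
        out[f"only:{a}&{b}"] = len((deg_sets[a] & deg_sets[b]) - inter_all)
        out[f"only:{a}&{c}"] = len((deg_sets[a] & deg_sets[c]) - inter_all)
        out[f"only:{b}&{c}"] = len((deg_sets[b] & deg_sets[c]) - inter_all)
    else:
        raise ValueError("venn_counts supports 2 or 3 sets")
    return out


def fisher_enrichment(
    list_hits: int, list_size: int, pop_hits: int, pop_size: int
) -> float:
    """Plain one-tailed (enrichment) Fisher exact p-value, P(X >= list_hits)."""
    _check_table(list_hits, list_size, pop_hits, pop_size)
    return float(stats.hypergeom.sf(list_hits - 1, pop_size, pop_hits, list_size))


def ease_score(list_hits: int, list_size: int, pop_hits: int, pop_size: int) -> float:
    """EASE statistic: one-tailed Fisher p-value after removing one hit.

    The hit count is penalized to ``list_hits - 1`` (floored at 0, so 0 or 1
    hits give p = 1 exactly), making single-gene overlaps never significant.
    """
    _check_table(list_hits, list_size, pop_hits, pop_size)
    k = max(list_hits - 1, 0)
    return float(stats.hypergeom.sf(k - 1, pop_size, pop_hits, list_size))


def _check_table(list_hits: int, list_size: int, pop_hits: int, pop_size: int) -> None:
    ok = (
        0 <= list_hits <= list_size <= pop_size
        and list_hits <= pop_hits <= pop_size
        and list_size - list_hits <= pop_size - pop_hits
    )
    if not ok:
        raise ValueError(
            f"impossible 2x2 table: ({list_hits}, {list_size}, {pop_hits}, {pop_size})"
        )


def enrichment_score(ease_pvalues: Iterable[float]) -> float:
    """Cluster enrichment score: -log10 of the geometric mean of EASE p-values."""
    p = np.asarray(list(ease_pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.mean(np.log10(p)))
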