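"""Cross-method agreement of taxonomic assignments.

Given K methods' calls for each read, each call is projected to a canonical
rank and the read is placed in exactly one agreement class at that rank:

* ``ALL_SAME`` — every method projects to the same ranked taxon;
* ``NO_RANK`` — every method projects to the no-rank sentinel (the lineage
  genuinely lacks that rank, e.g. viruses at phylum);
* ``CONFUSED`` — at genus, the disagreeing pair between two designated
  composition-based methods belongs to a configured set of genus pairs
  those methods systematically swap;
* ``TWO_SAME`` — at least two (but not all) methods project to the same
  ranked taxon;
* ``UNASSIGNED_MAJORITY`` — more than half the methods made no call
  (consensus on absence is not an assignment);
* ``ALL_DIFFERENT`` — anything else.

Precedence is the order listed above except that UNASSIGNED_MAJORITY is
checked first.  Agreement on UNASSIGNED or on NO_RANK never produces
TWO_SAME/ALL_SAME: consensus requires an actual ranked taxon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .assign import UNASSIGNED
from .taxonomy import CANONICAL_RANKS, NO_RANK, TaxonomyTree

__all__ = [
    "AGREEMENT_CLASSES",
    "AgreementRecord",
    "ConfusedGenera",
    "classify_agreement",
    "consensus_assign",
    "agreement_table",
    "cross_tab_disagreements",
    "project_call",
]

AGREEMENT_CLASSES = (
    "ALL_SAME",
    "TWO_SAME",
    "ALL_DIFFERENT",
    "NO_RANK",
    "CONFUSED",
    "UNASSIGNED_MAJORITY",
)


@dataclass(frozen=True)
class ConfusedGenera:
    """Genus pairs systematically interchanged between two named methods."""

    method_a: str = ""
    method_b: str = ""
    pairs: frozenset = field(default_factory=frozenset)  # of frozenset({g1, g2})

    @classmethod
    def from_pairs(cls, method_a: str, method_b: str,
                   pairs: Iterable[tuple[str, str]]) -> "ConfusedGenera":
        return cls(method_a, method_b,
                   frozenset(frozenset(p) for p in pairs))

    def matches(self, taxon_a: str, taxon_b: str) -> bool:
        return frozenset((taxon_a, taxon_b)) in self.pairs


@dataclass
class AgreementRecord:
    read_id: str
    rank: str
    agreement_class: str
    agreeing_pair: tuple[str, str] | None = None
    consensus_taxon: str | None = None


def project_call(tree: TaxonomyTree, taxon: str, rank: str) -> str:
    """Project a call to a rank; UNASSIGNED stays UNASSIGNED."""
    if taxon == UNASSIGNED:
        return UNASSIGNED
    return tree.project_to_rank(taxon, rank)


def classify_agreement(calls: Mapping[str, str],
                       tree: TaxonomyTree,
                       rank: str,
                       confused: ConfusedGenera | None = None,
                       read_id: str = "") -> AgreementRecord:
    """Place one read's per-method calls in an agreement class at `rank`.

    `calls` maps method_id -> taxon_id or UNASSIGNED (raw calls; projection
    to `rank` happens here).  At least two methods are required.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if len(calls) < 2:
        raise ValueError("agreement needs at least two methods")
    projected = {m: project_call(tree, t, rank) for m, t in calls.items()}
    k = len(projected)
    values = list(projected.values())

    n_unassigned = sum(v == UNASSIGNED for v in values)
    if n_unassigned * 2 > k:
        return AgreementRecord(read_id, rank, "UNASSIGNED_MAJORITY")

    ranked = Counter(v for v in values if v not in (UNASSIGNED, NO_RANK))
    if ranked and len(ranked) == 1 and next(iter(ranked.values())) == k:
        taxon = next(iter(ranked))
        return AgreementRecord(read_id, rank, "ALL_SAME", consensus_taxon=taxon)
    if all(v == NO_RANK for v in values):
        return AgreementRecord(read_id, rank, "NO_RANK")

    if (confused is not None and rank == "genus"
            and confused.method_a in projected and confused.method_b in projected):
        a = projected[confused.method_a]
        b = projected[confused.method_b]
        if a != b and a not in (UNASSIGNED, NO_RANK) and b not in (UNASSIGNED, NO_RANK) \
                and confused.matches(a, b):
            return AgreementRecord(read_id, rank, "CONFUSED")

    shared = [t for t, c in ranked.items() if c >= 2]
    if shared:
        taxon = max(shared, key=lambda t: (ranked[t], t))
        pair = tuple(sorted(m for m, v in projected.items() if v == taxon))[:2]
        return AgreementRecord(read_id, rank, "TWO_SAME",
                               agreeing_pair=(pair[0], pair[1]),
                               consensus_taxon=taxon)
    return AgreementRecord(read_id, rank, "ALL_DIFFERENT")


def consensus_assign(calls: Mapping[str, str],
                     tree: TaxonomyTree,
                     rank: str) -> str | None:
    """The ranked taxon >= 2 methods converge on after projection, else None.

    UNASSIGNED and NO_RANK never form a consensus.
    """
    if len(calls) < 2:
        raise ValueError("consensus needs at least two methods")
    projected = [project_call(tree, t, rank) for t in calls.values()]
    counts = Counter(v for v in projected if v not in (UNASSIGNED, NO_RANK))
    best = [t for t, c in counts.items() if c >= 2]
    if not best:
        return None
    return max(best, key=lambda t: (counts[t], t))


def _calls_by_read(frame: pd.DataFrame,
                   methods: list[str] | None = None) -> tuple[list[str], dict[str, dict[str, str]]]:
    methods = methods or sorted(frame["method_id"].unique())
    pivot = frame.pivot_table(index="read_id", columns="method_id",
                              values="taxon_id", aggfunc="first")
    pivot = pivot.reindex(columns=methods).fillna(UNASSIGNED)
    return methods, {rid: row.to_dict() for rid, row in pivot.iterrows()}


def agreement_table(frame: pd.DataFrame,
                    tree: TaxonomyTree,
                    ranks: Iterable[str] = CANONICAL_RANKS,
                    confused: ConfusedGenera | None = None,
                    methods: list[str] | None = None) -> pd.DataFrame:
    """Long-format counts per rank x agreement class over all reads.

    A read absent for some method counts as UNASSIGNED for it, so per-rank
    counts always sum to the total number of reads.
    """
    _, calls = _calls_by_read(frame, methods)
    rows = []
    for rank in ranks:
        counts = Counter(
            classify_agreement(c, tree, rank, confused, read_id=rid).agreement_class
            for rid, c in calls.items()
        )
        for cls in AGREEMENT_CLASSES:
            rows.append((rank, cls, counts.get(cls, 0)))
    return pd.DataFrame(rows, columns=["rank", "agreement_class", "count"])


def cross_tab_disagreements(frame: pd.DataFrame,
                            method_a: str,
                            method_b: str,
                            rank: str,
                            tree: TaxonomyTree,
                            top_n: int | None = 10) -> pd.DataFrame:
    """Ranked cross-tabulation of two methods' disagreeing projections.

    Among reads where both methods project to ranked taxa that differ,
    the percentage of each ordered (taxon_a, taxon_b) pair, descending.
    """
    _, calls = _calls_by_read(frame, [method_a, method_b])
    pairs = Counter()
    for c in calls.values():
        a = project_call(tree, c[method_a], rank)
        b = project_call(tree, c[method_b], rank)
        if a in (UNASSIGNED, NO_RANK) or b in (UNASSIGNED, NO_RANK) or a == b:
            continue
        pairs[(a, b)] += 1
    total = sum(pairs.values())
    rows = [
        (a, b, 100.0 * n / total)
        for (a, b), n in sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "percent"])
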