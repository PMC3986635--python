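"""Independent brute-force oracles shared across tests.

Everything here is written against the documented semantics, not against
the package internals: lineages and LCAs are computed by explicit path
walks, and agreement classification by a direct cascade of ifs over
projected labels.
"""

from __future__ import annotations

import numpy as np

from metaconsist.assign import UNASSIGNED
from metaconsist.taxonomy import (CANONICAL_RANKS, NO_RANK, TaxonNode,
                                  TaxonomyTree)

_ALIASES = {r: r for r in CANONICAL_RANKS}
_ALIASES["superkingdom"] = "domain"


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """A random rooted taxonomy whose rank labels are depth-consistent
    (a node's canonical rank is always deeper than any ranked ancestor's).
    """
    nodes = [TaxonNode("n0", "n0", "no rank", "root")]
    deepest_rank = {0: -1}  # node index -> index of deepest canonical rank above
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        floor = deepest_rank[parent]
        if floor < len(CANONICAL_RANKS) - 1 and rng.random() < 0.7:
            rank_idx = int(rng.integers(floor + 1, len(CANONICAL_RANKS)))
            rank = CANONICAL_RANKS[rank_idx]
        else:
            rank_idx = floor
            rank = "no rank"
        deepest_rank[i] = rank_idx
        nodes.append(TaxonNode(f"n{i}", f"n{parent}", rank, f"name{i}"))
    return TaxonomyTree(nodes)


def brute_path(tree: TaxonomyTree, taxon_id: str) -> list[str]:
    path = [taxon_id]
    while path[-1] != tree.root_id:
        path.append(tree.node(path[-1]).parent_id)
    return path


def brute_lineage_at(tree: TaxonomyTree, taxon_id: str, rank: str) -> str:
    """First ancestor-or-self whose rank label maps to `rank`."""
    for tid in brute_path(tree, taxon_id):
        if _ALIASES.get(tree.node(tid).rank) == rank:
            return tid
    return NO_RANK


def brute_lca(tree: TaxonomyTree, taxon_ids) -> str:
    """Deepest element of the intersection of root-paths, found by scanning
    root-to-leaf along the first taxon's path."""
    paths = [list(reversed(brute_path(tree, t))) for t in taxon_ids]
    common = paths[0]
    for p in paths[1:]:
        members = set(p)
        common = [t for t in common if t in members]
    return common[-1]


def brute_classify(projections: dict[str, str],
                   confused_pairs: set[frozenset] = frozenset(),
                   method_a: str = "", method_b: str = "",
                   at_genus: bool = False) -> str:
    """Direct cascade over already-projected labels."""
    values = list(projections.values())
    k = len(values)
    if sum(v == UNASSIGNED for v in values) * 2 > k:
        return "UNASSIGNED_MAJORITY"
    ranked = [v for v in values if v not in (UNASSIGNED, NO_RANK)]
    if len(ranked) == k and len(set(ranked)) == 1:
        return "ALL_SAME"
    if all(v == NO_RANK for v in values):
        return "NO_RANK"
    if at_genus and method_a in projections and method_b in projections:
        a, b = projections[method_a], projections[method_b]
        if (a != b and a not in (UNASSIGNED, NO_RANK)
                and b not in (UNASSIGNED, NO_RANK)
                and frozenset((a, b)) in confused_pairs):
            return "CONFUSED"
    for v in set(ranked):
        if ranked.count(v) >= 2:
            return "TWO_SAME"
    return "ALL_DIFFERENT"
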