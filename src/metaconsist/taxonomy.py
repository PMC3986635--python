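"""Rooted, ranked taxonomies: loading, canonical-rank lineages and LCAs.

A taxonomy is a rooted tree of named nodes, each carrying a free-text rank
label ("superkingdom", "phylum", ..., "no rank").  Downstream comparisons
always happen on the seven canonical ranks (domain, phylum, class, order,
family, genus, species).  A lineage that genuinely lacks one of those ranks
— e.g. viruses, which have no phylum — yields the :data:`NO_RANK` sentinel
at that rank; this is distinct from a read being unassigned.

Two on-disk dialects are supported: the NCBI taxonomy dump (``nodes.dmp`` /
``names.dmp``, pipe-tab delimited) and a simple 4-column TSV
(taxon_id, parent_id, rank, name) convenient for fixtures.  Taxon
identifiers are opaque strings throughout, so non-NCBI taxonomies work
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

__all__ = [
    "CANONICAL_RANKS",
    "NO_RANK",
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "MalformedTaxonomyError",
    "MissingNodeError",
    "load_taxonomy",
    "load_taxonomy_table",
    "lineage",
    "lca",
    "project_to_rank",
]

#: The seven comparison levels, shallowest first.
CANONICAL_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel for "this lineage has no node at that canonical rank".
NO_RANK = "NO_RANK"

# NCBI calls the deepest-level-above-everything "superkingdom"; we map it to
# the canonical "domain".  Viruses/Bacteria/Archaea are all domain outcomes.
_RANK_ALIASES: dict[str, str] = {rank: rank for rank in CANONICAL_RANKS}
_RANK_ALIASES["superkingdom"] = "domain"


class TaxonomyError(Exception):
    """Base class for taxonomy problems."""


class MalformedTaxonomyError(TaxonomyError):
    """The node set does not form a single rooted tree (cycle, no/two roots)."""


class MissingNodeError(TaxonomyError):
    """A parent_id or looked-up taxon_id is absent from the taxonomy."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identifier, parent, free-text rank label and name."""

    taxon_id: str
    parent_id: str
    rank: str
    name: str = ""

    @property
    def canonical_rank(self) -> str | None:
        """The canonical rank this node sits at, or None."""
        return _RANK_ALIASES.get(self.rank)


class TaxonomyTree:
    """A validated rooted taxonomy with rank projection and LCA queries.

    Construction verifies the tree invariants: exactly one root (a node
    whose parent is itself or empty), every parent_id resolvable, and no
    cycles.  Per-node depths are cached for LCA queries.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise MalformedTaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise MalformedTaxonomyError("empty taxonomy")

        roots = [
            n.taxon_id
            for n in self._nodes.values()
            if n.parent_id in ("", n.taxon_id)
        ]
        if len(roots) != 1:
            raise MalformedTaxonomyError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        self.root_id: str = roots[0]

        for node in self._nodes.values():
            if node.taxon_id != self.root_id and node.parent_id not in self._nodes:
                raise MissingNodeError(
                    f"node {node.taxon_id!r} has unknown parent {node.parent_id!r}"
                )

        # Depth computation doubles as cycle detection: every node must
        # reach the root without revisiting itself.
        self._depth: dict[str, int] = {self.root_id: 0}
        for tid in self._nodes:
            self._resolve_depth(tid)

        self._name_index: dict[str, str] = {}
        for node in self._nodes.values():
            if node.name:
                self._name_index.setdefault(node.name, node.taxon_id)

        self._lineage_cache: dict[str, dict[str, str]] = {}

    def _resolve_depth(self, taxon_id: str) -> int:
        chain: list[str] = []
        tid = taxon_id
        while tid not in self._depth:
            if tid in chain:
                raise MalformedTaxonomyError(f"cycle detected at taxon {tid!r}")
            chain.append(tid)
            tid = self._nodes[tid].parent_id
        depth = self._depth[tid]
        for t in reversed(chain):
            depth += 1
            self._depth[t] = depth
        return self._depth[taxon_id]

    # -- basic queries ------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise MissingNodeError(f"unknown taxon_id {taxon_id!r}") from None

    def depth(self, taxon_id: str) -> int:
        if taxon_id not in self._nodes:
            raise MissingNodeError(f"unknown taxon_id {taxon_id!r}")
        return self._depth[taxon_id]

    def name_to_id(self, name: str) -> str | None:
        """Resolve a scientific name to a taxon id (None if unknown)."""
        return self._name_index.get(name)

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Taxon ids from the node up to and including the root."""
        node = self.node(taxon_id)
        path = [node.taxon_id]
        while node.taxon_id != self.root_id:
            node = self._nodes[node.parent_id]
            path.append(node.taxon_id)
        return path

    def is_ancestor(self, ancestor_id: str, taxon_id: str) -> bool:
        """True when `ancestor_id` is an ancestor-or-self of `taxon_id`."""
        return ancestor_id in self.path_to_root(taxon_id)

    # -- rank projection ----------------------------------------------

    def lineage(self, taxon_id: str) -> dict[str, str]:
        """Project a taxon onto the seven canonical ranks.

        Each rank is filled with the nearest ancestor-or-self carrying that
        rank label; ranks with no such ancestor get :data:`NO_RANK`.
        Projection only climbs upward: a taxon above the requested rank has
        no say about its descendants, so e.g. a domain-level taxon projects
        to NO_RANK at species.
        """
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return dict(cached)
        result = {rank: NO_RANK for rank in CANONICAL_RANKS}
        for tid in self.path_to_root(taxon_id):
            canon = self._nodes[tid].canonical_rank
            if canon is not None and result[canon] == NO_RANK:
                result[canon] = tid
        self._lineage_cache[taxon_id] = dict(result)
        return result

    def project_to_rank(self, taxon_id: str, rank: str) -> str:
        """The taxon's ancestor-or-self at `rank`, or NO_RANK."""
        if rank not in CANONICAL_RANKS:
            raise ValueError(
                f"unknown rank {rank!r}; expected one of {CANONICAL_RANKS}"
            )
        return self.lineage(taxon_id)[rank]

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input taxon."""
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        common: set[str] = set(self.path_to_root(ids[0]))
        for tid in ids[1:]:
            common &= set(self.path_to_root(tid))
        return max(common, key=lambda t: self._depth[t])

    # -- serialization ------------------------------------------------

    def to_table(self) -> str:
        """Serialize as the 4-column TSV fixture dialect."""
        lines = ["#taxon_id\tparent_id\trank\tname"]
        for node in self._nodes.values():
            lines.append(
                f"{node.taxon_id}\t{node.parent_id}\t{node.rank}\t{node.name}"
            )
        return "\n".join(lines) + "\n"


def _split_dump_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_taxonomy(nodes_stream: IO[str] | Iterable[str],
                  names_stream: IO[str] | Iterable[str] | None = None) -> TaxonomyTree:
    """Load a taxonomy in the NCBI dump dialect.

    Parameters
    ----------
    nodes_stream:
        Lines of ``nodes.dmp``: ``tax_id | parent | rank | ...`` with
        fields separated by ``"\\t|\\t"`` and records ending ``"\\t|"``.
    names_stream:
        Lines of ``names.dmp``; only rows whose name class is
        ``"scientific name"`` are used.  Optional.
    """
    names: dict[str, str] = {}
    if names_stream is not None:
        for line in names_stream:
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            if len(fields) >= 4 and fields[3].strip() == "scientific name":
                names[fields[0].strip()] = fields[1].strip()

    nodes: list[TaxonNode] = []
    for line in nodes_stream:
        if not line.strip():
            continue
        fields = _split_dump_line(line)
        if len(fields) < 3:
            raise MalformedTaxonomyError(
                f"nodes record has {len(fields)} fields, expected >= 3: {line!r}"
            )
        tid, parent, rank = (f.strip() for f in fields[:3])
        nodes.append(TaxonNode(tid, parent, rank, names.get(tid, "")))
    return TaxonomyTree(nodes)


def load_taxonomy_table(stream: IO[str] | Iterable[str]) -> TaxonomyTree:
    """Load the simple 4-column TSV dialect (taxon_id, parent_id, rank, name)."""
    nodes: list[TaxonNode] = []
    for i, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MalformedTaxonomyError(
                f"line {i}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        name = fields[3] if len(fields) > 3 else ""
        nodes.append(TaxonNode(fields[0], fields[1], fields[2], name))
    return TaxonomyTree(nodes)


# Thin functional facade mirroring the tree methods.

def lineage(tree: TaxonomyTree, taxon_id: str) -> dict[str, str]:
    return tree.lineage(taxon_id)


def lca(tree: TaxonomyTree, taxon_ids: Iterable[str]) -> str:
    return tree.lca(taxon_ids)


def project_to_rank(tree: TaxonomyTree, taxon_id: str, rank: str) -> str:
    return tree.project_to_rank(taxon_id, rank)
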