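"""Per-read taxonomic assignment.

Three routes produce assignments:

* similarity: BLAST tabular hits filtered at an e-value cutoff (default
  1e-5) and collapsed to the lowest common ancestor of the hit taxa;
* composition: a naive Bayes k-mer classifier trained on reference genomes
  (canonical, strand-collapsed k-mers with add-one smoothing), including a
  posterior retention cutoff (the "ε value": ε = 0 retains everything,
  larger ε retains fewer reads) and a BLAST-restricted combination in which
  the classifier may only choose among genomes with a surviving hit;
* adapters: tables emitted by external classifiers are ingested as-is.

Assignments are plain records (read, method, taxon-or-UNASSIGNED, score);
consistency and metrics modules consume them as a pandas DataFrame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

__all__ = [
    "UNASSIGNED",
    "BlastHit",
    "Assignment",
    "EpsilonConfig",
    "NBCModel",
    "BlastParseError",
    "TrainingError",
    "IngestError",
    "read_blast_tabular",
    "write_blast_tabular",
    "lca_assign",
    "train_nbc",
    "nbc_classify",
    "apply_epsilon_cutoff",
    "combine_blast_nbc",
    "ingest_external_assignments",
    "assignments_to_frame",
    "write_assignments",
    "read_assignments",
    "DEFAULT_E_CUTOFF",
]

logger = logging.getLogger(__name__)

#: Sentinel for "this method made no assignment for this read".
UNASSIGNED = "UNASSIGNED"

#: e-value cutoff used when collapsing similarity hits to an LCA.
DEFAULT_E_CUTOFF = 1e-5

_BLAST_FIELDS = ("query_id", "subject_id", "percent_identity", "alignment_length",
                 "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
                 "e_value", "bit_score")


class BlastParseError(ValueError):
    """A tabular hit line could not be parsed (message names the line)."""


class TrainingError(ValueError):
    """Classifier training inputs are inconsistent."""


class IngestError(ValueError):
    """An external assignment table is malformed."""


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular output (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def to_line(self) -> str:
        return "\t".join(str(getattr(self, f)) for f in _BLAST_FIELDS)


@dataclass
class Assignment:
    """One method's call for one read."""

    read_id: str
    method_id: str
    taxon_id: str = UNASSIGNED
    score: float | None = None
    read_length: int | None = None
    log_likelihoods: dict[str, float] | None = None
    note: str = ""

    @property
    def is_assigned(self) -> bool:
        return self.taxon_id != UNASSIGNED


@dataclass(frozen=True)
class EpsilonConfig:
    """Posterior retention cutoff for the Bayes classifier.

    ε = 0 retains every assignment; ε = 1 retains only reads whose softmax
    posterior concentrates entirely on one genome; larger ε always retains
    a subset of what smaller ε retains.
    """

    epsilon: float = 0.0
    mode: str = "nbc_only"  # or "lca_plus_nbc"

    def __post_init__(self):
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.mode not in ("nbc_only", "lca_plus_nbc"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# BLAST tabular I/O and LCA collapsing


def read_blast_tabular(stream: IO[str] | Iterable[str]) -> list[BlastHit]:
    """Parse 12-column tab-separated hits; errors name the offending line."""
    hits = []
    for i, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise BlastParseError(
                f"line {i}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(BlastHit(
                fields[0], fields[1], float(fields[2]), int(fields[3]),
                int(fields[4]), int(fields[5]), int(fields[6]), int(fields[7]),
                int(fields[8]), int(fields[9]), float(fields[10]), float(fields[11]),
            ))
        except ValueError as exc:
            raise BlastParseError(f"line {i}: {exc}") from None
    return hits


def write_blast_tabular(hits: Iterable[BlastHit]) -> str:
    return "".join(h.to_line() + "\n" for h in hits)


def lca_assign(hits_for_query: list[BlastHit],
               subject_taxa: Mapping[str, str],
               tree: TaxonomyTree,
               e_cutoff: float = DEFAULT_E_CUTOFF,
               method_id: str = "lca",
               read_id: str | None = None) -> Assignment:
    """Collapse one read's hits to the LCA of their taxa.

    Hits with e_value <= e_cutoff survive; subjects with no taxon mapping
    are dropped with a warning; no survivors means UNASSIGNED.  The score
    is the best surviving bit score.
    """
    if e_cutoff <= 0:
        raise ValueError(f"e_cutoff must be > 0, got {e_cutoff}")
    if read_id is None:
        read_id = hits_for_query[0].query_id if hits_for_query else ""
    taxa, best_bits = [], None
    for hit in hits_for_query:
        if hit.e_value > e_cutoff:
            continue
        taxon = subject_taxa.get(hit.subject_id)
        if taxon is None:
            logger.warning("subject %s has no taxon mapping; hit dropped",
                           hit.subject_id)
            continue
        taxa.append(taxon)
        best_bits = hit.bit_score if best_bits is None else max(best_bits, hit.bit_score)
    if not taxa:
        return Assignment(read_id, method_id)
    return Assignment(read_id, method_id, tree.lca(taxa), score=best_bits)


# ---------------------------------------------------------------------------
# naive Bayes k-mer classifier


def _canonical_map(k: int) -> np.ndarray:
    """Map every k-mer code to the smaller of itself and its revcomp code."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return np.minimum(codes, rc)


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonicalize k-mer codes without a 4^k lookup table."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return np.minimum(codes, rc)


def _kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Codes of all valid (ACGT-only) k-mers of a sequence."""
    codes = _BASE_CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = codes[i:i + n]
        valid &= window >= 0
        out = out * 4 + np.where(window >= 0, window, 0)
    return out[valid]


@dataclass
class NBCModel:
    """Per-genome log-frequency tables over the canonical k-mer space."""

    k: int
    genome_ids: list[str]
    taxon_map: dict[str, str]
    log_probs: np.ndarray  # (n_genomes, 4^k), mass on canonical slots
    canon: np.ndarray = field(repr=False, default=None)  # code -> canonical code

    def __post_init__(self):
        if self.canon is None:
            self.canon = _canonical_map(self.k)

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "genome_ids": self.genome_ids,
            "taxon_map": self.taxon_map,
            "log_probs": self.log_probs.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "NBCModel":
        d = json.loads(text)
        return cls(d["k"], d["genome_ids"], d["taxon_map"],
                   np.asarray(d["log_probs"], dtype=float))


def train_nbc(genomes: Iterable[tuple[str, str]],
              genome_to_taxon: Mapping[str, str],
              k: int = 8) -> NBCModel:
    """Train per-genome canonical k-mer frequency tables.

    All overlapping k-mers are counted with both strands collapsed onto the
    canonical (lexicographically smaller) code, add-one smoothed over the
    canonical slot set, and log-normalized.
    """
    if not (4 <= k <= 12):
        raise TrainingError(f"k must lie in [4, 12], got {k}")
    records = list(genomes)
    missing = [g for g, _ in records if g not in genome_to_taxon]
    if missing:
        raise TrainingError(f"genomes without a taxon mapping: {missing}")
    short = [g for g, s in records if len(s) <= k]
    if short:
        raise TrainingError(f"genomes shorter than k={k}: {short}")

    canon = _canonical_map(k)
    canonical_slots = np.flatnonzero(canon == np.arange(4 ** k))
    # non-canonical slots never receive counts (reads are canonicalized the
    # same way), so zeros there are inert in the dot product
    log_probs = np.zeros((len(records), 4 ** k))
    for row, (gid, seq) in enumerate(records):
        counts = np.bincount(canon[_kmer_codes(seq, k)], minlength=4 ** k).astype(float)
        counts[canonical_slots] += 1.0  # add-one smoothing on canonical slots
        log_probs[row, canonical_slots] = np.log(
            counts[canonical_slots] / counts[canonical_slots].sum()
        )
    return NBCModel(k, [g for g, _ in records],
                    {g: genome_to_taxon[g] for g, _ in records}, log_probs, canon)


def nbc_classify(model: NBCModel, read_id: str, read_sequence: str,
                 method_id: str = "nbc") -> Assignment:
    """Score a read against every trained genome and take the argmax taxon.

    score_g = Σ over read k-mers of log p(kmer | g); reads shorter than k
    are UNASSIGNED with a note; argmax ties break lexicographically on
    genome_id (logged).
    """
    codes = _kmer_codes(read_sequence, model.k)
    if len(codes) == 0:
        return Assignment(read_id, method_id, read_length=len(read_sequence),
                          note="read shorter than k")
    counts = np.bincount(model.canon[codes], minlength=4 ** model.k).astype(float)
    scores = model.log_probs @ counts
    best = float(scores.max())
    tied = [model.genome_ids[i] for i in np.flatnonzero(scores >= best - 1e-12)]
    if len(tied) > 1:
        logger.info("read %s: %d-way tie, keeping %s", read_id, len(tied), min(tied))
    winner = min(tied)
    return Assignment(
        read_id, method_id, model.taxon_map[winner], score=best,
        read_length=len(read_sequence),
        log_likelihoods={g: float(s) for g, s in zip(model.genome_ids, scores)},
    )


def _best_posterior(log_likelihoods: Mapping[str, float]) -> float:
    ll = np.array(list(log_likelihoods.values()), dtype=float)
    ll -= ll.max()
    post = np.exp(ll)
    return float(post.max() / post.sum())


def apply_epsilon_cutoff(assignment: Assignment,
                         eps_config: EpsilonConfig) -> Assignment:
    """Drop an assignment whose softmax posterior falls below ε.

    Retained iff posterior of the best genome >= ε; ε = 0 therefore retains
    everything, ε = 1 only posterior-1 reads, and the retained set shrinks
    monotonically as ε grows.
    """
    if not assignment.is_assigned:
        return assignment
    if assignment.log_likelihoods is None:
        raise ValueError("epsilon cutoff needs the per-genome log-likelihood vector")
    if eps_config.epsilon == 0.0:
        return assignment
    if _best_posterior(assignment.log_likelihoods) >= eps_config.epsilon:
        return assignment
    return Assignment(assignment.read_id, assignment.method_id,
                      read_length=assignment.read_length,
                      note=f"below epsilon {eps_config.epsilon:g}")


def combine_blast_nbc(model: NBCModel,
                      read_id: str,
                      read_sequence: str,
                      hits_for_query: list[BlastHit],
                      subject_genomes: Mapping[str, str],
                      e_cutoff: float = DEFAULT_E_CUTOFF,
                      method_id: str = "nbc_blast") -> Assignment:
    """Bayes classification restricted to genomes with a surviving hit.

    The candidate set is the genomes named by hits with e_value <= e_cutoff;
    the classifier takes its argmax over that set only.  A read with no
    surviving hits (e.g. a contaminant absent from the reference set) is
    never assigned.
    """
    candidates = sorted({
        subject_genomes[h.subject_id]
        for h in hits_for_query
        if h.e_value <= e_cutoff and h.subject_id in subject_genomes
        and subject_genomes[h.subject_id] in model.taxon_map
    })
    if not candidates:
        return Assignment(read_id, method_id, read_length=len(read_sequence),
                          note="no surviving similarity hits")
    full = nbc_classify(model, read_id, read_sequence, method_id=method_id)
    if full.log_likelihoods is None:
        return Assignment(read_id, method_id, read_length=len(read_sequence),
                          note=full.note)
    restricted = {g: full.log_likelihoods[g] for g in candidates}
    winner = min(g for g in restricted if restricted[g] >= max(restricted.values()) - 1e-12)
    return Assignment(read_id, method_id, model.taxon_map[winner],
                      score=restricted[winner], read_length=len(read_sequence),
                      log_likelihoods=restricted)


# ---------------------------------------------------------------------------
# adapters & table I/O


def ingest_external_assignments(stream: IO[str] | Iterable[str],
                                method_id: str,
                                tree: TaxonomyTree | None = None) -> list[Assignment]:
    """Ingest an external classifier's TSV: read_id, taxon id or name,
    optional score, optional length.

    Names not present in the taxonomy resolve to UNASSIGNED with a warning;
    a duplicate read_id within the table is an error.
    """
    assignments: list[Assignment] = []
    seen: set[str] = set()
    for i, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise IngestError(f"line {i}: expected >= 2 columns")
        read_id, taxon = fields[0], fields[1]
        if read_id in seen:
            raise IngestError(f"line {i}: duplicate read_id {read_id!r}")
        seen.add(read_id)
        score = float(fields[2]) if len(fields) > 2 and fields[2] not in ("", "NA") else None
        length = int(fields[3]) if len(fields) > 3 and fields[3] not in ("", "NA") else None
        if taxon != UNASSIGNED and tree is not None and taxon not in tree:
            resolved = tree.name_to_id(taxon)
            if resolved is None:
                logger.warning("line %d: unresolvable taxon %r -> UNASSIGNED", i, taxon)
                taxon = UNASSIGNED
            else:
                taxon = resolved
        assignments.append(Assignment(read_id, method_id, taxon, score, length))
    return assignments


def assignments_to_frame(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Long-format table: read_id, method_id, taxon_id, score, read_length."""
    return pd.DataFrame(
        [(a.read_id, a.method_id, a.taxon_id, a.score, a.read_length)
         for a in assignments],
        columns=["read_id", "method_id", "taxon_id", "score", "read_length"],
    )


def write_assignments(frame: pd.DataFrame) -> str:
    out = frame.copy()
    return out.to_csv(sep="\t", index=False, na_rep="NA")


def read_assignments(stream: IO[str]) -> pd.DataFrame:
    frame = pd.read_csv(stream, sep="\t", na_values=["NA"],
                        dtype={"read_id": str, "method_id": str, "taxon_id": str})
    required = {"read_id", "method_id", "taxon_id"}
    missing = required - set(frame.columns)
    if missing:
        raise IngestError(f"assignment table missing columns: {sorted(missing)}")
    return frame
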