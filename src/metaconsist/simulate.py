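"""Diversity-driven metagenome read simulation.

The simulator designs a mock community from a target Shannon diversity H'
(nats) and a dominance cap (the maximum relative abundance any one species
may take, e.g. 5% vs 80% scenarios), fits the expected rarefaction curve
through three anchor points, fragments the chosen genomes into 350-600 bp
reads, and injects pyrosequencing-style errors (point substitutions plus
homopolymer-run length changes).  Every read is emitted together with its
ground truth (source genome/taxon, coordinates, strand, injected-error
counts), which downstream sensitivity/precision evaluation consumes.

Community design uses a geometric rank-abundance series p_i ∝ θ^i whose
single parameter θ is solved by bisection so that the realized entropy
−Σ p_i ln p_i hits H' to within 1e-3 nats; abundances above the dominance
cap are truncated with the excess redistributed proportionally, and θ is
solved against the *capped* entropy so the cap never drags the realized
H' off target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .taxonomy import CANONICAL_RANKS

__all__ = [
    "SimulationConfig",
    "CommunityProfile",
    "RarefactionCurve",
    "SimulatedRead",
    "SCENARIOS",
    "ConfigurationError",
    "GenomeTooShortError",
    "design_community",
    "fit_rarefaction",
    "sample_fragments",
    "apply_error_model",
    "simulate_reads",
    "simulate_metagenome",
    "diverge_genome",
    "make_mock_genomes",
    "shannon_entropy",
    "reverse_complement",
    "TRUTH_HEADER",
]

TRUTH_HEADER = "#coords=0-based-half-open"
_TRUTH_COLUMNS = ("read_id", "genome_id", "taxon_id", "start", "end", "strand", "length")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: The four study scenarios: caps of 5% (non-dominant) and 80% (dominant),
#: 60,000 reads each.  H' targets and genome counts are package defaults
#: (see docs/methods.md); the caps and read counts are the study conditions.
SCENARIOS: dict[str, dict] = {
    "all_genomes": dict(h_target=3.4, max_taxa=40, dominance_cap=0.05, n_reads=60_000),
    "all_genomes_dominant": dict(h_target=1.0, max_taxa=40, dominance_cap=0.80, n_reads=60_000),
    "bacterial_genomes": dict(h_target=3.0, max_taxa=25, dominance_cap=0.05, n_reads=60_000),
    "bacterial_genomes_dominant": dict(h_target=1.0, max_taxa=25, dominance_cap=0.80, n_reads=60_000),
}


class ConfigurationError(ValueError):
    """The requested community is infeasible (H', cap, taxon count)."""


class GenomeTooShortError(ValueError):
    """A genome is shorter than the maximum fragment length."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def shannon_entropy(abundances) -> float:
    """Shannon H' = −Σ p_i ln p_i in nats, ignoring zero entries."""
    p = np.asarray(abundances, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated metagenome.

    `genome_set` lists (genome_id, taxon_id, sequence) triples; rates are
    per-base (substitutions) and per-homopolymer-run-length-unit (indels).
    """

    h_target: float
    n_reads: int
    max_taxa: int
    dominance_cap: float
    fragment_min: int = 350
    fragment_max: int = 600
    substitution_rate: float = 0.001
    homopolymer_rate: float = 0.01
    seed: int = 0
    genome_set: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        errors = []
        if not (0 < self.dominance_cap <= 1):
            errors.append(f"dominance_cap must be in (0, 1], got {self.dominance_cap}")
        if self.fragment_min > self.fragment_max:
            errors.append(
                f"fragment_min ({self.fragment_min}) > fragment_max ({self.fragment_max})"
            )
        if self.max_taxa < 1:
            errors.append(f"max_taxa must be >= 1, got {self.max_taxa}")
        elif self.dominance_cap * self.max_taxa < 1:
            errors.append(
                f"infeasible: dominance_cap*max_taxa = "
                f"{self.dominance_cap * self.max_taxa:.3f} < 1"
            )
        if self.max_taxa >= 1 and self.h_target > math.log(max(self.max_taxa, 1)) + 1e-9:
            errors.append(
                f"infeasible: h_target {self.h_target} > ln(max_taxa) "
                f"= {math.log(self.max_taxa):.4f}"
            )
        if self.h_target < 0:
            errors.append(f"h_target must be >= 0, got {self.h_target}")
        if self.n_reads < 0:
            errors.append(f"n_reads must be >= 0, got {self.n_reads}")
        if errors:
            raise ConfigurationError("; ".join(errors))


@dataclass
class CommunityProfile:
    """Selected genomes with relative abundances hitting the H' target."""

    entries: list[tuple[str, str, float]]  # (genome_id, taxon_id, abundance)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)

    @property
    def genome_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def shannon(self) -> float:
        return shannon_entropy(self.abundances)


@dataclass
class RarefactionCurve:
    """S(n) = a·ln(1 + b·n) fitted through three anchor points."""

    a: float
    b: float
    anchors: list[tuple[float, float]]  # (0,0), (n_linear, s_linear), (n_reads, max_taxa)
    degenerate: bool = False

    def predict(self, n) -> np.ndarray:
        return self.a * np.log1p(self.b * np.asarray(n, dtype=float))


@dataclass
class SimulatedRead:
    """One read plus its ground truth.

    Coordinates are 0-based half-open on the forward strand of the source
    genome; minus-strand reads carry the reverse complement of that slice.
    The pre-error fragment length is ``end - start``; homopolymer edits may
    change the emitted sequence length.
    """

    read_id: str
    sequence: str
    source_genome_id: str
    source_taxon_id: str
    start: int
    end: int
    strand: str
    n_substitutions: int = 0
    n_homopolymer_edits: int = 0

    @property
    def fragment_length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# community design


def _geometric_series(theta: float, s: int) -> np.ndarray:
    if s == 1:
        return np.ones(1)
    if theta >= 1.0:
        return np.full(s, 1.0 / s)
    w = theta ** np.arange(s, dtype=float)
    return w / w.sum()


def _truncate_at_cap(p: np.ndarray, cap: float) -> np.ndarray:
    """Truncate entries at the cap, redistributing excess proportionally.

    Exact water-filling: with weights sorted descending, the capped set is
    a prefix; the smallest prefix size k for which rescaling the remaining
    mass (1 − k·cap) over the tail keeps every tail entry <= cap gives the
    fixed point of "clip and redistribute proportionally".
    """
    if p.max() <= cap:
        return p.copy()
    order = np.argsort(-p)
    w = p[order]
    out = np.empty_like(w)
    for k in range(1, len(w) + 1):
        if k * cap >= 1.0 - 1e-15:
            out[:k] = (1.0 / k)  # cap*k == 1: everything pinned
            out[k:] = 0.0
            break
        tail = w[k:]
        scale = (1.0 - k * cap) / tail.sum()
        if tail[0] * scale <= cap:
            out[:k] = cap
            out[k:] = tail * scale
            break
    result = np.empty_like(p)
    result[order] = out
    return result


def _solve_abundances(s: int, h_target: float, cap: float,
                      tol: float = 1e-9) -> np.ndarray:
    """Bisection on θ of the cap-truncated geometric series to hit H'."""
    if s == 1:
        return np.ones(1)

    def realized(theta: float) -> float:
        return shannon_entropy(_truncate_at_cap(_geometric_series(theta, s), cap))

    lo, hi = 1e-12, 1.0
    h_lo, h_hi = realized(lo), realized(hi)
    if h_target >= h_hi - 1e-12:
        return _truncate_at_cap(_geometric_series(1.0, s), cap)
    if h_target < h_lo - 1e-3:
        raise ConfigurationError(
            f"h_target {h_target:.4f} below the minimum entropy "
            f"{h_lo:.4f} reachable with {s} taxa under cap {cap}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        h_mid = realized(mid)
        if abs(h_mid - h_target) <= tol:
            lo = hi = mid
            break
        if h_mid < h_target:
            lo = mid
        else:
            hi = mid
    p = _truncate_at_cap(_geometric_series(0.5 * (lo + hi), s), cap)
    if abs(shannon_entropy(p) - h_target) > 1e-3:
        raise ConfigurationError(
            f"could not reach H'={h_target:.4f} within 1e-3 nats "
            f"(s={s}, cap={cap}, got {shannon_entropy(p):.4f})"
        )
    return p


def design_community(genomes: list[tuple[str, str]] | list[tuple[str, str, str]],
                     h_target: float,
                     dominance_cap: float,
                     max_taxa: int,
                     seed: int | np.random.Generator = 0) -> CommunityProfile:
    """Pick `max_taxa` genomes at random and give them abundances with
    Shannon entropy `h_target` (nats), none exceeding `dominance_cap`.

    `genomes` is a list of (genome_id, taxon_id[, sequence]) records; at
    least `max_taxa` must be available.
    """
    if max_taxa < 1:
        raise ConfigurationError(f"max_taxa must be >= 1, got {max_taxa}")
    if not (0 < dominance_cap <= 1):
        raise ConfigurationError(f"dominance_cap must be in (0, 1], got {dominance_cap}")
    if dominance_cap * max_taxa < 1:
        raise ConfigurationError(
            f"infeasible: cap*max_taxa = {dominance_cap * max_taxa:.3f} < 1"
        )
    if h_target > math.log(max_taxa) + 1e-9:
        raise ConfigurationError(
            f"infeasible: h_target {h_target} > ln(max_taxa) = "
            f"{math.log(max_taxa):.4f}"
        )
    if len(genomes) < max_taxa:
        raise ConfigurationError(
            f"need >= {max_taxa} candidate genomes, got {len(genomes)}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chosen = rng.choice(len(genomes), size=max_taxa, replace=False)
    p = _solve_abundances(max_taxa, h_target, dominance_cap)
    entries = [
        (genomes[int(g)][0], genomes[int(g)][1], float(p[i]))
        for i, g in enumerate(chosen)
    ]
    return CommunityProfile(entries)


# ---------------------------------------------------------------------------
# rarefaction


def expected_accumulation(abundances, n) -> np.ndarray:
    """Expected number of distinct taxa seen in n reads: Σ 1 − (1 − p_i)^n."""
    p = np.asarray(abundances, dtype=float)[:, None]
    n = np.atleast_1d(np.asarray(n, dtype=float))[None, :]
    return np.sum(1.0 - (1.0 - p) ** n, axis=0)


def fit_rarefaction(n_reads: int, max_taxa: int,
                    profile: CommunityProfile,
                    slope_fraction: float = 1.0 / math.e) -> RarefactionCurve:
    """Fit S(n) = a·ln(1+b·n) through (0,0), the maximum linear point, and
    (n_reads, max_taxa).

    The maximum linear point is the largest read count where the discrete
    accumulation-curve slope E[S](n+1) − E[S](n) is still at least
    `slope_fraction` (default 1/e) of the initial slope.
    """
    if n_reads <= 0 or max_taxa < 1:
        raise ConfigurationError("n_reads must be > 0 and max_taxa >= 1")
    p = profile.abundances
    degenerate = len(p) == 1

    def slope(n: float) -> float:
        return float(np.sum(p * (1.0 - p) ** n))

    s0 = slope(0.0)  # = 1 for a normalized profile
    target = slope_fraction * s0
    lo, hi = 0, n_reads
    if slope(n_reads) >= target:
        n_lin = n_reads
    else:
        while hi - lo > 1:  # slope is decreasing in n
            mid = (lo + hi) // 2
            if slope(mid) >= target:
                lo = mid
            else:
                hi = mid
        n_lin = lo
    s_lin = float(expected_accumulation(p, n_lin)[0])
    anchors = [(0.0, 0.0), (float(n_lin), s_lin), (float(n_reads), float(max_taxa))]

    from scipy.optimize import least_squares

    xs = np.array([a[0] for a in anchors[1:]])
    ys = np.array([a[1] for a in anchors[1:]])

    def residuals(params):
        a, b = params
        return a * np.log1p(b * xs) - ys

    b0 = 1.0 / max(n_lin, 1)
    a0 = max_taxa / max(math.log1p(b0 * n_reads), 1e-9)
    fit = least_squares(residuals, x0=[a0, b0], bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    curve = RarefactionCurve(float(fit.x[0]), float(fit.x[1]), anchors, degenerate)
    if degenerate:
        warnings.warn("single-taxon profile: rarefaction curve is degenerate")
    return curve


# ---------------------------------------------------------------------------
# fragment sampling & error model


def sample_fragments(genome_sequence: str, n: int,
                     fragment_min: int, fragment_max: int,
                     seed: int | np.random.Generator = 0,
                     genome_id: str = "genome",
                     taxon_id: str = "taxon",
                     id_offset: int = 0) -> list[SimulatedRead]:
    """Sample n error-free fragments uniformly from a genome.

    Lengths are uniform on [fragment_min, fragment_max], start positions
    uniform over valid positions, strands Bernoulli(1/2) with minus-strand
    reads reverse-complemented.
    """
    if len(genome_sequence) < fragment_max:
        raise GenomeTooShortError(
            f"genome {genome_id!r} has length {len(genome_sequence)} "
            f"< fragment_max {fragment_max}"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = rng.integers(fragment_min, fragment_max + 1, size=n)
    starts = rng.integers(0, len(genome_sequence) - lengths + 1)
    minus = rng.random(n) < 0.5
    reads = []
    for i in range(n):
        start = int(starts[i])
        end = start + int(lengths[i])
        frag = genome_sequence[start:end]
        strand = "-" if minus[i] else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        reads.append(SimulatedRead(
            read_id=f"read_{id_offset + i:06d}",
            sequence=frag,
            source_genome_id=genome_id,
            source_taxon_id=taxon_id,
            start=start,
            end=end,
            strand=strand,
        ))
    return reads


_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(sequence: str) -> np.ndarray:
    return _BASE_TO_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def _substitute(codes: np.ndarray, rate: float,
                rng: np.random.Generator) -> tuple[np.ndarray, int]:
    if rate <= 0:
        return codes, 0
    mask = (rng.random(len(codes)) < rate) & (codes < 4)
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        # shift by 1..3 mod 4: always lands on one of the 3 other bases
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return codes, n


def _homopolymer_edit(codes: np.ndarray, rate: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, int]:
    if rate <= 0 or len(codes) == 0:
        return codes, 0
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    run_starts = np.concatenate(([0], boundaries))
    run_lengths = np.diff(np.concatenate((run_starts, [len(codes)])))
    eligible = run_lengths >= 2
    p_edit = np.minimum(1.0, rate * run_lengths)
    edit = eligible & (rng.random(len(run_lengths)) < p_edit)
    n_edits = int(edit.sum())
    if n_edits == 0:
        return codes, 0
    delta = np.where(rng.random(len(run_lengths)) < 0.5, -1, 1)
    new_lengths = run_lengths.copy()
    new_lengths[edit] += delta[edit]
    values = codes[run_starts]
    return np.repeat(values, new_lengths), n_edits


def apply_error_model(read: SimulatedRead,
                      substitution_rate: float,
                      homopolymer_rate: float,
                      seed: int | np.random.Generator = 0) -> SimulatedRead:
    """Inject pyrosequencing-style errors into a read.

    Each base is substituted with probability `substitution_rate` (uniform
    over the 3 alternatives); each maximal homopolymer run of length >= 2
    is lengthened or shortened by one base (equal odds) with probability
    min(1, homopolymer_rate * run_length).  Rates of 0 are the identity.
    """
    if not (0 <= substitution_rate < 1) or not (0 <= homopolymer_rate < 1):
        raise ValueError("error rates must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = _encode(read.sequence)
    codes, n_sub = _substitute(codes, substitution_rate, rng)
    codes, n_homo = _homopolymer_edit(codes, homopolymer_rate, rng)
    return replace(
        read,
        sequence=_decode(codes),
        n_substitutions=read.n_substitutions + n_sub,
        n_homopolymer_edits=read.n_homopolymer_edits + n_homo,
    )


# ---------------------------------------------------------------------------
# whole-metagenome simulation


def simulate_reads(config: SimulationConfig) -> tuple[CommunityProfile, list[SimulatedRead]]:
    """Design the community and sample all error-bearing reads.

    Per-genome read counts are multinomial on the community abundances, so
    the total read count equals `config.n_reads` exactly.  All randomness
    flows from `config.seed` through named substreams (community / counts /
    fragments / errors), making the run bit-reproducible.
    """
    config.validate()
    if not config.genome_set:
        raise ConfigurationError("genome_set is empty")
    ss = np.random.SeedSequence(config.seed)
    rng_community, rng_counts, rng_frag, rng_err = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    profile = design_community(
        [(g, t) for g, t, _ in config.genome_set],
        config.h_target, config.dominance_cap, config.max_taxa, rng_community,
    )
    sequences = {g: s for g, t, s in config.genome_set}
    counts = rng_counts.multinomial(config.n_reads, profile.abundances)
    reads: list[SimulatedRead] = []
    offset = 0
    for (genome_id, taxon_id, _), k in zip(profile.entries, counts):
        if k == 0:
            continue
        fragments = sample_fragments(
            sequences[genome_id], int(k),
            config.fragment_min, config.fragment_max,
            rng_frag, genome_id=genome_id, taxon_id=taxon_id, id_offset=offset,
        )
        reads.extend(
            apply_error_model(r, config.substitution_rate,
                              config.homopolymer_rate, rng_err)
            for r in fragments
        )
        offset += int(k)
    return profile, reads


def reads_to_fasta(reads: list[SimulatedRead]) -> str:
    return "".join(f">{r.read_id}\n{r.sequence}\n" for r in reads)


def reads_to_truth(reads: list[SimulatedRead]) -> str:
    lines = [TRUTH_HEADER, "\t".join(_TRUTH_COLUMNS)]
    for r in reads:
        lines.append("\t".join(map(str, (
            r.read_id, r.source_genome_id, r.source_taxon_id,
            r.start, r.end, r.strand, r.fragment_length,
        ))))
    return "\n".join(lines) + "\n"


def simulate_metagenome(config: SimulationConfig) -> tuple[str, str]:
    """Run the full simulator; returns (reads FASTA text, truth TSV text)."""
    _, reads = simulate_reads(config)
    return reads_to_fasta(reads), reads_to_truth(reads)


# ---------------------------------------------------------------------------
# novel-taxon stand-in & fixtures


def diverge_genome(genome_sequence: str,
                   substitution_rate: float,
                   indel_rate: float,
                   seed: int | np.random.Generator = 0) -> str:
    """Derive a diverged genome by random substitutions and 1 bp indels.

    A deliberately simple neutral-divergence generator used to build
    novel-taxon ("synthetic genome") scenarios: the diverged sequence is
    excluded from classifier training and should behave as an unknown
    taxon downstream.
    """
    if not (0 <= substitution_rate < 0.5) or not (0 <= indel_rate < 0.5):
        raise ValueError("divergence rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = _encode(genome_sequence)
    codes, _ = _substitute(codes, substitution_rate, rng)
    if indel_rate > 0:
        keep = rng.random(len(codes)) >= indel_rate
        kept = codes[keep]
        ins_here = rng.random(len(codes)) < indel_rate
        positions = np.cumsum(keep)[ins_here]  # insert after surviving prefix
        bases = rng.integers(0, 4, size=int(ins_here.sum())).astype(np.uint8)
        codes = np.insert(kept, positions, bases)
    return _decode(codes)


def make_mock_genomes(n_genomes: int,
                      genome_length: int,
                      gc_content: float | list[float] = 0.5,
                      branching: int = 2,
                      seed: int = 0) -> tuple[list[tuple[str, str]], str, dict[str, str]]:
    """Generate i.i.d. random genomes attached to a balanced 7-rank taxonomy.

    Returns (FASTA records as (id, sequence) pairs, taxonomy TSV text in the
    4-column fixture dialect, genome_id -> species taxon_id map).  Genomes
    are grouped `branching`-fold per step going up the ranks, so LCA depth
    between two genomes is controlled by their index distance.  `gc_content`
    may be a scalar or one value per genome (distinct values give
    compositionally well-separated genomes).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    gcs = (np.full(n_genomes, gc_content, dtype=float)
           if np.isscalar(gc_content) else np.asarray(gc_content, dtype=float))
    if len(gcs) != n_genomes:
        raise ValueError("gc_content list must have one entry per genome")

    records: list[tuple[str, str]] = []
    genome_to_taxon: dict[str, str] = {}
    for i in range(n_genomes):
        gc = gcs[i]
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = _decode(rng.choice(4, size=genome_length, p=probs).astype(np.uint8))
        gid = f"genome_{i:03d}"
        records.append((gid, seq))
        genome_to_taxon[gid] = f"species_{i:03d}"

    prefixes = ("dom", "phy", "cla", "ord", "fam", "gen", "spe")
    lines = ["#taxon_id\tparent_id\trank\tname", "root\troot\tno rank\troot"]
    seen = set()
    for i in range(n_genomes):
        # group index at rank r (species = deepest): i // branching^(6 - r)
        chain = ["root"]
        for r, rank in enumerate(CANONICAL_RANKS):
            group = i // (branching ** (len(CANONICAL_RANKS) - 1 - r))
            tid = (f"species_{i:03d}" if rank == "species"
                   else f"{prefixes[r]}_{group:03d}")
            if tid not in seen:
                seen.add(tid)
                lines.append(f"{tid}\t{chain[-1]}\t{rank}\t{tid}")
            chain.append(tid)
    taxonomy_tsv = "\n".join(lines) + "\n"
    return records, taxonomy_tsv, genome_to_taxon
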