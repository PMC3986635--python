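"""Top-level pipeline: simulate -> assign -> evaluate -> report.

The default three-method roster mirrors a typical consistency study: a
similarity route (shared-k-mer hit finding collapsed by LCA), a naive
Bayes k-mer classifier, and a perturbed Bayes variant standing in for a
second composition-based program.  External classifier tables can replace
or extend the roster.  Every stage draws randomness from a named substream
of the root seed, and a manifest records SHA-256 checksums of every
artifact so identical configurations replay bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import assign as asg
from . import consistency as cons
from . import metrics as met
from . import report as rep
from . import simulate as sim
from .config import PipelineConfig
from .io import read_fasta
from .taxonomy import TaxonomyTree, load_taxonomy_table

__all__ = ["run_pipeline", "kmer_hits", "noisy_nbc_classify"]

logger = logging.getLogger(__name__)

_STAGES = ("community", "simulate", "noise")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, _STAGES.index(stage)]))


def kmer_hits(read_id: str, sequence: str,
              genome_kmers: dict[str, set[int]], k: int = 16,
              min_shared: int = 3) -> list[asg.BlastHit]:
    """Similarity heuristic: hits from exact shared k-mers per genome.

    Each genome sharing >= `min_shared` k-mers with the read yields one hit
    whose bit score is the shared-k-mer count and whose e-value decays ten-
    fold per shared k-mer (10^-shared, floored at 1e-180) — a monotone
    stand-in score, adequate for cutoff-style filtering.
    """
    read_kmers = set(
        asg._canonical_codes(asg._kmer_codes(sequence, k), k).tolist())
    hits = []
    for gid, kmers in genome_kmers.items():
        shared = len(read_kmers & kmers)
        if shared >= min_shared:
            hits.append(asg.BlastHit(
                read_id, gid, 100.0, shared + k - 1, 0, 0, 1, len(sequence),
                1, len(sequence), max(10.0 ** -shared, 1e-180), float(shared)))
    return hits


def noisy_nbc_classify(model: asg.NBCModel, read_id: str, sequence: str,
                       rng: np.random.Generator, sigma: float,
                       method_id: str = "nbc_noisy") -> asg.Assignment:
    """Bayes classification with Gaussian noise added to the log-likelihoods.

    A deliberately degraded classifier variant used as a third roster
    method; sigma is in log-likelihood units.
    """
    base = asg.nbc_classify(model, read_id, sequence, method_id=method_id)
    if base.log_likelihoods is None:
        return base
    genomes = sorted(base.log_likelihoods)
    noisy = {g: base.log_likelihoods[g] + sigma * rng.standard_normal()
             for g in genomes}
    winner = min(g for g in genomes if noisy[g] >= max(noisy.values()) - 1e-12)
    return asg.Assignment(read_id, method_id, model.taxon_map[winner],
                          score=noisy[winner], read_length=len(sequence),
                          log_likelihoods=noisy)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full workflow; returns the path to the manifest JSON.

    Outputs under `out_dir`: reads.fasta, truth.tsv, assignments.tsv,
    agreement.tsv, crosstab_<a>_<b>.tsv, metrics.tsv, rarefaction.tsv and
    manifest.json.  With a single-method roster the consistency stages are
    skipped with a logged notice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # --- inputs: genomes + taxonomy (mock fixtures when none are given)
    if config.genomes_fasta:
        records = [(r.id, r.sequence) for r in
                   read_fasta(open(config.genomes_fasta))]
        genome_to_taxon = dict(
            line.split("\t")[:2]
            for line in Path(config.genome_taxon_map).read_text().splitlines()
            if line.strip() and not line.startswith("#"))
        tree = load_taxonomy_table(open(config.taxonomy))
    else:
        logger.info("no genomes_fasta given: generating mock genomes")
        records, taxonomy_tsv, genome_to_taxon = sim.make_mock_genomes(
            n_genomes=max(config.simulation["max_taxa"], 8),
            genome_length=20_000,
            gc_content=list(np.linspace(
                0.35, 0.65, max(config.simulation["max_taxa"], 8))),
            seed=config.seed)
        (out / "taxonomy.tsv").write_text(taxonomy_tsv)
        tree = load_taxonomy_table(taxonomy_tsv.splitlines())

    genome_set = [(g, genome_to_taxon[g], s) for g, s in records]

    # --- simulate
    sim_config = config.simulation_config(genome_set)
    profile, reads = sim.simulate_reads(sim_config)
    (out / "reads.fasta").write_text(sim.reads_to_fasta(reads))
    (out / "truth.tsv").write_text(sim.reads_to_truth(reads))
    curve = sim.fit_rarefaction(max(sim_config.n_reads, 1),
                                sim_config.max_taxa, profile)
    (out / "rarefaction.tsv").write_text(
        "a\tb\tdegenerate\n"
        f"{curve.a:.6g}\t{curve.b:.6g}\t{curve.degenerate}\n")

    # --- assign
    model = asg.train_nbc(records, genome_to_taxon, k=config.assignment["k"])
    kmer_index = {
        g: set(asg._canonical_codes(asg._kmer_codes(s, 16), 16).tolist())
        for g, s in records
    }
    subject_genomes = {g: g for g, _ in records}
    rng_noise = _stage_rng(config.seed, "noise")
    sigma = config.assignment.get("noise_sigma", 100.0)
    e_cutoff = config.assignment["e_cutoff"]

    methods = list(config.assignment["methods"])
    assignments: list[asg.Assignment] = []
    for read in reads:
        hits = None
        for method in methods:
            if method == "nbc":
                assignments.append(asg.nbc_classify(model, read.read_id, read.sequence))
            elif method == "nbc_noisy":
                assignments.append(noisy_nbc_classify(
                    model, read.read_id, read.sequence, rng_noise, sigma))
            elif method == "lca":
                hits = kmer_hits(read.read_id, read.sequence, kmer_index)
                assignments.append(asg.lca_assign(
                    hits, genome_to_taxon, tree, e_cutoff=e_cutoff,
                    read_id=read.read_id))
            elif method == "nbc_blast":
                hits = hits or kmer_hits(read.read_id, read.sequence, kmer_index)
                a = asg.combine_blast_nbc(model, read.read_id, read.sequence,
                                          hits, subject_genomes, e_cutoff=e_cutoff)
                assignments.append(a)
            else:
                raise ValueError(f"unknown roster method {method!r}")
    frame = asg.assignments_to_frame(assignments)
    (out / "assignments.tsv").write_text(asg.write_assignments(frame))

    # --- evaluate & report
    truth = {r.read_id: r.source_taxon_id for r in reads}
    ranks = config.evaluation["ranks"]
    if len(methods) >= 2:
        agreement = cons.agreement_table(frame, tree, ranks)
        agreement.to_csv(out / "agreement.tsv", sep="\t", index=False)
        a, b = methods[0], methods[1]
        crosstab = cons.cross_tab_disagreements(frame, a, b, ranks[0], tree)
        crosstab.to_csv(out / f"crosstab_{a}_{b}.tsv", sep="\t", index=False)
        split = met.true_false_split(frame, truth, tree, ranks)
        split.to_csv(out / "true_false_split.tsv", sep="\t", index=False)
    else:
        logger.info("single-method roster: consistency stages skipped")
    table = met.metrics_table(frame, truth, tree, ranks,
                              include_combined=len(methods) >= 2)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False, na_rep="NA")
    if len(methods) >= 2:
        lc = rep.length_consistency(
            frame, tree, ranks[min(1, len(ranks) - 1)],
            bin_width=config.evaluation["bin_width"],
            degree=config.evaluation["polynomial_degree"])
        with open(out / "length_consistency.tsv", "w") as fh:
            fh.write("midpoint\tn\tproportion\n")
            for m, n, p in zip(lc.midpoints, lc.n_reads, lc.proportions):
                fh.write(f"{m:g}\t{n}\t{p:.6f}\n")

    manifest = {
        "seed": config.seed,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
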