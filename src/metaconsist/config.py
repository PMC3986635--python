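"""Pipeline configuration: YAML parsing, defaults and validation.

A configuration file is a flat-ish YAML document with three sections
(simulation / assignment / evaluation) plus a root seed and paths.  All
violations are collected and reported at once; defaults mirror the study
conditions (fragment range 350-600 bp, similarity e-value cutoff 1e-5).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import yaml

from .assign import DEFAULT_E_CUTOFF
from .simulate import SimulationConfig, ConfigurationError
from .taxonomy import CANONICAL_RANKS

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "dump_config"]


class ConfigError(ValueError):
    """One or more configuration violations (all listed in the message)."""


_SIM_DEFAULTS = dict(
    h_target=1.5, n_reads=1000, max_taxa=10, dominance_cap=0.5,
    fragment_min=350, fragment_max=600,
    substitution_rate=0.001, homopolymer_rate=0.01,
)

_ASSIGN_DEFAULTS = dict(
    k=8, e_cutoff=DEFAULT_E_CUTOFF, epsilons=[0.0],
    methods=["nbc", "nbc_noisy", "lca"], noise_sigma=100.0,
)

_EVAL_DEFAULTS = dict(
    ranks=list(CANONICAL_RANKS), bin_width=25, polynomial_degree=3,
    confused_genera=None,
)


@dataclass
class PipelineConfig:
    simulation: dict = field(default_factory=dict)
    assignment: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    genomes_fasta: str | None = None
    genome_taxon_map: str | None = None
    taxonomy: str | None = None

    def simulation_config(self, genome_set) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            h_target=s["h_target"], n_reads=s["n_reads"],
            max_taxa=s["max_taxa"], dominance_cap=s["dominance_cap"],
            fragment_min=s["fragment_min"], fragment_max=s["fragment_max"],
            substitution_rate=s["substitution_rate"],
            homopolymer_rate=s["homopolymer_rate"],
            seed=self.seed, genome_set=genome_set,
        )


def validate_config(source: str | Path | IO[str] | dict) -> PipelineConfig:
    """Parse, default-fill and validate a configuration.

    `source` may be a path, an open stream, YAML text, or an already-parsed
    mapping.  Raises :class:`ConfigError` listing every violation found.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        raw = yaml.safe_load(_io.StringIO(text)) or {}

    sim = {**_SIM_DEFAULTS, **(raw.get("simulation") or {})}
    asg = {**_ASSIGN_DEFAULTS, **(raw.get("assignment") or {})}
    ev = {**_EVAL_DEFAULTS, **(raw.get("evaluation") or {})}

    errors: list[str] = []
    if sim["fragment_min"] > sim["fragment_max"]:
        errors.append(
            f"simulation.fragment_min ({sim['fragment_min']}) > "
            f"simulation.fragment_max ({sim['fragment_max']})")
    if not (0 < sim["dominance_cap"] <= 1):
        errors.append(f"simulation.dominance_cap must be in (0, 1], "
                      f"got {sim['dominance_cap']}")
    elif sim["dominance_cap"] * sim["max_taxa"] < 1:
        errors.append("simulation: infeasible diversity settings "
                      "(dominance_cap * max_taxa < 1)")
    if sim["max_taxa"] >= 1 and sim["h_target"] > math.log(max(sim["max_taxa"], 1)) + 1e-9:
        errors.append("simulation: infeasible diversity settings "
                      f"(h_target {sim['h_target']} > ln(max_taxa))")
    if not (4 <= asg["k"] <= 12):
        errors.append(f"assignment.k must lie in [4, 12], got {asg['k']}")
    if asg["e_cutoff"] <= 0:
        errors.append(f"assignment.e_cutoff must be > 0, got {asg['e_cutoff']}")
    bad_eps = [e for e in asg["epsilons"] if not (0 <= e <= 1)]
    if bad_eps:
        errors.append(f"assignment.epsilons outside [0, 1]: {bad_eps}")
    bad_ranks = [r for r in ev["ranks"] if r not in CANONICAL_RANKS]
    if bad_ranks:
        errors.append(f"evaluation.ranks unknown: {bad_ranks}")
    if ev["bin_width"] < 1:
        errors.append(f"evaluation.bin_width must be >= 1, got {ev['bin_width']}")
    for key in ("genomes_fasta", "genome_taxon_map", "taxonomy"):
        path = raw.get(key)
        if path is not None and not Path(path).exists():
            errors.append(f"{key}: path does not exist: {path}")
    if errors:
        raise ConfigError("; ".join(errors))

    return PipelineConfig(
        simulation=sim, assignment=asg, evaluation=ev,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        genomes_fasta=raw.get("genomes_fasta"),
        genome_taxon_map=raw.get("genome_taxon_map"),
        taxonomy=raw.get("taxonomy"),
    )


def dump_config(config: PipelineConfig) -> str:
    """Serialize a normalized configuration; re-validates identically."""
    doc = {
        "simulation": config.simulation,
        "assignment": config.assignment,
        "evaluation": config.evaluation,
        "seed": config.seed,
        "log_level": config.log_level,
    }
    for key in ("genomes_fasta", "genome_taxon_map", "taxonomy"):
        value = getattr(config, key)
        if value is not None:
            doc[key] = value
    return yaml.safe_dump(doc, sort_keys=True)
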