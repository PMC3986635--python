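"""Derived analyses: read-length vs. consistency, ε sweeps, score summaries.

These are the presentation-layer computations behind the usual figures of a
consistency study: the proportion of reads on which at least two methods
converge as a function of read length (with a polynomial fit and the read
length needed to reach a given agreement level), the number of reads a
Bayes classifier retains as its ε cutoff grows (alone and combined with a
similarity search), and per-category confidence-score means with 95%
t-intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assign import (EpsilonConfig, NBCModel, apply_epsilon_cutoff, BlastHit,
                     combine_blast_nbc, nbc_classify)
from .consistency import consensus_assign, _calls_by_read, project_call
from .taxonomy import TaxonomyTree

__all__ = [
    "LengthConsistencyCurve",
    "ScoreCategorySummary",
    "NOT_REACHED",
    "length_consistency",
    "threshold_length",
    "epsilon_sweep",
    "score_category_summary",
    "plot_agreement",
    "plot_length_consistency",
    "plot_epsilon_sweep",
]

logger = logging.getLogger(__name__)

#: Returned by threshold_length when the fitted curve never sustains the level.
NOT_REACHED = None


@dataclass
class LengthConsistencyCurve:
    """Binned >= 2-method agreement proportions with a polynomial fit."""

    midpoints: np.ndarray      # bp
    n_reads: np.ndarray
    proportions: np.ndarray    # in [0, 1]
    coefficients: np.ndarray   # ascending powers
    degree: int

    def predict(self, lengths) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(lengths, dtype=float), self.coefficients)


@dataclass
class ScoreCategorySummary:
    category: str
    mean: float
    ci_half_width: float  # NaN when n < 2
    n: int


def length_consistency(frame: pd.DataFrame,
                       tree: TaxonomyTree,
                       rank: str,
                       bin_width: int = 25,
                       degree: int = 3,
                       methods: list[str] | None = None) -> LengthConsistencyCurve:
    """Bin reads by length; per bin, the proportion with a >= 2-method
    consensus at `rank`; fit a least-squares polynomial (default cubic)
    of proportion on bin midpoint.

    Read lengths are taken from the table's ``read_length`` column (the
    first non-null value per read).  Empty bins are dropped with a warning.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1 bp")
    methods, calls = _calls_by_read(frame, methods)
    lengths = (frame.dropna(subset=["read_length"])
               .groupby("read_id")["read_length"].first())
    consistent = {
        rid: consensus_assign(per_method, tree, rank) is not None
        for rid, per_method in calls.items()
    }
    data = pd.DataFrame({
        "length": lengths,
        "consistent": pd.Series(consistent),
    }).dropna()
    if data.empty:
        raise ValueError("no reads with lengths available")
    bins = (data["length"] // bin_width).astype(int)
    grouped = data.groupby(bins)
    mids, ns, props = [], [], []
    for b, grp in grouped:
        mids.append((b + 0.5) * bin_width)
        ns.append(len(grp))
        props.append(grp["consistent"].mean())
    n_empty = int(bins.max() - bins.min() + 1) - len(mids)
    if n_empty > 0:
        logger.warning("%d empty length bins dropped", n_empty)
    mids = np.asarray(mids, dtype=float)
    props = np.asarray(props, dtype=float)
    deg = min(degree, len(mids) - 1)
    coeffs = np.polynomial.polynomial.polyfit(mids, props, deg, w=np.sqrt(ns))
    return LengthConsistencyCurve(mids, np.asarray(ns), props, coeffs, deg)


def threshold_length(curve: LengthConsistencyCurve, level: float) -> float | None:
    """Smallest read length where the fitted curve reaches `level` and stays
    at or above it for the rest of the observed range (1 bp grid).

    Sustained crossing is required because a polynomial can dip back below
    the level; returns :data:`NOT_REACHED` (None) if no such length exists.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    grid = np.arange(math.floor(curve.midpoints.min()),
                     math.ceil(curve.midpoints.max()) + 1.0)
    values = curve.predict(grid)
    above = values >= level
    if not above.any():
        return NOT_REACHED
    # last index below level determines where a sustained crossing can start
    below_idx = np.flatnonzero(~above)
    start = below_idx.max() + 1 if len(below_idx) else 0
    if start >= len(grid):
        return NOT_REACHED
    return float(grid[start])


def epsilon_sweep(reads: Sequence[tuple[str, str]],
                  model: NBCModel,
                  blast_hits: Mapping[str, list[BlastHit]],
                  subject_genomes: Mapping[str, str],
                  tree: TaxonomyTree,
                  rank: str,
                  epsilons: Sequence[float],
                  modes: Sequence[str] = ("nbc_only", "lca_plus_nbc"),
                  contaminant_ids: set[str] | frozenset[str] = frozenset(),
                  e_cutoff: float = 1e-5) -> pd.DataFrame:
    """Count retained assignments per (ε, mode) at a rank.

    `reads` are (read_id, sequence) pairs; `blast_hits` maps read_id to its
    similarity hits (missing or empty = no hits, the contaminant surrogate).
    Emits per combination: reads assigned, contaminant reads assigned, and
    reads where the two modes' projections agree at `rank`.
    """
    if 0.0 not in [float(e) for e in epsilons]:
        raise ValueError("epsilons must include 0")
    base = {}
    for mode in modes:
        per_read = {}
        for rid, seq in reads:
            if mode == "nbc_only":
                per_read[rid] = nbc_classify(model, rid, seq)
            else:
                per_read[rid] = combine_blast_nbc(
                    model, rid, seq, blast_hits.get(rid, []),
                    subject_genomes, e_cutoff=e_cutoff)
        base[mode] = per_read

    rows = []
    for eps in epsilons:
        cut = {}
        for mode in modes:
            cfg = EpsilonConfig(float(eps), mode)
            cut[mode] = {
                rid: apply_epsilon_cutoff(a, cfg) if a.log_likelihoods is not None else a
                for rid, a in base[mode].items()
            }
        for mode in modes:
            assigned = [rid for rid, a in cut[mode].items() if a.is_assigned]
            n_contam = sum(rid in contaminant_ids for rid in assigned)
            if len(modes) >= 2:
                other = modes[1] if mode == modes[0] else modes[0]
                concordant = sum(
                    1 for rid in assigned
                    if cut[other][rid].is_assigned
                    and project_call(tree, cut[mode][rid].taxon_id, rank)
                    == project_call(tree, cut[other][rid].taxon_id, rank)
                )
            else:
                concordant = 0
            rows.append((float(eps), mode, len(assigned), n_contam, concordant))
    return pd.DataFrame(rows, columns=[
        "epsilon", "mode", "n_assigned", "n_contaminant_assigned", "n_concordant",
    ])


def score_category_summary(scores_by_category: Mapping[str, Sequence[float]]
                           ) -> list[ScoreCategorySummary]:
    """Mean and 95% t-interval half-width of scores per read category.

    Categories with fewer than two scores get a NaN half-width.
    """
    out = []
    for category in sorted(scores_by_category):
        values = np.asarray(scores_by_category[category], dtype=float)
        n = len(values)
        mean = float(values.mean()) if n else math.nan
        if n >= 2:
            sem = stats.sem(values)
            half = float(stats.t.ppf(0.975, n - 1) * sem)
        else:
            half = math.nan
        out.append(ScoreCategorySummary(category, mean, half, n))
    return out


# ---------------------------------------------------------------------------
# plain-figure exports


def _agg_backend():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_agreement(agreement: pd.DataFrame, path: str) -> None:
    """Stacked bars of agreement-class counts per rank."""
    plt = _agg_backend()
    pivot = agreement.pivot(index="rank", columns="agreement_class", values="count")
    pivot = pivot.reindex(index=agreement["rank"].unique())
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 5))
    ax.set_ylabel("reads")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)


def plot_length_consistency(curve: LengthConsistencyCurve, path: str,
                            level: float | None = 0.75) -> None:
    """Scatter of binned proportions with the fitted polynomial."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(curve.midpoints, curve.proportions, s=12, label="binned")
    grid = np.linspace(curve.midpoints.min(), curve.midpoints.max(), 200)
    ax.plot(grid, curve.predict(grid), color="red", label=f"degree-{curve.degree} fit")
    if level is not None:
        ax.axhline(level, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("read length (bp)")
    ax.set_ylabel("proportion >= 2-method consistent")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_epsilon_sweep(sweep: pd.DataFrame, path: str) -> None:
    """Assigned-read counts vs. ε for each mode."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(7, 5))
    for mode, grp in sweep.groupby("mode"):
        grp = grp.sort_values("epsilon")
        ax.plot(grp["epsilon"], grp["n_assigned"], marker="o", label=mode)
    ax.set_xlabel("epsilon")
    ax.set_ylabel("reads assigned")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
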