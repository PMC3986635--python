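"""Truth-based evaluation: per-rank sensitivity and precision.

Definitions follow the standard taxonomic-binning convention:

* sensitivity = 100 x (correct assignments) / (sequences in the dataset) —
  unassigned reads count against it;
* precision = 100 x (correct assignments) / (assignments made) —
  abstentions do not count against it (NA when nothing was assigned).

Both are computed per canonical rank for each method and for the combined
strategy, in which a read is assigned the taxon at least two methods
converge on.  Raw integer counts are always emitted alongside percentages
so every figure is recomputable.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .assign import UNASSIGNED
from .consistency import (AgreementRecord, ConfusedGenera, classify_agreement,
                          consensus_assign, project_call, _calls_by_read)
from .taxonomy import CANONICAL_RANKS, NO_RANK, TaxonomyTree

__all__ = [
    "COMBINED",
    "CORRECT",
    "WRONG",
    "score_correctness",
    "metrics_table",
    "true_false_split",
    "EvaluationError",
]

COMBINED = "COMBINED"
CORRECT = "CORRECT"
WRONG = "WRONG"


class EvaluationError(ValueError):
    """Truth table does not cover the assignment table."""


def score_correctness(call_taxon: str,
                      truth_taxon: str,
                      tree: TaxonomyTree,
                      rank: str) -> str:
    """Judge one call against truth at one rank.

    Both are projected to the rank; equal ranked taxa are CORRECT, and a
    call of NO_RANK against a truth lineage that genuinely lacks the rank
    is also CORRECT.  UNASSIGNED is its own outcome; everything else is
    WRONG.
    """
    if call_taxon == UNASSIGNED:
        return UNASSIGNED
    truth_at_rank = tree.project_to_rank(truth_taxon, rank)
    call_at_rank = tree.project_to_rank(call_taxon, rank)
    if call_at_rank == truth_at_rank:  # includes NO_RANK == NO_RANK
        return CORRECT
    return WRONG


def metrics_table(frame: pd.DataFrame,
                  truth: Mapping[str, str],
                  tree: TaxonomyTree,
                  ranks: Iterable[str] = CANONICAL_RANKS,
                  methods: list[str] | None = None,
                  include_combined: bool = True) -> pd.DataFrame:
    """Sensitivity/precision rows per rank x method (plus COMBINED).

    `truth` maps read_id -> true taxon_id and must cover every read in the
    table.  The combined strategy's denominator of assignments made is the
    number of reads with a >= 2-method consensus taxon.
    """
    methods, calls = _calls_by_read(frame, methods)
    missing = [r for r in calls if r not in truth]
    if missing:
        raise EvaluationError(f"reads missing from truth: {sorted(missing)[:5]}")

    rows = []
    for rank in ranks:
        for method in list(methods) + ([COMBINED] if include_combined else []):
            n_total = len(calls)
            n_correct = n_assigned = 0
            for rid, per_method in calls.items():
                if method == COMBINED:
                    consensus = consensus_assign(per_method, tree, rank)
                    if consensus is None:
                        continue
                    n_assigned += 1
                    if consensus == tree.project_to_rank(truth[rid], rank):
                        n_correct += 1
                else:
                    outcome = score_correctness(per_method[method], truth[rid],
                                                tree, rank)
                    if outcome == UNASSIGNED:
                        continue
                    n_assigned += 1
                    if outcome == CORRECT:
                        n_correct += 1
            sensitivity = 100.0 * n_correct / n_total if n_total else math.nan
            precision = 100.0 * n_correct / n_assigned if n_assigned else math.nan
            rows.append((rank, method, sensitivity, precision,
                         n_correct, n_assigned, n_total))
    return pd.DataFrame(rows, columns=[
        "rank", "method_id", "sensitivity", "precision",
        "n_correct", "n_assigned", "n_total",
    ])


def true_false_split(frame: pd.DataFrame,
                     truth: Mapping[str, str],
                     tree: TaxonomyTree,
                     ranks: Iterable[str] = CANONICAL_RANKS,
                     confused: ConfusedGenera | None = None,
                     methods: list[str] | None = None) -> pd.DataFrame:
    """Partition each agreement class into true/false positives per rank.

    For ALL_SAME/TWO_SAME the consensus taxon is judged against truth; for
    the remaining classes a record counts as TP when at least one method's
    projected call matches truth at the rank.  Per rank x class, tp + fp
    equals the agreement-table count.
    """
    methods, calls = _calls_by_read(frame, methods)
    missing = [r for r in calls if r not in truth]
    if missing:
        raise EvaluationError(f"reads missing from truth: {sorted(missing)[:5]}")
    rows = []
    for rank in ranks:
        tallies: dict[str, list[int]] = {}
        for rid, per_method in calls.items():
            record: AgreementRecord = classify_agreement(
                per_method, tree, rank, confused, read_id=rid)
            truth_at_rank = tree.project_to_rank(truth[rid], rank)
            if record.consensus_taxon is not None:
                is_tp = record.consensus_taxon == truth_at_rank
            else:
                projections = [project_call(tree, t, rank)
                               for t in per_method.values()]
                is_tp = any(p == truth_at_rank for p in projections)
            tally = tallies.setdefault(record.agreement_class, [0, 0])
            tally[0 if is_tp else 1] += 1
        for cls, (tp, fp) in sorted(tallies.items()):
            rows.append((rank, cls, tp, fp))
    return pd.DataFrame(rows, columns=["rank", "agreement_class", "tp", "fp"])
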