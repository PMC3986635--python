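import math

import numpy as np
import pytest

from metaconsist.assign import (Assignment, BlastHit, UNASSIGNED,
                                assignments_to_frame)
from metaconsist.report import (NOT_REACHED, LengthConsistencyCurve,
                                epsilon_sweep, length_consistency,
                                score_category_summary, threshold_length)


def _consistency_frame(rng, n_reads, prob_of_length, lengths=None,
                       rank_taxa=("ecoli", "senterica", "t4")):
    """Three-method assignments where a read is all-same with probability
    prob_of_length(L), otherwise all-different."""
    rows = []
    lengths = lengths if lengths is not None else rng.integers(100, 601, n_reads)
    for i, L in enumerate(lengths):
        rid = f"r{i}"
        if rng.random() < prob_of_length(L):
            calls = (rank_taxa[0],) * 3
        else:
            calls = rank_taxa
        for m, t in zip(("m1", "m2", "m3"), calls):
            rows.append(Assignment(rid, m, t, read_length=int(L)))
    return assignments_to_frame(rows)


class TestLengthConsistency:
    def test_fully_consistent_reads_fit_constant_one(self, mini_tree):
        rng = np.random.default_rng(20)
        frame = _consistency_frame(rng, 400, lambda L: 1.0)
        curve = length_consistency(frame, mini_tree, "species")
        assert np.allclose(curve.proportions, 1.0)
        grid = np.linspace(curve.midpoints.min(), curve.midpoints.max(), 50)
        assert np.allclose(curve.predict(grid), 1.0, atol=1e-6)

    def test_proportions_match_brute_force_counting(self, mini_tree):
        rng = np.random.default_rng(21)
        frame = _consistency_frame(rng, 500, lambda L: 0.5)
        bin_width = 50
        curve = length_consistency(frame, mini_tree, "species",
                                   bin_width=bin_width)
        # brute-force recount per bin from the raw table
        pivot = frame.pivot(index="read_id", columns="method_id",
                            values="taxon_id")
        lengths = frame.groupby("read_id")["read_length"].first()
        consistent = (pivot.nunique(axis=1) == 1)
        for mid, prop, n in zip(curve.midpoints, curve.proportions,
                                curve.n_reads):
            members = lengths[(lengths // bin_width) == int(mid // bin_width)]
            assert n == len(members)
            assert prop == pytest.approx(consistent[members.index].mean())

    def test_logistic_construction_recovered(self, mini_tree):
        # a gentle logistic length-dependence; degree 5 so the polynomial
        # has enough freedom to track the sigmoid over the whole range
        rng = np.random.default_rng(22)
        logistic = lambda L: 1.0 / (1.0 + math.exp(-(L - 300) / 60.0))
        frame = _consistency_frame(rng, 3000, logistic)
        curve = length_consistency(frame, mini_tree, "species", bin_width=25,
                                   degree=5)
        grid = np.linspace(150, 550, 100)
        expected = np.array([logistic(L) for L in grid])
        assert np.max(np.abs(curve.predict(grid) - expected)) < 0.05


class TestThresholdLength:
    def _constant_curve(self, value):
        mids = np.arange(112.5, 600, 25.0)
        return LengthConsistencyCurve(mids, np.full(len(mids), 50),
                                      np.full(len(mids), value),
                                      np.array([value]), 0)

    def test_constant_above_level_returns_min_length(self):
        curve = self._constant_curve(0.9)
        assert threshold_length(curve, 0.75) == pytest.approx(
            math.floor(curve.midpoints.min()))

    def test_constant_below_level_not_reached(self):
        assert threshold_length(self._constant_curve(0.5), 0.75) is NOT_REACHED

    def test_non_decreasing_in_level(self, mini_tree):
        rng = np.random.default_rng(23)
        logistic = lambda L: 1.0 / (1.0 + math.exp(-(L - 300) / 40.0))
        frame = _consistency_frame(rng, 2000, logistic)
        curve = length_consistency(frame, mini_tree, "species")
        thresholds = [threshold_length(curve, lv) for lv in (0.5, 0.65, 0.8)]
        assert all(t is not NOT_REACHED for t in thresholds)
        assert thresholds == sorted(thresholds)

    def test_known_crossing_recovered_within_bin_width(self, mini_tree):
        bin_width = 25
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            crossing = 300.0  # logistic hits 75% at L* + s*ln 3
            s = 60.0
            logistic = lambda L: 1.0 / (1.0 + math.exp(-(L - crossing) / s))
            true_75 = crossing + s * math.log(3)
            frame = _consistency_frame(rng, 3000, logistic)
            curve = length_consistency(frame, mini_tree, "species",
                                       bin_width=bin_width)
            recovered = threshold_length(curve, 0.75)
            assert recovered is not NOT_REACHED
            assert abs(recovered - true_75) <= bin_width


class TestEpsilonSweep:
    @pytest.fixture()
    def sweep_inputs(self, mock_world, nbc_model):
        rng = np.random.default_rng(24)
        reads, hits = [], {}
        for i in range(40):
            gid, seq = mock_world["records"][i % 10]
            start = int(rng.integers(0, len(seq) - 400))
            rid = f"r{i}"
            reads.append((rid, seq[start:start + 400]))
            hits[rid] = [BlastHit(rid, gid, 99.0, 400, 0, 0, 1, 400, 1, 400,
                                  1e-30, 500.0)]
        contaminants = set()
        for i in range(10):  # alien reads, no hits at all
            rid = f"c{i}"
            reads.append((rid, "".join(rng.choice(list("ACGT"), size=400))))
            contaminants.add(rid)
        return reads, hits, contaminants

    def test_zero_epsilon_assigns_all_classifiable(self, mock_world, nbc_model,
                                                   sweep_inputs):
        reads, hits, contaminants = sweep_inputs
        sweep = epsilon_sweep(reads, nbc_model, hits, {}, mock_world["tree"],
                              "phylum", epsilons=[0.0],
                              contaminant_ids=contaminants)
        nbc_row = sweep[(sweep["mode"] == "nbc_only")].iloc[0]
        assert nbc_row["n_assigned"] == len(reads)

    def test_contaminants_never_assigned_under_combination(self, mock_world,
                                                           nbc_model,
                                                           sweep_inputs):
        reads, hits, contaminants = sweep_inputs
        genomes = {g: g for g, _ in mock_world["records"]}
        sweep = epsilon_sweep(reads, nbc_model, hits, genomes,
                              mock_world["tree"], "phylum",
                              epsilons=[0.0, 0.5, 0.99],
                              contaminant_ids=contaminants)
        combined = sweep[sweep["mode"] == "lca_plus_nbc"]
        assert (combined["n_contaminant_assigned"] == 0).all()

    def test_assigned_counts_non_increasing_in_epsilon(self, mock_world,
                                                       nbc_model, sweep_inputs):
        reads, hits, contaminants = sweep_inputs
        genomes = {g: g for g, _ in mock_world["records"]}
        sweep = epsilon_sweep(reads, nbc_model, hits, genomes,
                              mock_world["tree"], "phylum",
                              epsilons=[0.0, 0.3, 0.6, 0.9, 1.0],
                              contaminant_ids=contaminants)
        for _, grp in sweep.groupby("mode"):
            counts = list(grp.sort_values("epsilon")["n_assigned"])
            assert counts == sorted(counts, reverse=True)

    def test_epsilons_must_include_zero(self, mock_world, nbc_model):
        with pytest.raises(ValueError):
            epsilon_sweep([], nbc_model, {}, {}, mock_world["tree"],
                          "phylum", epsilons=[0.5])


class TestPlots:
    def test_figures_written(self, mini_tree, tmp_path):
        from metaconsist.consistency import agreement_table
        from metaconsist.report import (plot_agreement, plot_epsilon_sweep,
                                        plot_length_consistency)
        import pandas as pd

        rng = np.random.default_rng(26)
        frame = _consistency_frame(rng, 200, lambda L: 0.6)
        plot_agreement(agreement_table(frame, mini_tree),
                       str(tmp_path / "agreement.svg"))
        curve = length_consistency(frame, mini_tree, "species")
        plot_length_consistency(curve, str(tmp_path / "curve.svg"))
        sweep = pd.DataFrame({"epsilon": [0.0, 0.5], "mode": ["nbc_only"] * 2,
                              "n_assigned": [10, 5]})
        plot_epsilon_sweep(sweep, str(tmp_path / "sweep.svg"))
        for name in ("agreement.svg", "curve.svg", "sweep.svg"):
            assert (tmp_path / name).stat().st_size > 0


class TestScoreSummary:
    def test_identical_scores_zero_width(self):
        [summary] = score_category_summary({"same": [0.8, 0.8, 0.8]})
        assert summary.mean == pytest.approx(0.8)
        assert summary.ci_half_width == pytest.approx(0.0)
        assert summary.n == 3

    def test_single_observation_has_na_interval(self):
        [summary] = score_category_summary({"cont": [0.9]})
        assert math.isnan(summary.ci_half_width)

    def test_normal_samples_recovered(self):
        rng = np.random.default_rng(25)
        data = {
            "contaminant": rng.normal(0.84, 0.02, size=500),
            "same": rng.normal(0.80, 0.02, size=500),
        }
        summaries = {s.category: s for s in score_category_summary(data)}
        se = 0.02 / math.sqrt(500)
        assert abs(summaries["contaminant"].mean - 0.84) <= 3 * se
        assert abs(summaries["same"].mean - 0.80) <= 3 * se
        # brute-force mean check
        assert summaries["same"].mean == pytest.approx(
            sum(data["same"]) / 500)
        # 95% t-interval ~ 1.96 * SE at n = 500
        assert summaries["same"].ci_half_width == pytest.approx(1.96 * np.std(
            data["same"], ddof=1) / math.sqrt(500), rel=0.01)
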