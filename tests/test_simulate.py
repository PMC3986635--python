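import math

import numpy as np
import pytest
from scipy import stats

from metaconsist.simulate import (CommunityProfile, ConfigurationError,
                                  GenomeTooShortError, SimulationConfig,
                                  apply_error_model, design_community,
                                  diverge_genome, expected_accumulation,
                                  fit_rarefaction, make_mock_genomes,
                                  reverse_complement, sample_fragments,
                                  shannon_entropy, simulate_metagenome,
                                  simulate_reads)
from metaconsist.taxonomy import CANONICAL_RANKS, load_taxonomy_table


def _candidates(n):
    return [(f"g{i}", f"t{i}") for i in range(n)]


class TestDesignCommunity:
    def test_single_taxon_degenerate(self):
        profile = design_community(_candidates(3), 0.0, 1.0, 1, seed=0)
        assert len(profile.entries) == 1
        assert profile.abundances[0] == pytest.approx(1.0)
        assert profile.shannon() == pytest.approx(0.0)

    def test_maximum_entropy_limit_is_uniform(self):
        s = 12
        profile = design_community(_candidates(s), math.log(s), 1.0, s, seed=1)
        assert np.allclose(profile.abundances, 1.0 / s)

    def test_target_entropy_and_cap_hold(self):
        profile = design_community(_candidates(40), 3.2, 0.05, 40, seed=2)
        p = profile.abundances
        # entropy recomputed independently from the emitted profile
        assert abs(float(-(p * np.log(p)).sum()) - 3.2) <= 1e-3
        assert p.max() <= 0.05 + 1e-12
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_entropy_below_cap_floor_rejected(self):
        # max abundance <= 0.05 forces H' >= ln 20 ~ 2.996: a target of 2.5
        # cannot be reached and must be refused, not silently missed
        with pytest.raises(ConfigurationError):
            design_community(_candidates(40), 2.5, 0.05, 40, seed=2)

    @pytest.mark.parametrize("cap", [0.05, 0.80])
    def test_dominance_cap_never_exceeded(self, cap):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = int(rng.integers(max(2, math.ceil(1 / cap)), 60))
            h_max = math.log(s)
            h_min = shannon_entropy(np.full(math.ceil(1 / cap), cap)[:s])
            h = float(rng.uniform(min(h_min + 0.2, h_max), h_max))
            profile = design_community(_candidates(s), h, cap, s,
                                       seed=int(rng.integers(2**31)))
            assert profile.abundances.max() <= cap + 1e-12

    def test_entropy_recovery_over_random_feasible_configs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = int(rng.integers(5, 50))
            cap = float(rng.uniform(2.0 / s, 1.0))
            h = float(rng.uniform(math.log(math.ceil(1 / cap)) + 0.1,
                                  math.log(s)))
            profile = design_community(_candidates(s), h, cap, s,
                                       seed=int(rng.integers(2**31)))
            assert abs(profile.shannon() - h) <= 1e-3

    def test_infeasible_entropy_rejected(self):
        with pytest.raises(ConfigurationError):
            design_community(_candidates(5), math.log(5) + 0.5, 1.0, 5)

    def test_infeasible_cap_rejected(self):
        with pytest.raises(ConfigurationError):
            design_community(_candidates(5), 1.0, 0.1, 5)

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ConfigurationError):
            design_community(_candidates(3), 1.0, 1.0, 5)


class TestRarefaction:
    def test_fit_close_to_monte_carlo_for_uniform_profile(self):
        profile = CommunityProfile([(f"g{i}", f"t{i}", 0.1) for i in range(10)])
        curve = fit_rarefaction(1000, 10, profile)
        rng = np.random.default_rng(5)
        mc = np.mean([
            np.count_nonzero(rng.multinomial(1000, profile.abundances))
            for _ in range(100)
        ])
        assert curve.predict(1000) == pytest.approx(mc, rel=0.05)

    def test_single_taxon_profile_degenerate(self):
        profile = CommunityProfile([("g0", "t0", 1.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            curve = fit_rarefaction(500, 1, profile)
        assert curve.degenerate
        grid = np.arange(0, 501)
        assert np.all(curve.predict(grid) <= 1.0 + 1e-6)
        assert curve.anchors[-1] == (500.0, 1.0)

    def test_curve_passes_through_anchors(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            s = int(rng.integers(3, 30))
            profile = design_community(_candidates(s), 0.8 * math.log(s), 1.0,
                                       s, seed=int(rng.integers(2**31)))
            curve = fit_rarefaction(2000, s, profile)
            for n, expected in curve.anchors:
                assert curve.predict(n) == pytest.approx(expected, abs=0.05 * s)

    def test_expected_accumulation_is_concave_increasing(self):
        p = np.array([0.5, 0.3, 0.2])
        grid = np.arange(0, 50)
        values = expected_accumulation(p, grid)
        diffs = np.diff(values)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 1e-12)


class TestFragmentSampling:
    def test_zero_reads(self):
        assert sample_fragments("ACGT" * 500, 0, 350, 600) == []

    def test_short_genome_rejected(self):
        with pytest.raises(GenomeTooShortError):
            sample_fragments("ACGT" * 10, 5, 350, 600)

    def test_lengths_uniform_and_bounded(self):
        rng = np.random.default_rng(8)
        genome = "".join(rng.choice(list("ACGT"), size=100_000))
        reads = sample_fragments(genome, 10_000, 350, 600, seed=9)
        lengths = np.array([r.fragment_length for r in reads])
        assert lengths.min() >= 350 and lengths.max() <= 600
        observed = np.bincount(lengths - 350, minlength=251)
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_coordinates_round_trip(self):
        rng = np.random.default_rng(10)
        genome = "".join(rng.choice(list("ACGT"), size=5_000))
        for read in sample_fragments(genome, 200, 350, 600, seed=11):
            slice_ = genome[read.start:read.end]
            if read.strand == "+":
                assert read.sequence == slice_
            else:
                assert read.sequence == reverse_complement(slice_)


class TestErrorModel:
    def _read(self, seq):
        from metaconsist.simulate import SimulatedRead

        return SimulatedRead("r0", seq, "g0", "t0", 0, len(seq), "+")

    def test_zero_rates_identity(self):
        read = self._read("ACGTACGTAACCGGTT")
        out = apply_error_model(read, 0.0, 0.0, seed=1)
        assert out.sequence == read.sequence
        assert out.n_substitutions == 0 and out.n_homopolymer_edits == 0

    def test_saturated_substitution_changes_every_base(self):
        seq = "ACGT" * 100
        out = apply_error_model(self._read(seq), 0.999999999, 0.0, seed=2)
        assert all(a != b for a, b in zip(seq, out.sequence))
        assert out.n_substitutions == len(seq)

    def test_substitution_rate_recovered(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        out = apply_error_model(self._read(seq), 0.01, 0.0, seed=13)
        n = len(seq)
        se = math.sqrt(0.01 * 0.99 / n)
        assert abs(out.n_substitutions / n - 0.01) <= 3 * se
        realized = sum(a != b for a, b in zip(seq, out.sequence))
        assert realized == out.n_substitutions

    def test_homopolymer_edits_change_length_only(self):
        seq = "AAAACCCCGGGGTTTT" * 20
        out = apply_error_model(self._read(seq), 0.0, 0.2, seed=14)
        assert out.n_homopolymer_edits > 0
        assert abs(len(out.sequence) - len(seq)) <= out.n_homopolymer_edits


class TestWholeSimulation:
    def _config(self, records, g2t, **kw):
        defaults = dict(h_target=1.4, n_reads=500, max_taxa=5,
                        dominance_cap=0.8, seed=21)
        defaults.update(kw)
        return SimulationConfig(
            genome_set=[(g, g2t[g], s) for g, s in records], **defaults)

    def test_exact_read_count_and_truth_rows(self, mock_world):
        cfg = self._config(mock_world["records"],
                           mock_world["genome_to_taxon"])
        fasta, truth = simulate_metagenome(cfg)
        assert fasta.count(">") == 500
        assert len(truth.strip().splitlines()) == 2 + 500  # header lines

    def test_single_genome_truth(self, mock_world):
        records = mock_world["records"][:1]
        cfg = self._config(records, mock_world["genome_to_taxon"],
                           h_target=0.0, max_taxa=1, dominance_cap=1.0,
                           n_reads=100)
        _, reads = simulate_reads(cfg)
        assert {r.source_genome_id for r in reads} == {records[0][0]}

    def test_same_seed_byte_identical(self, mock_world):
        cfg = self._config(mock_world["records"],
                           mock_world["genome_to_taxon"], n_reads=300)
        assert simulate_metagenome(cfg) == simulate_metagenome(cfg)


class TestDivergeGenome:
    def test_zero_rates_identity(self):
        seq = "ACGT" * 100
        assert diverge_genome(seq, 0.0, 0.0, seed=1) == seq

    def test_identity_tracks_substitution_rate(self):
        import edlib

        rng = np.random.default_rng(15)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        out = diverge_genome(seq, 0.1, 0.0, seed=16)
        window = 1000
        dist = edlib.align(seq[:window], out[:window], task="distance")
        identity = 1.0 - dist["editDistance"] / window
        assert identity == pytest.approx(0.90, abs=0.02)

    def test_indels_change_length_within_bounds(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        out = diverge_genome(seq, 0.0, 0.05, seed=18)
        # insertions and deletions each ~5%: length stays near the original
        assert abs(len(out) - len(seq)) < 0.02 * len(seq)


class TestMockGenomes:
    def test_single_genome_full_lineage(self):
        records, taxonomy_tsv, g2t = make_mock_genomes(1, 2000, seed=1)
        tree = load_taxonomy_table(taxonomy_tsv.splitlines())
        lin = tree.lineage(g2t[records[0][0]])
        assert all(v != "NO_RANK" for v in lin.values())

    def test_gc_content_realized(self):
        records, _, _ = make_mock_genomes(1, 100_000, gc_content=0.5, seed=2)
        seq = records[0][1]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.01)

    def test_taxonomy_loads_and_separates_genomes(self):
        records, taxonomy_tsv, g2t = make_mock_genomes(8, 1000, seed=3)
        tree = load_taxonomy_table(taxonomy_tsv.splitlines())
        # adjacent genomes share a genus; index-distant ones split higher up
        assert tree.lca([g2t["genome_000"], g2t["genome_001"]]).startswith("gen")
        assert tree.lca([g2t["genome_000"], g2t["genome_007"]]) == "ord_000"
        for rank in CANONICAL_RANKS:
            assert tree.project_to_rank(g2t["genome_000"], rank) != "NO_RANK"
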