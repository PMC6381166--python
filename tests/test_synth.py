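"""Simulator: closed-form first-nucleotide oracle, genome composition,
phasing structure, determinism, and the wt/mutant pairing contract."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from pirnabias.composition import first_nt_frequencies
from pirnabias.core import revcomp
from pirnabias.synth import (GatingModel, SL_MUTANT, WT,
                             expected_first_nt_freqs, simulate_genome,
                             simulate_library)

UNIFORM = {b: 0.25 for b in "ACGT"}
NO_GATING = dict(w_proc={b: 1.0 for b in "ACGT"},
                 a_sl={b: 1.0 for b in "ACGT"},
                 body_weight=0.0, multimap_frac=0.0)


class TestExpectedFirstNtFreqs:
    def test_uniform_model_is_uniform(self):
        model = GatingModel(cluster_base_freqs=UNIFORM, **NO_GATING)
        freqs = expected_first_nt_freqs(model)
        assert freqs == pytest.approx({b: 0.25 for b in "UAGC"})

    @pytest.mark.parametrize("condition, expected", [
        (WT, {"U": 0.683, "C": 0.124}),
        (SL_MUTANT, {"U": 0.646, "C": 0.172}),
    ])
    def test_default_calibration(self, default_model, condition, expected):
        freqs = expected_first_nt_freqs(default_model, condition)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)
        for base, value in expected.items():
            assert freqs[base] == pytest.approx(value, abs=1e-3)

    def test_rejecting_everything_raises(self):
        model = GatingModel(cluster_base_freqs={"A": 1.0, "C": 0, "G": 0, "T": 0},
                            w_proc={"T": 1, "A": 0, "G": 1, "C": 1})
        with pytest.raises(ValueError):
            expected_first_nt_freqs(model)


class TestGatingModelValidation:
    def test_w_proc_u_convention_enforced(self):
        with pytest.raises(ValueError, match="w_proc"):
            GatingModel(w_proc={"T": 0.9, "A": 0.2, "G": 0.2, "C": 0.4})

    def test_pmf_must_sum_to_one(self):
        with pytest.raises(ValueError, match="length_pmf"):
            GatingModel(length_pmf={26: 0.5, 27: 0.4})

    def test_u_keys_accepted(self):
        model = GatingModel(w_proc={"U": 1.0, "A": 0.2, "G": 0.2, "C": 0.4})
        assert model.w_proc["T"] == 1.0


class TestSimulateGenome:
    def test_uniform_composition(self):
        genome, clusters = simulate_genome(n_contigs=1, contig_len=40_000,
                                           n_clusters=2, cluster_len=10_000,
                                           cluster_base_freqs=UNIFORM, seed=0)
        c = clusters[0]
        seq = genome[c.contig][c.start:c.end]
        t_frac = seq.count("T") / len(seq)
        assert abs(t_frac - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_default_composition_on_producing_strand(self):
        genome, clusters = simulate_genome(n_contigs=1, contig_len=70_000,
                                           n_clusters=1, cluster_len=50_000,
                                           seed=5)
        c = clusters[0]
        seq = genome[c.contig][c.start:c.end]
        if c.strand == "-":
            seq = revcomp(seq)
        assert abs(seq.count("T") / len(seq) - 0.30) <= 0.01

    def test_deterministic(self):
        a = simulate_genome(seed=9, n_contigs=1, contig_len=50_000,
                            n_clusters=2, cluster_len=10_000)
        b = simulate_genome(seed=9, n_contigs=1, contig_len=50_000,
                            n_clusters=2, cluster_len=10_000)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_overfull_contig_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_genome(n_contigs=1, contig_len=30_000, n_clusters=3,
                            cluster_len=10_000)

    def test_per_cluster_freqs_must_match_count(self):
        with pytest.raises(ValueError, match="per-cluster"):
            simulate_genome(n_contigs=1, contig_len=100_000, n_clusters=2,
                            cluster_len=10_000, cluster_base_freqs=[UNIFORM])


@pytest.fixture(scope="module")
def small_genome():
    return simulate_genome(n_contigs=1, contig_len=140_000, n_clusters=2,
                           cluster_len=50_000, seed=7)


class TestSimulateLibrary:
    def test_no_gating_recovers_cluster_composition(self, small_genome):
        genome, clusters = small_genome
        model = GatingModel(**NO_GATING)
        reads, _ = simulate_library(genome, clusters, model, n_reads=20_000, seed=7)
        freqs = first_nt_frequencies(reads).freqs
        sigma = np.sqrt(0.3 * 0.7 / 20_000)
        for base, f in (("U", 0.30), ("A", 0.28), ("G", 0.23), ("C", 0.19)):
            assert abs(freqs[base] - f) <= 3 * sigma + 0.003

    def test_default_wt_first_nt_matches_closed_form(self, paired_libraries):
        freqs = first_nt_frequencies(paired_libraries[WT].kept).freqs
        assert freqs["U"] == pytest.approx(0.683, abs=0.02)

    def test_absorbing_rejection_of_c(self, small_genome):
        genome, clusters = small_genome
        model = GatingModel(a_sl={"T": 1, "A": 1, "G": 1, "C": 0.0},
                            multimap_frac=0.0)
        reads, truth = simulate_library(genome, clusters, model, n_reads=5_000, seed=3)
        assert not (truth.reads["first_nt"] == "C").any()
        assert all(r.first_nt != "C" for r in reads)

    def test_deterministic(self, small_genome, default_model):
        genome, clusters = small_genome
        a, _ = simulate_library(genome, clusters, default_model, n_reads=2_000, seed=5)
        b, _ = simulate_library(genome, clusters, default_model, n_reads=2_000, seed=5)
        assert a == b

    def test_lengths_in_pmf_support(self, small_genome, default_model):
        genome, clusters = small_genome
        reads, _ = simulate_library(genome, clusters, default_model,
                                    n_reads=5_000, seed=6)
        assert {len(r) for r in reads} <= set(default_model.length_pmf)

    def test_reads_lie_within_truth_clusters(self, small_genome, default_model):
        genome, clusters = small_genome
        reads, truth = simulate_library(genome, clusters, default_model,
                                        n_reads=5_000, seed=6)
        for row in truth.reads.itertuples():
            c = truth.clusters[row.cluster]
            assert c.contig == row.contig
            assert c.start <= row.start and row.end <= c.end

    def test_primary_sequences_match_genome(self, small_genome, default_model):
        genome, clusters = small_genome
        reads, _ = simulate_library(genome, clusters, default_model,
                                    n_reads=1_000, seed=8)
        for r in reads:
            if not r.is_primary:
                continue
            slice_ = genome[r.contig][r.start:r.end]
            assert r.sequence == (slice_ if r.strand == "+" else revcomp(slice_))

    def test_wt_is_subset_of_mutant_at_same_seed(self, small_genome, default_model):
        genome, clusters = small_genome
        wt, _ = simulate_library(genome, clusters, default_model, n_reads=10_000,
                                 condition=WT, seed=11)
        mut, _ = simulate_library(genome, clusters, default_model, n_reads=15_000,
                                  condition=SL_MUTANT, seed=11)
        wt_keys = {(r.contig, r.start, r.end, r.strand) for r in wt if r.is_primary}
        mut_keys = {(r.contig, r.start, r.end, r.strand) for r in mut if r.is_primary}
        assert wt_keys <= mut_keys

    def test_multimap_fraction(self, small_genome, default_model):
        genome, clusters = small_genome
        n = 4_000
        reads, _ = simulate_library(genome, clusters, default_model,
                                    n_reads=n, seed=12)
        primaries = [r for r in reads if r.is_primary]
        secondaries = [r for r in reads if not r.is_primary]
        assert len(primaries) == n
        assert len(secondaries) == round(default_model.multimap_frac * n)
        assert all(r.multiplicity == 2 for r in secondaries)

    def test_empty_cluster_set_rejected(self, small_genome, default_model):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            simulate_library(genome, [], default_model, n_reads=10, seed=0)
        with pytest.raises(ValueError):
            simulate_library(genome, [], default_model, n_reads=0, seed=0)


class TestDistributionalProperties:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_first_nt_chi2_goodness_of_fit(self, demo_genome, default_model, seed):
        """Empirical first-nt counts are consistent with the closed form."""
        genome, clusters = demo_genome
        reads, truth = simulate_library(genome, clusters, default_model,
                                        n_reads=100_000, condition=WT, seed=seed)
        counts = truth.reads["first_nt"].value_counts()
        expected = expected_first_nt_freqs(default_model, WT)
        obs = np.array([counts.get(b, 0) for b in "UAGC"])
        exp = obs.sum() * np.array([expected[b] for b in "UAGC"])
        pvalue = stats.chisquare(obs, exp).pvalue
        assert pvalue > 0.01

    def test_consecutive_phased_distance_mode_is_pmf_mode(self, paired_libraries):
        truth = paired_libraries[WT].truth.reads.sort_values(["chain", "cut_index"])
        nxt_start = truth.groupby("chain")["start"].shift(-1)
        nxt_cut = truth.groupby("chain")["cut_index"].shift(-1)
        phased = nxt_cut == truth["cut_index"] + 1
        distances = (nxt_start[phased] - truth.loc[phased, "start"]).abs()
        assert distances.mode().iloc[0] == 26
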