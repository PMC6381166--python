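"""Shared fixtures: simulated genomes and libraries reused across the suite.

All simulations are session-scoped so expensive libraries are generated once.
Seeds are fixed so every test is deterministic.
"""
from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from pirnabias.filters import filter_by_length, filter_by_mapping
from pirnabias.metagene import metagene_profile
from pirnabias.synth import (GatingModel, SL_MUTANT, WT, simulate_genome,
                             simulate_library)


@pytest.fixture(scope="session")
def default_model() -> GatingModel:
    return GatingModel.default()


@pytest.fixture(scope="session")
def demo_genome():
    """Default-geometry genome: 12 x 200 kb clusters on 2 x 1.4 Mb contigs."""
    return simulate_genome(seed=1)


def _library(genome, clusters, model, n_reads, condition, seed):
    reads, truth = simulate_library(genome, clusters, model, n_reads=n_reads,
                                    condition=condition, seed=seed)
    kept = filter_by_mapping(filter_by_length(reads, 24, 29), mode="unique")
    return SimpleNamespace(reads=reads, kept=kept, truth=truth)


@pytest.fixture(scope="session")
def paired_libraries(demo_genome, default_model):
    """Matched wt and SL-mutant libraries (n=100,000 each, same seed/genome)."""
    genome, clusters = demo_genome
    return {cond: _library(genome, clusters, default_model, 100_000, cond, seed=1)
            for cond in (WT, SL_MUTANT)}


@pytest.fixture(scope="session")
def paired_profiles(paired_libraries, demo_genome):
    genome, _ = demo_genome
    return {cond: metagene_profile(lib.kept, genome)
            for cond, lib in paired_libraries.items()}


@pytest.fixture(scope="session")
def deep_wt_library(demo_genome, default_model):
    """Deeper wild-type library (n=200,000) for phasing-peak detection."""
    genome, clusters = demo_genome
    return _library(genome, clusters, default_model, 200_000, WT, seed=2)


@pytest.fixture(scope="session")
def bias_sim(default_model):
    """20 clusters x 50 kb, n=60,000 wt reads: per-cluster bias analysis."""
    genome, clusters = simulate_genome(n_contigs=2, contig_len=600_000,
                                       n_clusters=20, cluster_len=50_000, seed=3)
    lib = _library(genome, clusters, default_model, 60_000, WT, seed=3)
    return SimpleNamespace(genome=genome, clusters=clusters, **vars(lib))


@pytest.fixture(scope="session")
def varied_composition_sim(default_model):
    """25 clusters with producing-strand T content drawn from U(0.22, 0.38)."""
    rng = np.random.default_rng(4)
    freqs = []
    for t in rng.uniform(0.22, 0.38, size=25):
        scale = (1.0 - t) / 0.70  # rescale A/C/G proportionally
        freqs.append({"A": 0.28 * scale, "C": 0.19 * scale,
                      "G": 0.23 * scale, "T": t})
    genome, clusters = simulate_genome(n_contigs=2, contig_len=750_000,
                                       n_clusters=25, cluster_len=50_000,
                                       cluster_base_freqs=freqs, seed=4)
    lib = _library(genome, clusters, default_model, 40_000, WT, seed=4)
    return SimpleNamespace(genome=genome, clusters=clusters, **vars(lib))
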