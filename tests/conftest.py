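"""Shared fixtures: simulated worlds reused across modules to keep runtime low."""

from __future__ import annotations

import numpy as np
import pytest

from scampps.gene_annotation import associate_transcripts, build_gene_model
from scampps.precursor_scan import build_consensus, scan_spliced
from scampps.synthetic_data import SimConfig, make_genome


@pytest.fixture(scope="session")
def sim20():
    """20 genes in 4 clusters at 10% precursor substitution (fixed seed)."""
    cfg = SimConfig(seed=11, n_genes=20, cluster_count=4,
                    precursor_sub_rate=0.10)
    return make_genome(cfg)


@pytest.fixture(scope="session")
def scan20(sim20):
    """Consensus + scan + annotated models for the 20-gene world."""
    profile = build_consensus([t.precursor for t in sim20.truth])
    hits = scan_spliced(sim20.genome, profile)
    models = [build_gene_model(h, sim20.genome) for h in hits]
    associate_transcripts(models, sim20.transcripts, genome=sim20.genome)
    return {"profile": profile, "hits": hits, "models": models}


@pytest.fixture(scope="session")
def sim_fixed():
    """Zero-noise world with fixed-length domains: the consensus then has the
    exact domain slot count, so recovery is unambiguous end to end."""
    cfg = SimConfig(seed=3, n_genes=12, cluster_count=3,
                    domain_len_range=(8, 8), expressed_fraction=0.75)
    return make_genome(cfg)


@pytest.fixture(scope="session")
def scan_fixed(sim_fixed):
    profile = build_consensus([t.precursor for t in sim_fixed.truth])
    hits = scan_spliced(sim_fixed.genome, profile)
    models = [build_gene_model(h, sim_fixed.genome) for h in hits]
    associate_transcripts(models, sim_fixed.transcripts,
                          genome=sim_fixed.genome)
    return {"profile": profile, "hits": hits, "models": models}


@pytest.fixture(scope="session")
def sim_small():
    """A compact single-cluster world for fast structural tests."""
    cfg = SimConfig(seed=5, n_genes=5, cluster_count=1,
                    inter_cluster_gap=50_000)
    return make_genome(cfg)


@pytest.fixture(scope="session")
def profile_small(sim_small):
    return build_consensus([t.precursor for t in sim_small.truth])


@pytest.fixture(scope="session")
def scan_small(sim_small, profile_small):
    return scan_spliced(sim_small.genome, profile_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
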