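"""Shared fixtures: tiny hand-built genomes for unit tests and
session-scoped simulated studies for pipeline-level tests."""
import numpy as np
import pandas as pd
import pytest

import dvnpchrom as dc


@pytest.fixture
def tiny_genome():
    """One 1000 bp chromosome with a known sequence."""
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    return dc.Genome({"chrI": 1000}, {"chrI": seq})


@pytest.fixture
def two_chrom_genome():
    return dc.Genome({"chrI": 1500, "chrII": 499})


@pytest.fixture
def flat_genes():
    """Two genes, one per strand, away from chromosome edges."""
    tab = pd.DataFrame({
        "id": ["gp", "gm"],
        "chrom": ["chrI", "chrI"],
        "strand": ["+", "-"],
        "tss": [300, 800],
        "polya": [500, 600],
    })
    return dc.GeneAnnotation(tab)


@pytest.fixture(scope="session")
def default_study():
    """Full-default simulated study (nucleoprotein-coupled loss, stability
    protection, promoter-proximal binding boost)."""
    return dc.simulate_chromatin_study(seed=11)


@pytest.fixture(scope="session")
def assoc_study():
    """Clean enrichment-coupled loss study: beta>0, gamma=0, no positional
    boost — the quintile-association recovery scenario."""
    return dc.simulate_chromatin_study(seed=12, stability_coupling=0.0,
                                       promoter_boost=1.0)


@pytest.fixture(scope="session")
def stability_study():
    """Stability-protection study: gamma>0, loss scaled by 1/weight, no
    between-gene binding heterogeneity."""
    return dc.simulate_chromatin_study(seed=13, gene_affinity_sd=0.0,
                                       n_mnase=400_000)


def occupancy_tracks(study):
    ctrl = dc.mnase_occupancy_track(study.mnase_control, study.genome)
    dvnp = dc.mnase_occupancy_track(study.mnase_dvnp, study.genome)
    return ctrl, dvnp


def chip_tracks(study):
    ip = dc.mnase_occupancy_track(study.chip_ip, study.genome,
                                  size_range=(50, 500))
    inp = dc.mnase_occupancy_track(study.chip_input, study.genome,
                                   size_range=(50, 500))
    return ip, inp
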