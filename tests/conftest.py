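"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

from rilmap import assoc, binmap, simpop


@pytest.fixture(scope="session")
def small_genome():
    """Four 5-Mb chromosomes at the default SNP density (desk scale)."""
    return simpop.default_genome(n_chromosomes=4)


@pytest.fixture(scope="session")
def ril_population(small_genome):
    """A noisy 120-line F10 population with truth, bin map and kinship."""
    cfg = simpop.RILSimConfig(
        n_lines=120,
        selfing_generations=9,
        genotyping_error_rate=0.01,
        missing_rate=0.05,
    )
    rng = np.random.default_rng(20240901)
    gm, truth = simpop.simulate_ril_population(cfg, small_genome, rng)
    pbm, tracks = binmap.build_binmap(gm)
    dm = assoc.dosage_matrix(pbm)
    K = assoc.kinship_matrix(dm)
    return {
        "genome": small_genome,
        "gm": gm,
        "truth": truth,
        "pbm": pbm,
        "tracks": tracks,
        "dm": dm,
        "K": K,
        "rng_seed": 20240901,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
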