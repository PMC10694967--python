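"""Shared fixtures: desk-scale replicate simulations reused across the suite.

The heavy scenario families (panmictic recovery, two-deme migration at
several rates, admixture, inversion) are simulated once per session at
desk scale (10 replicates each, fixed seeds) and reused by the unit,
property and acceptance tests.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from structne import (EstimatorConfig, build_genotype_matrix, draw_sample,
                      estimate_ne, load_preset, run_scenario)
from structne.config import (GenomeConfig, SampleSpec, ScenarioConfig)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

N_REPLICATES = 10
REPLICATE_SEEDS = tuple(range(1, N_REPLICATES + 1))


def simulate_replicates(preset_name: str, seeds=REPLICATE_SEEDS):
    sc = load_preset(preset_name)
    return [(replace(sc, seed=s), run_scenario(replace(sc, seed=s))) for s in seeds]


def cohort(sc, states, scheme=None, focal=0, seed=0, maf=0.05):
    """Draw the genotyped cohort and build its dosage matrix."""
    spec = sc.sample if scheme is None else SampleSpec(sc.sample.total_sample,
                                                       scheme, focal)
    rng = np.random.default_rng(seed)
    draw = draw_sample(states, spec, rng)
    return build_genotype_matrix(states, draw, sc.genome, maf_min=maf)


def trajectory(gm, seed=0, **kwargs):
    return estimate_ne(gm, EstimatorConfig(seed=seed, **kwargs))


@pytest.fixture(scope="session")
def panmictic_runs():
    """10 replicates of the rescaled constant-size design (N = 200)."""
    return simulate_replicates("panmictic-desk")


@pytest.fixture(scope="session")
def two_deme_nm1_runs():
    return simulate_replicates("two-deme-nm1-desk")


@pytest.fixture(scope="session")
def two_deme_nm2_runs():
    return simulate_replicates("two-deme-nm2-desk")


@pytest.fixture(scope="session")
def two_deme_nm10_runs():
    return simulate_replicates("two-deme-nm10-desk")


@pytest.fixture(scope="session")
def admix_runs():
    """Five long-isolated populations mixed one rescaled time unit ago."""
    return simulate_replicates("synthetic-5pop-n1000-t5-desk")


@pytest.fixture(scope="session")
def inversion_runs():
    """Balanced 20%-of-genome inversion in a constant-size population."""
    return simulate_replicates("inversion-constant-desk")


@pytest.fixture(scope="session")
def toy_scenario():
    """A seconds-scale scenario for IO / estimator / CLI plumbing tests."""
    return ScenarioConfig(
        name="toy", family="panmictic", deme_sizes=(50,),
        total_generations=500,
        genome=GenomeConfig(500_000, 2e-7, 1e-6, 3),
        sample=SampleSpec(30, "single_deme", 0), seed=7)


@pytest.fixture(scope="session")
def toy_states(toy_scenario):
    return run_scenario(toy_scenario)


@pytest.fixture(scope="session")
def toy_gm(toy_scenario, toy_states):
    return cohort(toy_scenario, toy_states, seed=3)
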