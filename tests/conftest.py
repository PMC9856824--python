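"""Shared fixtures: fixture loci, small cohorts, and noise-free simulations."""

from collections import Counter

import pytest
from hypothesis import HealthCheck, settings

from methamplicon.locus_model import (
    make_default_cohort,
    make_default_scheme,
    make_fixture_loci,
)
from methamplicon.synthetic_data import SimulationConfig, simulate_profiles

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def loci():
    return make_fixture_loci()


@pytest.fixture(scope="session")
def gstp1(loci):
    return next(l for l in loci if l.name == "GSTP1")


@pytest.fixture(scope="session")
def kiaa(loci):
    return next(l for l in loci if l.name == "KIAA1539")


@pytest.fixture(scope="session")
def small_cohort():
    return make_default_cohort(n_case=4, n_control=3, molecules_per_sample=150)


@pytest.fixture(scope="session")
def small_scheme(loci, small_cohort):
    return make_default_scheme(loci, small_cohort)


def noise_free_config(seed=11, molecules=150, **kw):
    return SimulationConfig(
        seed=seed,
        molecules_per_sample=molecules,
        conversion_failure_rate=0.0,
        sequencing_error_rate=0.0,
        chimera_rate=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def small_truth(loci, small_cohort):
    cfg = noise_free_config()
    return cfg, simulate_profiles(cfg, loci, small_cohort)


def toy_methylome(profile_counts: dict[str, int], sample="S1", locus="LOC"):
    """A single-sample methylome from raw profile->count pairs."""
    return {(sample, locus): Counter(profile_counts)}
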