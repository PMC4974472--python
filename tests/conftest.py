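import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

import paeffect as pa
from paeffect import glmm, measures, spatial


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    return pa.generate_world(
        pa.WorldConfig(n_studies=12, sites_per_study=(8, 16), random_seed=42)
    )


@pytest.fixture(scope="session")
def matched_fixture():
    return pa.generate_matched_fixture()


@pytest.fixture(scope="session")
def classified_world(small_world):
    pas = spatial.read_protected_areas(small_world.protected_areas)
    return spatial.assign_protection(small_world.sites, pas)


@pytest.fixture(scope="session")
def analysis_table(small_world, classified_world):
    m = measures.compute_site_measures(
        small_world.community, small_world.sites, small_world.ranges
    )
    return glmm.prepare_analysis_table(m, classified_world)
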