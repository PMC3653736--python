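"""Shared fixtures: calibrated family profiles and genome factories.

Profiles are expensive enough to build once per session; everything else is
generated per-test from fixed seeds.
"""

from __future__ import annotations

import pytest

from rnrscape.profile_engine import ProfileModel, build_profile, calibrate
from rnrscape.synthetic_data import ScenarioConfig, gen_family_seeds

SESSION_SEED = 1


@pytest.fixture(scope="session")
def scenario_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def family_seeds(scenario_config):
    """(msas, ancestors) for all nine families at the default divergence."""
    return gen_family_seeds(scenario_config, SESSION_SEED)


@pytest.fixture(scope="session")
def ancestors(family_seeds):
    return family_seeds[1]


@pytest.fixture(scope="session")
def profiles(family_seeds) -> list[ProfileModel]:
    """Calibrated profiles for all nine families."""
    msas, _ = family_seeds
    return [
        calibrate(build_profile(msa, fam), seed=7 + i)
        for i, (fam, msa) in enumerate(sorted(msas.items()))
    ]


@pytest.fixture(scope="session")
def profiles_by_family(profiles) -> dict[str, ProfileModel]:
    return {p.family: p for p in profiles}
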