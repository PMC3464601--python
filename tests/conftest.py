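"""Shared fixtures.

Expensive large-cohort simulations are session-scoped so that parameter
recovery, calibration and direction checks share one generation each.
"""

from __future__ import annotations

import pandas as pd
import pytest

from hddlink.config import (
    DEFAULT_LINKAGE_PASSES,
    CorruptionSpec,
    ExperimentConfig,
    SimulationConfig,
)
from hddlink.linkage import LinkagePass, link_records, standardise_keys
from hddlink.pipeline import run_experiment
from hddlink.synthetic import corrupt_linkage_keys, simulate_cohort

BIG_N = 20_000
BIG_SEED = 1234


def degenerate_config(n_persons: int = 400, **overrides) -> SimulationConfig:
    """All nuisance processes off: one acute emergency index episode per
    incident event, everyone community-dwelling, keys uncorrupted."""
    kw = dict(
        n_persons=n_persons,
        fracture_hazard=1.0,
        nursing_home_fraction=0.0,
        second_fracture_prob=0.0,
        transfer_prob=0.0,
        readmission_30d_prob=0.0,
        readmission_120d_prob=0.0,
        revision_readmission_prob=0.0,
        nonacute_episode_prob=0.0,
        inhospital_death_prob=0.0,
        nonfracture_fall_rate=0.0,
        shared_medicare_prob=0.0,
        hospital_acquired_prob=0.0,
        key_corruption=CorruptionSpec.none(),
        seed=5,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def big_sim():
    """Default-condition cohort at n=20,000 (uncorrupted keys as emitted)."""
    cfg = SimulationConfig(n_persons=BIG_N, seed=BIG_SEED)
    episodes, truth = simulate_cohort(cfg, BIG_SEED)
    return cfg, episodes, truth


@pytest.fixture(scope="session")
def big_linkage(big_sim):
    """Corrupted, standardised and linked version of the big cohort."""
    cfg, episodes, truth = big_sim
    corrupted = corrupt_linkage_keys(episodes, truth, cfg.key_corruption, BIG_SEED + 1)
    std = standardise_keys(corrupted)
    result = link_records(std, [LinkagePass(tuple(p)) for p in DEFAULT_LINKAGE_PASSES])
    return std, result


@pytest.fixture(scope="session")
def default_run():
    """A full default-condition pipeline run at n=10,000."""
    cfg = ExperimentConfig(
        simulation=SimulationConfig(n_persons=10_000), seed=BIG_SEED
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def perfect_coding_run():
    """n=20,000 cohort with every true condition coded on every episode,
    no hospital-acquired onset flags, uncorrupted keys — plus the reference
    incidents selected on the true person partition."""
    from hddlink.selection import extract_fall_injury_episodes, select_reference_standard

    cfg = SimulationConfig(
        n_persons=BIG_N, per_episode_coding_prob=1.0,
        hospital_acquired_prob=0.0, key_corruption=CorruptionSpec.none(),
        seed=77,
    )
    episodes, truth = simulate_cohort(cfg, 77)
    extracted = extract_fall_injury_episodes(episodes)
    assignment = truth.episodes.set_index("episode_id")["true_person_id"]
    incidents, _ = select_reference_standard(extracted, assignment)
    return cfg, truth, extracted, incidents


@pytest.fixture()
def tiny_episode_frame():
    """Hand-written four-episode frame exercising the code filters."""
    return pd.DataFrame(
        [
            # retained by extraction, hip fracture
            dict(episode_id=1, ext_mechanism="W05", principal_diagnosis="S72.1",
                 age_at_admission=70),
            # T80 = complication of medical care: outside S00-T75/T79
            dict(episode_id=2, ext_mechanism="W10", principal_diagnosis="T80",
                 age_at_admission=80),
            # age below 65
            dict(episode_id=3, ext_mechanism="W00", principal_diagnosis="S72.0",
                 age_at_admission=64),
            # retained by extraction, not hip fracture
            dict(episode_id=4, ext_mechanism="W19", principal_diagnosis="T79.0",
                 age_at_admission=90),
        ]
    )
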