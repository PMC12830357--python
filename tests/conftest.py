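import dataclasses

import pytest

from n2oaudit import simulate
from n2oaudit.footprint import GasConstants
from n2oaudit.model import EPISODE_COLUMNS, SedationEpisode


def make_episode(**overrides) -> SedationEpisode:
    base = dict(
        episode_id="E1",
        service_id="S1",
        site_id="T1",
        age_years=8,
        sex="female",
        asa_grade=1,
        flow_rate_lpm=5.0,
        max_n2o_fraction=0.30,
        duration_min=20.0,
        procedure="extraction",
        success=True,
        acclimatisation_only=False,
    )
    base.update(overrides)
    return SedationEpisode(**base)


def episode_row(**overrides) -> dict:
    """A valid CSV row for the episodes schema."""
    base = dict(
        episode_id="E1",
        service_id="S1",
        site_id="T1",
        age_years="8",
        sex="female",
        asa_grade="1",
        flow_lpm="5",
        max_n2o_pct="30",
        duration_min="20",
        procedure="extraction",
        success="true",
        acclimatisation_only="false",
    )
    base.update({k: str(v) for k, v in overrides.items()})
    return base


def write_csv(path, rows, columns=EPISODE_COLUMNS):
    lines = [",".join(columns)]
    lines += [",".join(str(row[c]) for c in columns) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def constants():
    return GasConstants()


@pytest.fixture
def worked_example_episode():
    """Flow 5 LPM, maximum titration 30%, 20 minutes."""
    return make_episode()


@pytest.fixture(scope="session")
def calibrated_rho():
    """Session-wide calibrated copula correlation for the default targets."""
    return simulate.calibrate_dependence(
        simulate.GeneratorParams(seed=1), n_pilot=400_000, tolerance=0.02
    )


@pytest.fixture(scope="session")
def calibrated_cohort_10k(calibrated_rho):
    params = dataclasses.replace(
        simulate.GeneratorParams(seed=7),
        n_episodes=10_000,
        dependence_param=calibrated_rho,
    )
    return simulate.generate_cohort(params)
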