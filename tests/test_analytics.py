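import numpy as np
import pytest

from n2oaudit import simulate
from n2oaudit.analytics import (
    flow_age_correlation,
    flow_age_table,
    ivs_eligible,
    national_rollup,
    success_by_acclimatisation_policy,
    summarise_service,
)
from n2oaudit.footprint import GasConstants

from .conftest import make_episode

UNIT_CONSTANTS = GasConstants(density_kg_per_l=1.0, gwp=1.0)  # co2e == volume


class TestIvsEligible:
    @pytest.mark.parametrize(
        "age,asa,expected",
        [
            (12, 2, True),  # boundary of the criterion
            (12, 1, True),
            (11, 1, False),
            (30, 3, False),
            (100, 2, True),
            (0, 1, False),
        ],
    )
    def test_cases(self, age, asa, expected):
        assert ivs_eligible(age, asa) is expected

    def test_invalid_asa(self):
        with pytest.raises(ValueError):
            ivs_eligible(30, 7)
        with pytest.raises(ValueError):
            ivs_eligible(30, 0)

    def test_invalid_age(self):
        with pytest.raises(ValueError):
            ivs_eligible(-1, 1)


class TestSummariseService:
    def test_arithmetic_mean(self):
        episodes = [
            make_episode(episode_id="a", flow_rate_lpm=1.0, max_n2o_fraction=1.0, duration_min=10.0),
            make_episode(episode_id="b", flow_rate_lpm=1.0, max_n2o_fraction=1.0, duration_min=20.0),
        ]
        summary = summarise_service(episodes, UNIT_CONSTANTS)
        assert summary.total_co2e_kg == 30.0
        assert summary.mean_co2e_kg_per_episode == 15.0
        assert summary.n_episodes == 2

    def test_single_worked_example_episode(self, worked_example_episode):
        summary = summarise_service([worked_example_episode])
        assert summary.mean_co2e_kg_per_episode == summary.total_co2e_kg
        assert summary.total_co2e_kg == pytest.approx(15.77, abs=0.01)

    def test_empty_collection_is_error(self):
        with pytest.raises(ValueError):
            summarise_service([])

    def test_mixed_services_rejected(self):
        episodes = [make_episode(service_id="S1"), make_episode(service_id="S2")]
        with pytest.raises(ValueError):
            summarise_service(episodes)

    def test_rates(self):
        episodes = [
            make_episode(episode_id="a", age_years=11, asa_grade=1, success=True),
            make_episode(episode_id="b", age_years=20, asa_grade=2, success=False),
            make_episode(episode_id="c", age_years=20, asa_grade=3, success=True),
            make_episode(episode_id="d", age_years=10, asa_grade=1, success=True),
        ]
        summary = summarise_service(episodes)
        assert summary.success_rate == 0.75
        assert summary.eligibility_rate == 0.25  # only episode b
        assert summary.paediatric_fraction == 0.5  # a (11) and d (10)

    def test_synthetic_891_calibrated_mean(self, calibrated_rho):
        import dataclasses

        params = dataclasses.replace(
            simulate.GeneratorParams(seed=11), dependence_param=calibrated_rho
        )
        cohort = simulate.generate_cohort(params)
        by_service = {}
        for e in cohort.episodes:
            by_service.setdefault(e.service_id, []).append(e)
        summaries = [summarise_service(eps) for eps in by_service.values()]
        rollup = national_rollup(summaries)
        # Monte-Carlo tolerance: sd of the 891-episode mean is ~0.3 kg with
        # antithetic draws; 1.5 kg is a 5-sigma bound
        assert rollup.mean_co2e_kg_per_episode == pytest.approx(28.62, abs=1.5)


class TestSuccessByAcclimatisationPolicy:
    @staticmethod
    def _service(service_id, n_success, n_total):
        return [
            make_episode(episode_id=f"{service_id}-{i}", service_id=service_id,
                         success=i < n_success)
            for i in range(n_total)
        ]

    def test_means_of_stated_rates(self):
        groups = [
            ("A", self._service("A", 90, 100), True),
            ("B", self._service("B", 92, 100), True),
            ("C", self._service("C", 94, 100), False),
        ]
        offering, not_offering = success_by_acclimatisation_policy(groups)
        assert offering == pytest.approx(0.91)
        assert not_offering == pytest.approx(0.94)

    def test_degenerate_all_succeed(self):
        groups = [
            ("A", self._service("A", 5, 5), True),
            ("B", self._service("B", 3, 3), False),
        ]
        assert success_by_acclimatisation_policy(groups) == (1.0, 1.0)

    def test_empty_group_is_missing_not_zero(self):
        groups = [("A", self._service("A", 1, 2), True)]
        offering, not_offering = success_by_acclimatisation_policy(groups)
        assert offering == 0.5
        assert not_offering is None

    def test_episode_weighting_option(self):
        groups = [
            ("A", self._service("A", 1, 2), True),  # 0.5 over 2 episodes
            ("B", self._service("B", 8, 8), True),  # 1.0 over 8 episodes
        ]
        service_pooled, _ = success_by_acclimatisation_policy(groups)
        episode_pooled, _ = success_by_acclimatisation_policy(groups, weighting="episode")
        assert service_pooled == pytest.approx(0.75)
        assert episode_pooled == pytest.approx(0.9)

    def test_parameter_recovery_on_simulation(self, calibrated_rho):
        import dataclasses

        params = dataclasses.replace(
            simulate.GeneratorParams(seed=3),
            n_episodes=20_000,
            dependence_param=calibrated_rho,
        )
        cohort = simulate.generate_cohort(params)
        policy = {s.service_id: s.offers_acclimatisation for s in cohort.services}
        by_service = {}
        for e in cohort.episodes:
            by_service.setdefault(e.service_id, []).append(e)
        groups = [(sid, eps, policy[sid]) for sid, eps in by_service.items()]
        offering, not_offering = success_by_acclimatisation_policy(
            groups, weighting="episode"
        )
        # binomial error at ~12k/8k episodes per group is ~0.003; allow 4 sigma
        assert offering == pytest.approx(0.91, abs=0.012)
        assert not_offering == pytest.approx(0.94, abs=0.012)


class TestNationalRollup:
    def test_single_service_identity(self):
        summary = summarise_service([make_episode()], UNIT_CONSTANTS)
        rollup = national_rollup([summary], anonymise=False)
        assert rollup.n_services == 1
        assert rollup.mean_co2e_kg_per_episode == summary.mean_co2e_kg_per_episode
        assert rollup.total_co2e_kg == summary.total_co2e_kg
        assert rollup.services[0] == summary

    def test_mean_of_weekly_totals(self):
        s1 = [
            make_episode(episode_id="a", service_id="S1", flow_rate_lpm=1.0,
                         max_n2o_fraction=1.0, duration_min=100.0)
        ]
        s2 = [
            make_episode(episode_id="b", service_id="S2", flow_rate_lpm=1.0,
                         max_n2o_fraction=1.0, duration_min=300.0)
        ]
        rollup = national_rollup(
            [summarise_service(s1, UNIT_CONSTANTS), summarise_service(s2, UNIT_CONSTANTS)]
        )
        assert rollup.mean_service_total_co2e_kg == 200.0
        assert rollup.service_total_range == (100.0, 300.0)

    def test_pooled_mean_is_episode_weighted(self):
        s1 = summarise_service(
            [make_episode(episode_id=str(i), service_id="S1") for i in range(3)]
        )
        s2 = summarise_service([make_episode(episode_id="x", service_id="S2")])
        rollup = national_rollup([s1, s2])
        expected = (s1.total_co2e_kg + s2.total_co2e_kg) / 4
        assert rollup.mean_co2e_kg_per_episode == expected

    def test_pseudonyms_stable_and_applied(self):
        summaries = [
            summarise_service([make_episode(service_id=sid, episode_id=sid)])
            for sid in ("beta", "alpha")
        ]
        rollup = national_rollup(summaries, anonymise=True)
        assert rollup.pseudonyms == {"alpha": "service-01", "beta": "service-02"}
        assert [s.service_id for s in rollup.services] == ["service-01", "service-02"]

    def test_eligibility_invariant_to_ordering_and_constants(self):
        episodes = [
            make_episode(episode_id=str(i), age_years=10 + i, asa_grade=1 + (i % 3))
            for i in range(6)
        ]
        forward = summarise_service(episodes).eligibility_rate
        reversed_ = summarise_service(list(reversed(episodes))).eligibility_rate
        other_constants = summarise_service(episodes, UNIT_CONSTANTS).eligibility_rate
        assert forward == reversed_ == other_constants

    def test_removing_one_service_leaves_others_unchanged(self):
        summaries = [
            summarise_service(
                [make_episode(episode_id=f"{sid}{i}", service_id=sid,
                              duration_min=10.0 * (i + 1))
                 for i in range(2)]
            )
            for sid in ("S1", "S2", "S3")
        ]
        full = national_rollup(summaries, anonymise=False)
        partial = national_rollup(summaries[:2], anonymise=False)
        kept = {s.service_id: s for s in full.services}
        for s in partial.services:
            assert kept[s.service_id] == s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            national_rollup([])


class TestFlowAge:
    def test_table(self):
        episodes = [make_episode(age_years=8, flow_rate_lpm=5.0),
                    make_episode(age_years=30, flow_rate_lpm=7.0)]
        assert flow_age_table(episodes) == [(8, 5.0), (30, 7.0)]

    def test_correlation_diagnostic(self):
        episodes = [
            make_episode(episode_id=str(i), age_years=i + 1, flow_rate_lpm=float(i + 1))
            for i in range(10)
        ]
        rho, _ = flow_age_correlation(episodes)
        assert rho == pytest.approx(1.0)
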