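"""Service-level and pooled cohort analytics.

Aggregates validated sedation episodes into per-service summaries (totals,
means, success and eligibility rates) and a pooled national rollup with
anonymised service identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .footprint import GasConstants, episode_footprint
from .model import PAEDIATRIC_MAX_AGE, SedationEpisode

#: Minimum age for standard-technique intravenous sedation eligibility.
IVS_MIN_AGE = 12

#: Maximum ASA physical-status grade for standard-technique IVS eligibility.
IVS_MAX_ASA = 2


def ivs_eligible(age_years: int, asa_grade: int) -> bool:
    """Eligibility screen for standard-technique intravenous sedation.

    True iff the patient is 12 years or older with ASA grade I or II.
    """
    if asa_grade not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"asa_grade must be in 1..6, got {asa_grade}")
    if age_years < 0:
        raise ValueError(f"age_years must be >= 0, got {age_years}")
    return age_years >= IVS_MIN_AGE and asa_grade <= IVS_MAX_ASA


@dataclass(frozen=True)
class ServiceSummary:
    """Aggregated audit result for one service over its collection period."""

    service_id: str
    n_episodes: int
    total_co2e_kg: float
    mean_co2e_kg_per_episode: float
    success_rate: float
    eligibility_rate: float
    paediatric_fraction: float
    mean_flow_lpm: float
    mean_titration_fraction: float
    mean_duration_min: float


def summarise_service(
    episodes: Sequence[SedationEpisode], constants: GasConstants = GasConstants()
) -> ServiceSummary:
    """Deterministic aggregation of one service's episodes.

    All episodes must share a single ``service_id``; an empty collection is
    an error (no silent zero summaries).
    """
    if not episodes:
        raise ValueError("cannot summarise an empty episode collection")
    service_ids = {e.service_id for e in episodes}
    if len(service_ids) != 1:
        raise ValueError(f"episodes span multiple services: {sorted(service_ids)}")
    n = len(episodes)
    footprints = [episode_footprint(e, constants).co2e_kg for e in episodes]
    total = sum(footprints)
    return ServiceSummary(
        service_id=service_ids.pop(),
        n_episodes=n,
        total_co2e_kg=total,
        mean_co2e_kg_per_episode=total / n,
        success_rate=sum(e.success for e in episodes) / n,
        eligibility_rate=sum(ivs_eligible(e.age_years, e.asa_grade) for e in episodes) / n,
        paediatric_fraction=sum(e.is_paediatric for e in episodes) / n,
        mean_flow_lpm=sum(e.flow_rate_lpm for e in episodes) / n,
        mean_titration_fraction=sum(e.max_n2o_fraction for e in episodes) / n,
        mean_duration_min=sum(e.duration_min for e in episodes) / n,
    )


def success_by_acclimatisation_policy(
    groups: Iterable[tuple[str, Sequence[SedationEpisode], bool]],
    weighting: str = "service",
) -> tuple[float | None, float | None]:
    """Pooled success rates for services that do / do not offer routine
    acclimatisation visits.

    Parameters
    ----------
    groups
        Triples ``(service_id, episodes, offers_acclimatisation)``.
    weighting
        ``"service"`` (default) pools as the unweighted mean of per-service
        success rates; ``"episode"`` pools over episodes directly.

    Returns
    -------
    (rate_offering, rate_not_offering); a group with no services is
    reported as ``None``, never as zero.
    """
    if weighting not in ("service", "episode"):
        raise ValueError(f"weighting must be 'service' or 'episode', got {weighting!r}")
    rates: dict[bool, list[float]] = {True: [], False: []}
    counts: dict[bool, list[tuple[int, int]]] = {True: [], False: []}
    for _service_id, episodes, offers in groups:
        if not episodes:
            continue
        n_success = sum(e.success for e in episodes)
        rates[bool(offers)].append(n_success / len(episodes))
        counts[bool(offers)].append((n_success, len(episodes)))

    def pooled(offers: bool) -> float | None:
        if not rates[offers]:
            return None
        if weighting == "service":
            return sum(rates[offers]) / len(rates[offers])
        successes = sum(s for s, _ in counts[offers])
        total = sum(n for _, n in counts[offers])
        return successes / total

    return pooled(True), pooled(False)


@dataclass(frozen=True)
class NationalRollup:
    """Pooled audit figures plus an anonymised per-service table."""

    n_services: int
    n_episodes: int
    total_co2e_kg: float
    mean_co2e_kg_per_episode: float  # episode-weighted: total / n_episodes
    mean_service_total_co2e_kg: float
    service_total_range: tuple[float, float]
    service_mean_range: tuple[float, float]
    pooled_success_rate: float  # episode-weighted
    pooled_eligibility_rate: float  # episode-weighted
    services: tuple[ServiceSummary, ...]  # anonymised when requested
    pseudonyms: dict[str, str]  # original service_id -> pseudonym


def national_rollup(
    summaries: Sequence[ServiceSummary], anonymise: bool = True
) -> NationalRollup:
    """Pool per-service summaries into national figures.

    The per-episode mean is episode-weighted (total CO2e over total
    episodes); per-service statistics are unweighted over services.
    Pseudonyms are stable for a given set of service identifiers (assigned
    in sorted order).
    """
    if not summaries:
        raise ValueError("cannot roll up an empty summary collection")
    ordered = sorted(summaries, key=lambda s: s.service_id)
    pseudonyms = {
        s.service_id: f"service-{i + 1:02d}" for i, s in enumerate(ordered)
    }
    n_episodes = sum(s.n_episodes for s in ordered)
    total = sum(s.total_co2e_kg for s in ordered)
    totals = [s.total_co2e_kg for s in ordered]
    means = [s.mean_co2e_kg_per_episode for s in ordered]
    table = tuple(
        ServiceSummary(
            service_id=pseudonyms[s.service_id] if anonymise else s.service_id,
            n_episodes=s.n_episodes,
            total_co2e_kg=s.total_co2e_kg,
            mean_co2e_kg_per_episode=s.mean_co2e_kg_per_episode,
            success_rate=s.success_rate,
            eligibility_rate=s.eligibility_rate,
            paediatric_fraction=s.paediatric_fraction,
            mean_flow_lpm=s.mean_flow_lpm,
            mean_titration_fraction=s.mean_titration_fraction,
            mean_duration_min=s.mean_duration_min,
        )
        for s in ordered
    )
    return NationalRollup(
        n_services=len(ordered),
        n_episodes=n_episodes,
        total_co2e_kg=total,
        mean_co2e_kg_per_episode=total / n_episodes,
        mean_service_total_co2e_kg=sum(totals) / len(totals),
        service_total_range=(min(totals), max(totals)),
        service_mean_range=(min(means), max(means)),
        pooled_success_rate=sum(s.success_rate * s.n_episodes for s in ordered) / n_episodes,
        pooled_eligibility_rate=sum(s.eligibility_rate * s.n_episodes for s in ordered)
        / n_episodes,
        services=table,
        pseudonyms=pseudonyms,
    )


def flow_age_table(episodes: Iterable[SedationEpisode]) -> list[tuple[int, float]]:
    """Plain (age, flow-rate) pairs for plotting or export."""
    return [(e.age_years, e.flow_rate_lpm) for e in episodes]


def flow_age_correlation(episodes: Sequence[SedationEpisode]) -> tuple[float, float]:
    """Optional Spearman rank-correlation diagnostic between age and flow.

    Returns ``(rho, p_value)``.  Purely descriptive; no conclusion is drawn
    from it elsewhere in the pipeline.
    """
    ages = [e.age_years for e in episodes]
    flows = [e.flow_rate_lpm for e in episodes]
    rho, p = stats.spearmanr(ages, flows)
    return float(rho), float(p)
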