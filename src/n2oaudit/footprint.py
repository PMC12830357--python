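"""Carbon-footprint arithmetic for administered nitrous oxide.

The administered volume of one sedation episode is the product of the total
gas flow rate (L/min), the maximum titrated N2O fraction and the length of
administration (min).  The volume is converted to mass using the density of
N2O gas and then to kilograms of CO2-equivalent with a global-warming
potential (GWP) multiplier.  Full precision is carried everywhere; rounding
happens only in report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import SedationEpisode

#: kg of N2O per litre of gas at the reference conditions used for auditing.
N2O_DENSITY_KG_PER_L = 0.001984467

#: 100-year global warming potential of N2O (AR5-era value used for audits).
GWP_N2O = 265

#: Updated 100-year global warming potential (latest assessment).
GWP_N2O_UPDATED = 273


@dataclass(frozen=True)
class GasConstants:
    """Unit-conversion constants for N2O carbon accounting.

    Parameters
    ----------
    density_kg_per_l : float
        Mass of one litre of N2O gas in kilograms.
    gwp : float
        Dimensionless global-warming-potential multiplier.  The default of
        265 reproduces audit figures computed before the update to 273;
        pass ``gwp=GWP_N2O_UPDATED`` for the current factor.
    """

    density_kg_per_l: float = N2O_DENSITY_KG_PER_L
    gwp: float = GWP_N2O

    def __post_init__(self) -> None:
        if not self.density_kg_per_l > 0:
            raise ValueError(f"density_kg_per_l must be > 0, got {self.density_kg_per_l}")
        if not self.gwp > 0:
            raise ValueError(f"gwp must be > 0, got {self.gwp}")


@dataclass(frozen=True)
class FootprintResult:
    """Administered N2O volume, mass and carbon footprint of one episode."""

    volume_l: float
    mass_kg: float
    co2e_kg: float


def episode_volume(
    flow_rate_lpm: float, max_n2o_fraction: float, duration_min: float
) -> float:
    """Administered N2O volume in litres: ``flow * fraction * duration``.

    The maximum titration is applied over the whole duration; initial
    titration increments are deliberately ignored as they have minimal
    impact on the overall volume.

    Examples
    --------
    >>> episode_volume(5, 0.30, 20)
    30.0
    """
    if not flow_rate_lpm > 0:
        raise ValueError(f"flow_rate_lpm must be > 0, got {flow_rate_lpm}")
    if not 0 < max_n2o_fraction <= 1:
        raise ValueError(f"max_n2o_fraction must be in (0, 1], got {max_n2o_fraction}")
    if not duration_min > 0:
        raise ValueError(f"duration_min must be > 0, got {duration_min}")
    return flow_rate_lpm * max_n2o_fraction * duration_min


def volume_to_co2e(volume_l: float, constants: GasConstants = GasConstants()) -> FootprintResult:
    """Convert a volume of N2O gas to mass and CO2-equivalent.

    ``mass = volume * density`` and ``co2e = mass * gwp``; zero maps to zero.

    Examples
    --------
    >>> round(volume_to_co2e(30.0).co2e_kg, 2)
    15.78
    """
    if volume_l < 0:
        raise ValueError(f"volume_l must be >= 0, got {volume_l}")
    mass_kg = volume_l * constants.density_kg_per_l
    return FootprintResult(volume_l=volume_l, mass_kg=mass_kg, co2e_kg=mass_kg * constants.gwp)


def episode_footprint(
    episode: SedationEpisode, constants: GasConstants = GasConstants()
) -> FootprintResult:
    """Carbon footprint of one sedation episode.

    Deterministic composition of :func:`episode_volume` and
    :func:`volume_to_co2e`.
    """
    return volume_to_co2e(
        episode_volume(episode.flow_rate_lpm, episode.max_n2o_fraction, episode.duration_min),
        constants,
    )
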