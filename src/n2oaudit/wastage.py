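"""Supply-side wastage estimation from procurement records.

Procurement is normalised to litres of N2O gas per week via a cylinder
capacity registry, then compared with the volume administered to patients;
any shortfall is wastage.  Negative wastage (administered exceeds procured,
typically an unusually busy collection period) is reported verbatim and
flagged, never clipped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import UnknownCylinderError, ValidationError
from .model import ProcurementRecord, SiteConfig

#: Wastage fraction above which investigation is recommended.
DEFAULT_WASTAGE_THRESHOLD = 0.20

#: Stricter in-study trigger used when services were asked to investigate.
STUDY_WASTAGE_THRESHOLD = 0.25

FLAG_OK = "ok"
FLAG_INVESTIGATE = "investigate"
FLAG_NEGATIVE = "negative_anomaly"


@dataclass(frozen=True)
class CylinderSpec:
    """Nominal litres of N2O gas held by one full cylinder of a size code."""

    size_code: str
    nominal_volume_l: float

    def __post_init__(self) -> None:
        if not self.nominal_volume_l > 0:
            raise ValidationError(
                f"nominal_volume_l must be > 0, got {self.nominal_volume_l}"
            )


def default_registry() -> dict[str, CylinderSpec]:
    """Default cylinder capacity registry: E = 1,800 L, G = 9,000 L of gas.

    These round-number capacities are the unique ones consistent with the
    standard weekly conversions (10 E/year -> 346 L/week, 6 G/year ->
    1,038 L/week under a 52-week year).  Extend or override via config for
    other sizes.
    """
    return build_registry([CylinderSpec("E", 1800.0), CylinderSpec("G", 9000.0)])


def build_registry(specs: Iterable[CylinderSpec]) -> dict[str, CylinderSpec]:
    registry: dict[str, CylinderSpec] = {}
    for spec in specs:
        if spec.size_code in registry:
            raise ValidationError(f"duplicate cylinder size code {spec.size_code!r}")
        registry[spec.size_code] = spec
    return registry


def period_weeks(period_days: int) -> float:
    """Weeks covered by a procurement period.

    Whole calendar years are treated as 52 weeks (the convention under which
    annual procurement figures convert to round weekly volumes); any other
    period is ``period_days / 7``.
    """
    if period_days <= 0:
        raise ValueError(f"period_days must be > 0, got {period_days}")
    if period_days in (365, 366):
        return 52.0
    return period_days / 7


@dataclass(frozen=True)
class WastageEstimate:
    """Procured vs administered weekly volume for one site."""

    site_id: str
    procured_l_per_week: float
    administered_l_per_week: float
    wastage_fraction: float
    flag: str

    @property
    def wastage_pct(self) -> int:
        """Wastage as a whole percentage (nearest integer)."""
        return round(self.wastage_fraction * 100)


def weekly_procured_volume(
    records: Iterable[ProcurementRecord],
    registry: Mapping[str, CylinderSpec] | None = None,
) -> float:
    """Total procured N2O volume in litres per week.

    Each record contributes ``quantity * nominal_volume / period_weeks``.
    Full precision is returned; round at report time.
    """
    registry = default_registry() if registry is None else registry
    total = 0.0
    for record in records:
        try:
            spec = registry[record.cylinder_size]
        except KeyError:
            raise UnknownCylinderError(
                f"unknown cylinder size code {record.cylinder_size!r}"
            ) from None
        total += record.quantity * spec.nominal_volume_l / period_weeks(record.period_days)
    return total


def estimate_wastage(
    procured_l_per_week: float,
    administered_l_per_week: float,
    threshold: float = DEFAULT_WASTAGE_THRESHOLD,
    site_id: str = "",
) -> WastageEstimate:
    """Wastage fraction ``1 - administered / procured`` with an action flag.

    The fraction may be negative (flagged ``negative_anomaly``) and is never
    clipped; fractions strictly above ``threshold`` are flagged
    ``investigate``.
    """
    if not procured_l_per_week > 0:
        raise ValueError(f"procured_l_per_week must be > 0, got {procured_l_per_week}")
    if administered_l_per_week < 0:
        raise ValueError(
            f"administered_l_per_week must be >= 0, got {administered_l_per_week}"
        )
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    fraction = 1 - administered_l_per_week / procured_l_per_week
    if fraction < 0:
        flag = FLAG_NEGATIVE
    elif fraction > threshold:
        flag = FLAG_INVESTIGATE
    else:
        flag = FLAG_OK
    return WastageEstimate(
        site_id=site_id,
        procured_l_per_week=procured_l_per_week,
        administered_l_per_week=administered_l_per_week,
        wastage_fraction=fraction,
        flag=flag,
    )


def eligible_for_wastage(site: SiteConfig) -> bool:
    """Whether a supply-side wastage estimate is possible for a site.

    Piped (manifold) supplies shared with other specialties cannot be
    attributed to dental sedation, so they are excluded; everything else is
    eligible.
    """
    return not (site.supply_type == "manifold" and site.shared_supply)


def episodes_per_cylinder(mean_episode_volume_l: float, spec: CylinderSpec) -> float:
    """How many average episodes one full cylinder supports."""
    if not mean_episode_volume_l > 0:
        raise ValueError(
            f"mean_episode_volume_l must be > 0, got {mean_episode_volume_l}"
        )
    return spec.nominal_volume_l / mean_episode_volume_l


def write_wastage_csv(estimates: Iterable[WastageEstimate], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["site_id", "procured_l_per_week", "administered_l_per_week", "wastage_pct", "flag"]
        )
        for est in estimates:
            writer.writerow(
                [
                    est.site_id,
                    round(est.procured_l_per_week),
                    round(est.administered_l_per_week),
                    est.wastage_pct,
                    est.flag,
                ]
            )
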