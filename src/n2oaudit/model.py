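"""Data model and CSV ingest/egress for sedation episodes, sites and procurement.

The on-disk representation is plain UTF-8 CSV with a single mandatory header
row.  The nitrous-oxide titration is stored externally as a percentage
(column ``max_n2o_pct``) and internally as a dimensionless fraction in
``(0, 1]``; conversion happens exactly once at ingest/egress and is performed
in decimal arithmetic so a write/read round trip reproduces field values
bit-for-bit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError, SchemaError, UnknownCylinderError, ValidationError

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "episode_id",
    "service_id",
    "site_id",
    "age_years",
    "sex",
    "asa_grade",
    "flow_lpm",
    "max_n2o_pct",
    "duration_min",
    "procedure",
    "success",
    "acclimatisation_only",
]
PROCUREMENT_COLUMNS = ["site_id", "cylinder_size", "quantity", "period_days"]
SITE_COLUMNS = ["site_id", "service_id", "supply_type", "scavenging", "shared_supply"]

SEXES = ("female", "male", "other")
PROCEDURES = ("extraction", "restoration", "acclimatisation", "other")
SUPPLY_TYPES = ("cylinder", "manifold")
SCAVENGING_MODES = ("central", "mobile", "high_speed_suction")

#: Paediatric/adult split: 15 years or younger is paediatric.
PAEDIATRIC_MAX_AGE = 15

_ROMAN_ASA = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


@dataclass(frozen=True)
class SedationEpisode:
    """One administration of inhalation sedation.

    ``max_n2o_fraction`` is the maximum titrated nitrous-oxide fraction of
    the gas mix, in ``(0, 1]``.
    """

    episode_id: str
    service_id: str
    site_id: str
    age_years: int
    sex: str
    asa_grade: int
    flow_rate_lpm: float
    max_n2o_fraction: float
    duration_min: float
    procedure: str
    success: bool
    acclimatisation_only: bool

    def __post_init__(self) -> None:
        problems = []
        if not self.flow_rate_lpm > 0:
            problems.append(f"flow_rate_lpm must be > 0, got {self.flow_rate_lpm}")
        if not self.duration_min > 0:
            problems.append(f"duration_min must be > 0, got {self.duration_min}")
        if not 0 < self.max_n2o_fraction <= 1:
            problems.append(
                f"max_n2o_fraction must be in (0, 1], got {self.max_n2o_fraction}"
            )
        if self.asa_grade not in (1, 2, 3, 4, 5, 6):
            problems.append(f"asa_grade must be in 1..6, got {self.asa_grade}")
        if self.age_years < 0:
            problems.append(f"age_years must be >= 0, got {self.age_years}")
        if self.sex not in SEXES:
            problems.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.procedure not in PROCEDURES:
            problems.append(f"procedure must be one of {PROCEDURES}, got {self.procedure!r}")
        if self.acclimatisation_only and self.procedure != "acclimatisation":
            problems.append("acclimatisation_only requires procedure == 'acclimatisation'")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def is_paediatric(self) -> bool:
        return self.age_years <= PAEDIATRIC_MAX_AGE


@dataclass(frozen=True)
class SiteConfig:
    """Supply and scavenging configuration of one physical site."""

    site_id: str
    service_id: str
    supply_type: str
    scavenging: str
    shared_supply: bool

    def __post_init__(self) -> None:
        if self.supply_type not in SUPPLY_TYPES:
            raise ValidationError(
                f"supply_type must be one of {SUPPLY_TYPES}, got {self.supply_type!r}"
            )
        if self.scavenging not in SCAVENGING_MODES:
            raise ValidationError(
                f"scavenging must be one of {SCAVENGING_MODES}, got {self.scavenging!r}"
            )
        if self.shared_supply and self.supply_type != "manifold":
            raise ValidationError("shared_supply may be true only for manifold supply")


@dataclass(frozen=True)
class ProcurementRecord:
    """Cylinders of one size bought by a site over a period."""

    site_id: str
    cylinder_size: str
    quantity: int
    period_days: int

    def __post_init__(self) -> None:
        if self.quantity < 1:
            raise ValidationError(f"quantity must be >= 1, got {self.quantity}")
        if self.period_days < 1:
            raise ValidationError(f"period_days must be >= 1, got {self.period_days}")


@dataclass(frozen=True)
class RowIssue:
    """One excluded input row and the reason for its exclusion."""

    row: int  # 1-based data-row number (header not counted)
    reason: str


@dataclass
class ValidationReport:
    """Outcome of validating every row of an input file.

    Totality: ``n_valid + len(issues) == n_rows`` always holds.
    """

    n_rows: int = 0
    n_valid: int = 0
    issues: list[RowIssue] = field(default_factory=list)


# ---------------------------------------------------------------------------
# field parsers

def parse_bool(raw: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {raw!r} as a boolean")


def parse_sex(raw: str) -> str:
    token = raw.strip().lower()
    if token in ("f", "female"):
        return "female"
    if token in ("m", "male"):
        return "male"
    return "other"


def parse_procedure(raw: str) -> str:
    token = raw.strip().lower().replace("acclimatization", "acclimatisation")
    return token if token in PROCEDURES else "other"


def parse_asa(raw: str) -> int:
    """Accept '1'..'6', Roman numerals I..VI, or an 'ASA ' prefixed form."""
    token = raw.strip().upper().removeprefix("ASA").strip()
    if token in _ROMAN_ASA:
        return _ROMAN_ASA[token]
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"cannot interpret {raw!r} as an ASA grade") from None


def percent_to_fraction(raw: str) -> float:
    """Convert a percentage string in (0, 100] to a fraction in (0, 1].

    Decimal arithmetic avoids a binary rounding step, so ``'30'`` maps to the
    double ``0.3`` exactly and `fraction_to_percent` inverts this losslessly.
    """
    try:
        return float(Decimal(raw.strip()) / 100)
    except InvalidOperation:
        raise ValidationError(f"cannot interpret {raw!r} as a percentage") from None


def fraction_to_percent(fraction: float) -> str:
    return str(Decimal(repr(fraction)) * 100)


def _require_float(raw: str, name: str) -> float:
    token = raw.strip()
    if token == "":
        raise ValidationError(f"missing required numeric field {name!r}")
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"non-numeric value {raw!r} for field {name!r}") from None


def _require_int(raw: str, name: str) -> int:
    token = raw.strip()
    if token == "":
        raise ValidationError(f"missing required integer field {name!r}")
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"non-integer value {raw!r} for field {name!r}") from None


# ---------------------------------------------------------------------------
# readers / writers

def _open_reader(path: str | Path, expected: Sequence[str]) -> tuple[csv.DictReader, object]:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        handle.close()
        raise InputError(f"{path}: file is empty (no header row)")
    missing = [c for c in expected if c not in reader.fieldnames]
    if missing:
        handle.close()
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return reader, handle


def _episode_from_row(row: dict[str, str]) -> SedationEpisode:
    return SedationEpisode(
        episode_id=row["episode_id"].strip(),
        service_id=row["service_id"].strip(),
        site_id=row["site_id"].strip(),
        age_years=_require_int(row["age_years"], "age_years"),
        sex=parse_sex(row["sex"]),
        asa_grade=parse_asa(row["asa_grade"]),
        flow_rate_lpm=_require_float(row["flow_lpm"], "flow_lpm"),
        max_n2o_fraction=percent_to_fraction(row["max_n2o_pct"])
        if row["max_n2o_pct"].strip()
        else _require_float(row["max_n2o_pct"], "max_n2o_pct"),
        duration_min=_require_float(row["duration_min"], "duration_min"),
        procedure=parse_procedure(row["procedure"]),
        success=parse_bool(row["success"]),
        acclimatisation_only=parse_bool(row["acclimatisation_only"]),
    )


def read_episodes(
    path: str | Path, strict: bool = False
) -> tuple[list[SedationEpisode], ValidationReport]:
    """Read and validate an episodes CSV.

    Every data row is either returned as a valid :class:`SedationEpisode` or
    enumerated in the report with a reason.  Rows with missing or non-numeric
    core fields (flow, titration, duration) are excluded, never imputed.
    With ``strict=True`` the first invalid row raises instead.
    """
    reader, handle = _open_reader(path, EPISODE_COLUMNS)
    report = ValidationReport()
    episodes: list[SedationEpisode] = []
    with handle:
        for i, row in enumerate(reader, start=1):
            report.n_rows += 1
            try:
                episodes.append(_episode_from_row(row))
                report.n_valid += 1
            except ValidationError as exc:
                if strict:
                    raise ValidationError(f"{path}: row {i}: {exc}") from exc
                logger.warning("%s: excluding row %d: %s", path, i, exc)
                report.issues.append(RowIssue(row=i, reason=str(exc)))
    return episodes, report


def write_episodes(episodes: Iterable[SedationEpisode], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EPISODE_COLUMNS)
        for e in episodes:
            writer.writerow(
                [
                    e.episode_id,
                    e.service_id,
                    e.site_id,
                    e.age_years,
                    e.sex,
                    e.asa_grade,
                    repr(e.flow_rate_lpm),
                    fraction_to_percent(e.max_n2o_fraction),
                    repr(e.duration_min),
                    e.procedure,
                    e.success,
                    e.acclimatisation_only,
                ]
            )


def read_procurement(
    path: str | Path, registry: dict | None = None
) -> list[ProcurementRecord]:
    """Read a procurement CSV; any invalid row raises.

    If ``registry`` (size code -> :class:`~n2oaudit.wastage.CylinderSpec`)
    is given, unknown size codes raise :class:`UnknownCylinderError`.
    """
    reader, handle = _open_reader(path, PROCUREMENT_COLUMNS)
    records: list[ProcurementRecord] = []
    with handle:
        for i, row in enumerate(reader, start=1):
            code = row["cylinder_size"].strip()
            if registry is not None and code not in registry:
                raise UnknownCylinderError(
                    f"{path}: row {i}: unknown cylinder size code {code!r}"
                )
            try:
                records.append(
                    ProcurementRecord(
                        site_id=row["site_id"].strip(),
                        cylinder_size=code,
                        quantity=_require_int(row["quantity"], "quantity"),
                        period_days=_require_int(row["period_days"], "period_days"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_procurement(records: Iterable[ProcurementRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PROCUREMENT_COLUMNS)
        for r in records:
            writer.writerow([r.site_id, r.cylinder_size, r.quantity, r.period_days])


def read_sites(path: str | Path) -> list[SiteConfig]:
    reader, handle = _open_reader(path, SITE_COLUMNS)
    sites: list[SiteConfig] = []
    with handle:
        for i, row in enumerate(reader, start=1):
            try:
                sites.append(
                    SiteConfig(
                        site_id=row["site_id"].strip(),
                        service_id=row["service_id"].strip(),
                        supply_type=row["supply_type"].strip().lower(),
                        scavenging=row["scavenging"].strip().lower(),
                        shared_supply=parse_bool(row["shared_supply"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return sites


def write_sites(sites: Iterable[SiteConfig], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(SITE_COLUMNS)
        for s in sites:
            writer.writerow(
                [s.site_id, s.service_id, s.supply_type, s.scavenging, s.shared_supply]
            )
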