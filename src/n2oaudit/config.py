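"""Audit configuration: constants, cylinder registry, thresholds, rendering."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .footprint import GasConstants
from .wastage import (
    DEFAULT_WASTAGE_THRESHOLD,
    CylinderSpec,
    build_registry,
    default_registry,
)


@dataclass(frozen=True)
class AuditConfig:
    constants: GasConstants = field(default_factory=GasConstants)
    registry: dict[str, CylinderSpec] = field(default_factory=default_registry)
    wastage_threshold: float = DEFAULT_WASTAGE_THRESHOLD
    report_decimal_places: int = 2
    anonymise: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.wastage_threshold <= 1:
            raise ConfigurationError(
                f"wastage_threshold must be in [0, 1], got {self.wastage_threshold}"
            )
        if self.report_decimal_places < 0:
            raise ConfigurationError(
                f"report_decimal_places must be >= 0, got {self.report_decimal_places}"
            )


_KNOWN_KEYS = {
    "density_kg_per_l",
    "gwp",
    "registry",
    "wastage_threshold",
    "report_decimal_places",
    "anonymise",
}


def load_config(path: str | Path) -> AuditConfig:
    """Load an :class:`AuditConfig` from YAML (or JSON, a YAML subset).

    Recognised keys: ``density_kg_per_l``, ``gwp``, ``wastage_threshold``,
    ``report_decimal_places``, ``anonymise`` and ``registry`` (a map of
    cylinder size code to litres).  Omitted keys keep their defaults.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse config: {exc}") from exc
    if raw is None:
        return AuditConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    try:
        constants = GasConstants(
            density_kg_per_l=float(raw.get("density_kg_per_l", GasConstants().density_kg_per_l)),
            gwp=float(raw.get("gwp", GasConstants().gwp)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: invalid constants: {exc}") from exc
    registry = default_registry()
    if "registry" in raw:
        if not isinstance(raw["registry"], dict):
            raise ConfigurationError(f"{path}: registry must map size code to litres")
        try:
            registry.update(
                build_registry(
                    CylinderSpec(str(code), float(litres))
                    for code, litres in raw["registry"].items()
                )
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: invalid registry: {exc}") from exc
    try:
        return AuditConfig(
            constants=constants,
            registry=registry,
            wastage_threshold=float(raw.get("wastage_threshold", DEFAULT_WASTAGE_THRESHOLD)),
            report_decimal_places=int(raw.get("report_decimal_places", 2)),
            anonymise=bool(raw.get("anonymise", True)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: invalid config value: {exc}") from exc
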