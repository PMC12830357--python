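"""Audit orchestration and report rendering.

`run_audit` ties the pipeline together (ingest -> footprints -> summaries ->
wastage -> recommendations) and returns a plain bundle; `render_report`
writes the bundle as CSV, JSON and/or Markdown.  All formats are rendered
from the same bundle, so rounded numbers agree across outputs; raw
full-precision values are preserved in the JSON.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Sequence

from . import analytics, model, wastage
from .config import AuditConfig
from .footprint import episode_footprint, episode_volume

logger = logging.getLogger(__name__)

FORMATS = ("csv", "json", "markdown")

SUMMARY_FIELDS = [
    "service_id",
    "n_episodes",
    "total_co2e_kg",
    "mean_co2e_kg_per_episode",
    "success_rate",
    "eligibility_rate",
    "paediatric_fraction",
    "mean_flow_lpm",
    "mean_titration_fraction",
    "mean_duration_min",
]


def _administered_per_week(
    episodes: Sequence[model.SedationEpisode], collection_period_days: float
) -> dict[str, float]:
    """Weekly administered N2O volume per site from the episode log."""
    volumes: dict[str, float] = {}
    for e in episodes:
        v = episode_volume(e.flow_rate_lpm, e.max_n2o_fraction, e.duration_min)
        volumes[e.site_id] = volumes.get(e.site_id, 0.0) + v
    scale = 7.0 / collection_period_days
    return {site: v * scale for site, v in volumes.items()}


def _recommendations(bundle: dict[str, Any], threshold: float) -> list[str]:
    recs = ["Undertake regular audit of clinical N2O administration and estimate wastage."]
    over = [w.site_id for w in bundle["wastage"] if w.flag == wastage.FLAG_INVESTIGATE]
    if over:
        recs.append(
            f"Wastage over {round(threshold * 100)}% at site(s) {', '.join(sorted(over))}: "
            "investigate stock control (expired, stolen or prematurely changed cylinders) "
            "and faulty equipment (piping leaks, faulty cylinder gauges)."
        )
    negative = [w.site_id for w in bundle["wastage"] if w.flag == wastage.FLAG_NEGATIVE]
    if negative:
        recs.append(
            f"Negative wastage at site(s) {', '.join(sorted(negative))}: administered volume "
            "exceeded expected supply; check whether the collection period was unusually busy."
        )
    rollup = bundle["rollup"]
    if rollup.pooled_eligibility_rate >= 0.25:
        recs.append(
            f"{round(rollup.pooled_eligibility_rate * 100)}% of patients may be suitable for "
            "standard-technique intravenous sedation; consider increasing access to alternatives."
        )
    acc = bundle["acclimatisation"]
    if (
        acc["offering"] is not None
        and acc["not_offering"] is not None
        and acc["offering"] <= acc["not_offering"]
    ):
        recs.append(
            "Routine acclimatisation visits show no success-rate benefit here; consider "
            "offering them on an individual-patient basis only."
        )
    return recs


def run_audit(
    episodes_path: str | Path,
    sites_path: str | Path,
    procurement_path: str | Path | None = None,
    config: AuditConfig | None = None,
    collection_period_days: float = 7.0,
    strict: bool = False,
) -> dict[str, Any]:
    """Run the full audit pipeline over the input files.

    Missing procurement data downgrades gracefully to a footprint-only
    report (empty wastage table, logged notice); ingest errors propagate.
    """
    config = config or AuditConfig()
    episodes, ingest_report = model.read_episodes(episodes_path, strict=strict)
    if not episodes:
        raise model.ValidationError(f"{episodes_path}: no valid episodes")
    sites = model.read_sites(sites_path)
    logger.info(
        "ingested %d episodes (%d excluded), %d sites",
        ingest_report.n_valid,
        len(ingest_report.issues),
        len(sites),
    )

    by_service: dict[str, list[model.SedationEpisode]] = {}
    for e in episodes:
        by_service.setdefault(e.service_id, []).append(e)
    summaries = [
        analytics.summarise_service(eps, config.constants) for eps in by_service.values()
    ]
    rollup = analytics.national_rollup(summaries, anonymise=config.anonymise)

    # a service "offers acclimatisation" if any of its episodes were
    # acclimatisation visits (policy is not in the data-collection template)
    policy_groups = [
        (sid, eps, any(e.procedure == "acclimatisation" for e in eps))
        for sid, eps in by_service.items()
    ]
    offering, not_offering = analytics.success_by_acclimatisation_policy(policy_groups)

    wastage_estimates: list[wastage.WastageEstimate] = []
    wastage_skipped: list[str] = []
    if procurement_path is not None:
        records = model.read_procurement(procurement_path, registry=config.registry)
        if not records:
            logger.warning("%s: procurement file has no rows; skipping wastage", procurement_path)
        administered = _administered_per_week(episodes, collection_period_days)
        by_site: dict[str, list[model.ProcurementRecord]] = {}
        for r in records:
            by_site.setdefault(r.site_id, []).append(r)
        site_map = {s.site_id: s for s in sites}
        for site_id, recs in sorted(by_site.items()):
            site = site_map.get(site_id)
            if site is not None and not wastage.eligible_for_wastage(site):
                wastage_skipped.append(site_id)
                continue
            procured = wastage.weekly_procured_volume(recs, config.registry)
            est = wastage.estimate_wastage(
                procured,
                administered.get(site_id, 0.0),
                threshold=config.wastage_threshold,
                site_id=site_id,
            )
            if est.flag == wastage.FLAG_NEGATIVE:
                logger.warning("site %s: negative wastage (%d%%)", site_id, est.wastage_pct)
            wastage_estimates.append(est)
    else:
        logger.warning("no procurement data supplied; producing footprint-only report")

    bundle: dict[str, Any] = {
        "ingest": ingest_report,
        "services": rollup.services,
        "rollup": rollup,
        "acclimatisation": {"offering": offering, "not_offering": not_offering},
        "wastage": wastage_estimates,
        "wastage_skipped_shared_supply": wastage_skipped,
        "config": config,
    }
    bundle["recommendations"] = _recommendations(bundle, config.wastage_threshold)
    return bundle


# ---------------------------------------------------------------------------
# rendering

def _fmt(value: float, dp: int) -> str:
    return f"{value:.{dp}f}"


def _pseudonymise_wastage(
    estimates: Iterable[wastage.WastageEstimate], anonymise: bool
) -> list[wastage.WastageEstimate]:
    if not anonymise:
        return list(estimates)
    ordered = sorted(estimates, key=lambda w: w.site_id)
    return [
        dataclasses.replace(w, site_id=f"site-{i + 1:03d}") for i, w in enumerate(ordered)
    ]


def _display_bundle(bundle: dict[str, Any], dp: int) -> dict[str, Any]:
    """Rounded view of the bundle; the single source for md and json display."""
    rollup = bundle["rollup"]
    acc = bundle["acclimatisation"]
    cfg: AuditConfig = bundle["config"]
    services = [
        {
            "service_id": s.service_id,
            "n_episodes": s.n_episodes,
            "total_co2e_kg": _fmt(s.total_co2e_kg, dp),
            "mean_co2e_kg_per_episode": _fmt(s.mean_co2e_kg_per_episode, dp),
            "success_rate": _fmt(s.success_rate, dp),
            "eligibility_rate": _fmt(s.eligibility_rate, dp),
            "paediatric_fraction": _fmt(s.paediatric_fraction, dp),
            "mean_flow_lpm": _fmt(s.mean_flow_lpm, dp),
            "mean_titration_fraction": _fmt(s.mean_titration_fraction, dp),
            "mean_duration_min": _fmt(s.mean_duration_min, dp),
        }
        for s in bundle["services"]
    ]
    wastage_rows = [
        {
            "site_id": w.site_id,
            "procured_l_per_week": str(round(w.procured_l_per_week)),
            "administered_l_per_week": str(round(w.administered_l_per_week)),
            "wastage_pct": str(w.wastage_pct),
            "flag": w.flag,
        }
        for w in _pseudonymise_wastage(bundle["wastage"], cfg.anonymise)
    ]
    return {
        "n_services": rollup.n_services,
        "n_episodes": rollup.n_episodes,
        "total_co2e_kg": _fmt(rollup.total_co2e_kg, dp),
        "mean_co2e_kg_per_episode": _fmt(rollup.mean_co2e_kg_per_episode, dp),
        "mean_service_total_co2e_kg": _fmt(rollup.mean_service_total_co2e_kg, dp),
        "success_rate_offering_acclimatisation": None
        if acc["offering"] is None
        else _fmt(acc["offering"], dp),
        "success_rate_not_offering_acclimatisation": None
        if acc["not_offering"] is None
        else _fmt(acc["not_offering"], dp),
        "pooled_eligibility_rate": _fmt(rollup.pooled_eligibility_rate, dp),
        "services": services,
        "wastage": wastage_rows,
        "recommendations": list(bundle["recommendations"]),
    }


def _raw_bundle(bundle: dict[str, Any]) -> dict[str, Any]:
    rollup = bundle["rollup"]
    cfg: AuditConfig = bundle["config"]
    return {
        "rollup": {
            "n_services": rollup.n_services,
            "n_episodes": rollup.n_episodes,
            "total_co2e_kg": rollup.total_co2e_kg,
            "mean_co2e_kg_per_episode": rollup.mean_co2e_kg_per_episode,
            "mean_service_total_co2e_kg": rollup.mean_service_total_co2e_kg,
            "service_total_range": list(rollup.service_total_range),
            "service_mean_range": list(rollup.service_mean_range),
            "pooled_success_rate": rollup.pooled_success_rate,
            "pooled_eligibility_rate": rollup.pooled_eligibility_rate,
        },
        "acclimatisation": bundle["acclimatisation"],
        "services": [dataclasses.asdict(s) for s in bundle["services"]],
        "wastage": [
            dataclasses.asdict(w)
            for w in _pseudonymise_wastage(bundle["wastage"], cfg.anonymise)
        ],
        "wastage_skipped_shared_supply": bundle["wastage_skipped_shared_supply"],
        "ingest": dataclasses.asdict(bundle["ingest"]),
        "constants": dataclasses.asdict(cfg.constants),
    }


def render_report(
    bundle: dict[str, Any],
    out_dir: str | Path,
    formats: Sequence[str] = FORMATS,
) -> list[Path]:
    """Write the report bundle to ``out_dir`` in the requested formats.

    Returns the list of files written.  Deterministic: identical bundles
    produce identical bytes (no timestamps).
    """
    for fmt in formats:
        if fmt not in FORMATS:
            raise ValueError(f"unknown report format {fmt!r}; choose from {FORMATS}")
    cfg: AuditConfig = bundle["config"]
    dp = cfg.report_decimal_places
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    display = _display_bundle(bundle, dp)
    written: list[Path] = []

    if "csv" in formats:
        path = out / "service_summary.csv"
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.DictWriter(handle, fieldnames=SUMMARY_FIELDS)
            writer.writeheader()
            writer.writerows(display["services"])
        written.append(path)
        if display["wastage"]:
            path = out / "wastage.csv"
            with open(path, "w", newline="", encoding="utf-8") as handle:
                writer = csv.DictWriter(
                    handle,
                    fieldnames=[
                        "site_id",
                        "procured_l_per_week",
                        "administered_l_per_week",
                        "wastage_pct",
                        "flag",
                    ],
                )
                writer.writeheader()
                writer.writerows(display["wastage"])
            written.append(path)

    if "json" in formats:
        path = out / "report.json"
        payload = {"raw": _raw_bundle(bundle), "display": display}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(path)

    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(_render_markdown(display), encoding="utf-8")
        written.append(path)
    return written


def _render_markdown(display: dict[str, Any]) -> str:
    lines = [
        "# N2O sedation audit report",
        "",
        f"- Services: {display['n_services']}",
        f"- Episodes: {display['n_episodes']}",
        f"- Total carbon footprint (kg CO2e): {display['total_co2e_kg']}",
        f"- Mean per-episode footprint (kg CO2e): {display['mean_co2e_kg_per_episode']}",
        f"- Mean per-service total (kg CO2e): {display['mean_service_total_co2e_kg']}",
        f"- Eligibility for standard IVS: {display['pooled_eligibility_rate']}",
    ]
    if display["success_rate_offering_acclimatisation"] is not None:
        lines.append(
            "- Success rate, services offering acclimatisation: "
            f"{display['success_rate_offering_acclimatisation']}"
        )
    if display["success_rate_not_offering_acclimatisation"] is not None:
        lines.append(
            "- Success rate, services not offering acclimatisation: "
            f"{display['success_rate_not_offering_acclimatisation']}"
        )
    lines += ["", "## Per-service summary", ""]
    lines.append("| " + " | ".join(SUMMARY_FIELDS) + " |")
    lines.append("|" + "---|" * len(SUMMARY_FIELDS))
    for row in display["services"]:
        lines.append("| " + " | ".join(str(row[f]) for f in SUMMARY_FIELDS) + " |")
    if display["wastage"]:
        lines += ["", "## Wastage", ""]
        cols = ["site_id", "procured_l_per_week", "administered_l_per_week", "wastage_pct", "flag"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for row in display["wastage"]:
            lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    lines += ["", "## Recommendations", ""]
    lines += [f"- {rec}" for rec in display["recommendations"]]
    lines.append("")
    return "\n".join(lines)
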