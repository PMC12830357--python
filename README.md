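# n2oaudit

Carbon-footprint and supply-wastage auditing for nitrous oxide (N₂O) used in
dental inhalation sedation.

Dental services record, per sedation episode, the total gas flow rate
(L/min), the maximum titrated N₂O fraction and the administration time.
`n2oaudit` turns those records into:

- **per-episode carbon footprints** — administered volume
  (`flow × fraction × minutes`), converted to mass (0.001984467 kg/L) and to
  kg CO₂-equivalent with a configurable global-warming potential (265 by
  default; 273 selectable);
- **supply-wastage estimates** — procurement normalised to litres/week via a
  cylinder-capacity registry (E = 1,800 L, G = 9,000 L by default; whole
  calendar years count as 52 weeks), compared against administered volume,
  with negative anomalies flagged rather than clipped and an `investigate`
  flag above a configurable threshold (20% default);
- **cohort analytics** — per-service summaries, an anonymised national
  rollup, success-rate comparison by acclimatisation policy, and an
  eligibility screen for standard-technique intravenous sedation (age ≥ 12,
  ASA grade I–II);
- **synthetic cohorts** — a seeded generator with truncated log-normal
  marginals and a Gaussian-copula dependence parameter, calibrated so the
  generated mean per-episode footprint hits a configured target, plus
  procurement records realising per-site wastage targets.

## Command line

```sh
# generate a synthetic cohort (episodes, sites, procurement + manifest)
n2oaudit --seed 1 --out-dir sim simulate --n 891

# per-episode footprints
n2oaudit --out-dir out footprint sim/episodes.csv

# full audit report (CSV + JSON + Markdown)
n2oaudit --out-dir out report \
    --episodes sim/episodes.csv --sites sim/sites.csv \
    --procurement sim/procurement.csv

# wastage table and IVS eligibility on their own
n2oaudit --out-dir out wastage --episodes sim/episodes.csv \
    --sites sim/sites.csv --procurement sim/procurement.csv
n2oaudit eligibility sim/episodes.csv
```

Global flags: `--config <yaml>` (keys `density_kg_per_l`, `gwp`,
`wastage_threshold`, `report_decimal_places`, `anonymise`, `registry`),
`--gwp` to override the warming potential, `--seed`, `--out-dir`.
Exit codes: 0 success, 2 schema/validation failure, 3 configuration error.

## Input formats

UTF-8 CSV with one header row:

- episodes: `episode_id,service_id,site_id,age_years,sex,asa_grade,flow_lpm,max_n2o_pct,duration_min,procedure,success,acclimatisation_only`
  (titration given as a percent, stored internally as a fraction; ASA
  accepts Roman numerals)
- sites: `site_id,service_id,supply_type,scavenging,shared_supply`
- procurement: `site_id,cylinder_size,quantity,period_days`

Invalid episode rows are excluded and enumerated in a validation report
(`strict` mode raises instead); wastage is only estimated for sites whose
supply is not a manifold shared with other specialties.

## Library use

```python
from n2oaudit import (
    GasConstants, episode_volume, volume_to_co2e,
    estimate_wastage, weekly_procured_volume,
    GeneratorParams, calibrated_params, generate_cohort,
    run_audit, render_report,
)

volume = episode_volume(5, 0.30, 20)          # 30.0 L
result = volume_to_co2e(volume)               # 15.78 kg CO2e at GWP 265

params = calibrated_params(GeneratorParams(n_episodes=891, seed=1))
cohort = generate_cohort(params)              # deterministic for a given seed
```
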