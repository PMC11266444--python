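# CSV schemas

All files are RFC-4180 CSV, UTF-8, with a header row. Unknown extra
columns are preserved on read.

## Baseline table (`baseline.csv`)

One row per participant.

| column | type | description |
|---|---|---|
| `id` | string | participant identifier, unique |
| `arm` | enum | `LEARN`, `placebo`, `solanezumab` |
| `age` | float | years at baseline |
| `female` | bool | female sex |
| `education` | float | years of education |
| `apoe4_carrier` | bool | carries at least one APOE ε4 allele |
| `urg_member` | bool | race/ethnicity under-represented group membership |
| `amyloid_cl` | float | amyloid PET burden, Centiloids |
| `amyloid_suvr` | float | amyloid PET SUVr (cerebellar reference) |
| `ptau217` | float | plasma P-tau217, assay units |
| `tau_neocortical_suvr` | float or empty | tau PET neocortical composite SUVr; present only for the tau substudy subset |
| `baseline_pacc` | float | baseline PACC (sum of four component z-scores) |
| `baseline_cfi` | float | baseline combined CFI, 0–30 |
| `in_tau_substudy` | bool | tau PET substudy membership |

## Visit table (`visits.csv`)

One row per participant × week × measure; `(id, week, measure)` unique.

| column | type | description |
|---|---|---|
| `id` | string | participant identifier |
| `week` | float | scheduled study week (0, 24, … for cognitive; 0, 48, … for functional) |
| `measure` | enum | `PACC`, `CFI_combined` (0–30), `ADL_partner` (0–45), `CDR_SB` (0–18), `CDR_GS` (0, 0.5, 1, 2, 3) |
| `value` | float | measure value |
| `test_version` | A/B/C or empty | alternate cognitive test version; PACC visits only |

## Derived outputs

- `change_scores.csv`: `id`, `change_240` (estimated PACC change from
  baseline at week 240, z-sum units), `arm`.
- `progression_outcomes.csv`: `id`, `event` (bool), `time_weeks`.
- `progression_curves.csv`: `stratum`, `time`, `survival`, `lo`, `hi`,
  `at_risk`.
- `trajectory_predictions.csv`: `group`, `week`, `mean`, `se`, `lo`, `hi`.
- `commonality_summary.tsv` (tab-separated): `predictor`, `unique_r2`,
  `common_r2`, `total_r2`, `p_value`, `group`, `n`.
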