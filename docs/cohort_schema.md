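# Cohort file schema

Delimited text (tab-separated), one header row, one row per pregnancy,
missing values as empty fields.  Booleans serialize as `True`/`False`.

| column | type | meaning |
|---|---|---|
| `case_id` | int/str | unique case identifier |
| `ga_days` | int | gestational age at scan, days (79–99 for included records) |
| `svfmbv1`..`svfmbv5` | float in (0,1) | perfusion fractions at the five uteroplacental targets |
| `placental_volume` | float > 0 | segmented placental volume, ml |
| `dice_placenta` | float in [0,1] | Dice agreement of the two placental segmentations |
| `dice_fluid` | float in [0,1] | Dice agreement of the two amniotic-fluid segmentations |
| `delivery_ga_days` | int | gestational age at birth, days (also accepted as "weeks+days" strings by the parsers) |
| `signs_of_life` | bool | live birth flag (with `delivery_ga_days` classifies term/preterm/stillbirth/miscarriage) |
| `termination` | bool | termination of pregnancy |
| `neonatal_death` | bool | neonatal death |
| `anomaly` | bool | major fetal anomaly found after the scan |
| `nnu_admission` | bool | neonatal unit admission |
| `diabetes` | bool | maternal diabetes (pre-existing or gestational) |
| `hypertensive_disease` | bool | chronic/gestational hypertension or pre-eclampsia |
| `aps_sle` | bool | antiphospholipid syndrome or systemic lupus erythematosus |
| `smoker` | bool | smoker at presentation |
| `previous_pe` | bool | previous pre-eclampsia |
| `female_sex` | bool | female fetal sex |
| `bw_centile` | float in (0,100), may be missing | birth-weight centile; missing routes the record to the incomplete-outcome exclusion |
| `ua_pi_centile` | float in (0,100), optional | umbilical-artery pulsatility-index centile |
| `cpr_centile` | float in (0,100), optional | cerebroplacental-ratio centile |
| `incomplete_outcome` | bool | outcome data otherwise incomplete |

Synthetic cohorts additionally carry `volume_outlier_injected` (bool),
the generator's ground truth for injected volume outliers.

Fetal growth restriction is derived, not stored: birth weight < 3rd
centile, or < 10th centile with umbilical-artery PI > 95th centile or
cerebroplacental ratio < 5th centile.
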