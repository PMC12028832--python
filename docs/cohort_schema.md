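# Cohort CSV data dictionary

One row per singleton pregnancy. Mandatory columns must be present; rows
violating row-level invariants are rejected individually (with line numbers)
rather than failing the file. Unknown columns are warned about and carried
through untouched.

## Mandatory columns

| column | type | units | meaning / invariants |
|---|---|---|---|
| `subject_id` | int | – | unique identifier |
| `ifc` | 0/1 | – | intrapartum fetal compromise: urgent cesarean for abnormal CTG or scalp pH (urgent *instrumental* deliveries are not IFC) |
| `maternal_age` | float | years | |
| `maternal_height_cm` | float | cm | > 0 |
| `maternal_weight_kg` | float | kg | pre-pregnancy weight, > 0 |
| `parity` | int | count | previous births |
| `smoking` | 0/1 | – | |
| `male_sex` | 0/1 | – | fetal sex, 1 = male |
| `ga20_weeks` | float | decimal weeks | mid-pregnancy scan age (nominal window 20 ± 1 w) |
| `efw20_g` | float | g | 20-week EFW (Hadlock-4), > 0 |
| `ga3t_weeks` | float | decimal weeks | third-trimester scan age (nominal window 30+0 – 40+6); must not exceed `ga_delivery_weeks` |
| `efw3t_g` | float | g | third-trimester EFW, > 0 |
| `ua_pi` | float | – | umbilical artery pulsatility index, in (0, 5) |
| `mca_pi` | float | – | middle cerebral artery pulsatility index, in (0, 5) |
| `induction` | 0/1 | – | labor onset: 1 = induced, 0 = spontaneous |
| `interval_days` | int | days | scan-to-delivery interval; 0 ≤ interval ≤ 14 (delivery within two weeks of the scan) |
| `ga_delivery_weeks` | float | decimal weeks | |
| `birthweight_g` | float | g | > 0 |

## Optional columns

| column | type | units | meaning |
|---|---|---|---|
| `bmi` | float | kg/m² | pre-pregnancy body-mass index |
| `nulliparity` | 0/1 | – | convenience flag (parity == 0) |
| `apgar5` | int | – | Apgar score at 5 minutes |
| `cord_ph` | float | – | umbilical cord arterial pH |
| `neonatal_ward` | 0/1 | – | neonatal-ward (vs maternal-ward) disposition |

Gestational ages are decimal weeks (33 w + 1 d → 33.142857…; display
convention rounds to 33.14). Biometry-based files may replace `efw20_g` /
`efw3t_g` with `bpd20_cm, hc20_cm, ac20_cm, fl20_cm` (and the `3t`
equivalents) when calling the assessment directly; the shipped reader
expects the EFW columns.

The per-subject assessment table emitted by `fetalgp assess` / the pipeline
has fixed columns `subject_id, efw20_mom, exfw3t_g, pct_exfw3t, ua_pi_mom,
mca_pi_mom, cpr, cpr_mom, efwc_local, efwc_ig`.
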