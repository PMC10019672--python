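# Cohort CSV schema

UTF-8, comma-separated, header row required.  Column names below are the
defaults; any of them can be remapped through the `schema` argument of
`read_cohort` (or a YAML config with a `columns:` mapping for the CLI).

## Required (physiologic; rows missing any are excluded, with a log)

| column                    | type / units                                   |
|---------------------------|------------------------------------------------|
| `maternal_height`         | cm, 100–220                                    |
| `maternal_weight_prepreg` | kg, > 0                                        |
| `parity`                  | non-negative integer (2+ pooled at encoding)   |
| `race`                    | `NH-White`, `NH-Black`, `Hispanic`, `Asian/PI` (common aliases accepted) |
| `infant_sex`              | `male` / `female` (or `m` / `f`)               |
| `ga_delivery`             | days; record invariant 168–301, analysis window configurable (default 259–293) |
| `birthweight`             | g, > 0                                         |

## Optional (pathologic flags; blank = absent, logged as a warning)

`smoking`, `gestational_diabetes`, `antepartum_bleeding`: boolean
(`0/1`, `true/false`, `yes/no`).  `hypertensive_disease`: free-text
category, `none`/blank meaning none (any other value counts as
hypertensive at encoding).  `bmi`: kg/m², derived from height and
weight when blank.

## Optional (other)

`paternal_height` (cm), `paternal_weight` (kg), `morbidity_sga`,
`morbidity_lga` (boolean composite neonatal morbidity outcomes).

## Longitudinal visits CSV

Separate file read by `read_visits`: `subject` (0-based row index into
the cohort file), `ga` (days), `hc`, `ac`, `fl` (mm, optional), `efw`
(g, optional).
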