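# Reference cohort tables

The regression checks in `tests/test_acceptance.py` that reproduce the
study cohort's published summary results read participant-level reference
tables from this directory.  These tables are part of the study's deposited
dataset / supplementary material and are **not** distributed with this
package; place them here as plain CSV files to enable the checks.

Expected files and schemas:

- `initial_cohort_metabolic_indicators.csv` — one row per participant of
  the 32-person initial cohort, columns:
  `participant_id, sspg, di, ie_pct, hepatic_ir`
  (SSPG mg/dl; DI in (pmol dl)/(kg ml); incretin effect %, hepatic IR
  index dimensionless).

- `initial_cohort_glucose_series.csv` — long-format plasma glucose of the
  same participants on the 16-point grid, columns:
  `participant_id, time_min, glucose_mg_dl`.

Everything else in the test suite runs on synthetic cohorts generated by
`glucopheno.simulate` and needs no external data.
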