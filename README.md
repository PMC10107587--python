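# bpvalidate

Accuracy evaluation of non-invasive blood-pressure (BP) devices against the
ISO 81060-2:2018 / AAMI-ESH-ISO universal-standard criteria, with a
synthetic study simulator for testing the full pipeline without field data.

## Who this is for

Teams running (or auditing) a cuff-reference validation study of a BP
device — including cuffless, smartphone-based estimators — in which two
blinded nurses take simultaneous auscultatory readings through a double
stethoscope while the test device records its own estimate, round after
round. The package covers everything downstream of data collection:

* **Reference derivation and round validity** — a round is valid when the
  two nurses agree within 4 mmHg on both SBP and DBP and the device
  produced a reading; the reference is the nurses' mean.
* **Subject screening** — age range, between-arm BP difference
  (>15 systolic / >10 diastolic excludes), resting-BP caps (180/120
  general, 160/110 pregnant).
* **The ordered exclusion cascade** — device failure → inter-nurse
  disagreement → subjects with fewer than three valid pairs → subjects
  with excessive within-subject reference variability (>12 SBP / >8 DBP
  mmHg from the subject's median on two or more rounds), with a
  count-conserving ledger.
* **ISO criterion 1**: pooled device−reference errors must satisfy
  −5 ≤ mean ≤ 5 mmHg and SD ≤ 8 mmHg.
* **ISO criterion 2**: the between-subject SD of per-subject mean errors
  must not exceed a ceiling that depends on the pooled mean error.
* **Sampling audits** — the protocol's recruitment distribution bounds
  (e.g., ≥5 % of measurements with SBP ≤ 100 mmHg; ≥20 subjects in each
  pregnancy BP group).
* **Bland–Altman agreement** and dual-observer qualification checks.

## The criterion-2 ceiling

Criterion 2 bounds the between-subject spread σ of per-subject mean errors
so that, under a normal error model with the observed pooled mean error μ,
at least 85 % of subjects' errors fall inside ±10 mmHg:

    Φ((10 − |μ|)/σ) − Φ((−10 − |μ|)/σ) = 0.85

`max_permissible_sd(μ)` solves this by bracketed root-finding (to well
below 1e−6 mmHg); `table6_grid()` tabulates it for μ = 0.0…5.0 mmHg in
0.1 steps, reproducing the standard's published grid (e.g. μ=0 → 6.95,
μ=4.2 → 5.49, μ=3.3 → 6.09). The envelope and coverage level are
configurable through `Criterion2Constants`.

## Worked example

Simulate a Tanzania-like general-population study and evaluate it:

```python
import bpvalidate as bv

study = bv.generate_study(bv.scenario("TZ_general"), seed=7)
report = bv.evaluate(study.rounds, study.subjects)
print(report.render_tables())
```

```
Site TZ — general population (N = 105, M = 419)

Criterion 1 (pooled measurement errors, device − reference)
                         requirement    observed       verdict
  SBP mean             −5 ≤ mean ≤ 5         0.6        passed
  SBP SD                      SD ≤ 8         6.5        passed
  DBP mean             −5 ≤ mean ≤ 5         0.3        passed
  DBP SD                      SD ≤ 8         3.9        passed

Criterion 2 (SD of per-subject mean errors)
  SBP: observed 5.7 ≤ permissible 6.92 (mean error used 0.6) → passed
  DBP: observed 3.6 ≤ permissible 6.94 (mean error used 0.3) → passed
```

N is the number of retained subjects, M the number of retained paired
measurements. The criterion-1 rows show the pooled mean error (device −
reference, so a positive value means the device overestimates) and its SD;
the criterion-2 rows compare the between-subject SD of per-subject mean
errors against the ceiling evaluated at the pooled mean error. The same
run's exclusion ledger reported 79 device-failure and 39 inter-nurse
measurement exclusions (inter-nurse share 33.1 % of exclusions), zero
subject-level exclusions, and a passing sampling audit.

The same pipeline runs from the shell on CSV files (one row per round):

```sh
bpvalidate simulate --scenario TZ_general --seed 7 --out sim/
bpvalidate evaluate --rounds sim/rounds.csv --subjects sim/subjects.csv \
    --population general --out results/
bpvalidate table6            # print the permissible-SD grid
bpvalidate check --mean-error 3.3 --observed-sd 6.4 --table-mode
```

The last command checks a published summary directly:
`permissible SD 6.09 mmHg; observed 6.4 → did not pass`.

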