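# Methods

## The evaluation model

The package evaluates a test BP device against a dual-observer
auscultatory reference. For each retained paired measurement the error is
defined as device − reference, where the reference is the mean of two
simultaneous nurse readings that agree within 4 mmHg on both arms.

**Criterion 1** treats all retained measurements as one pooled sample:
pass iff −5 ≤ mean ≤ 5 mmHg and sample SD ≤ 8 mmHg. **Criterion 2**
averages errors within each subject and bounds the between-subject SD of
those means by the ceiling σ_max(μ) solving

    Φ((Δ − |μ|)/σ) − Φ((−Δ − |μ|)/σ) = p ,   Δ = 10 mmHg, p = 0.85,

at the pooled (criterion-1) mean error μ. The root is found with Brent's
method on a bracket that always contains it (coverage is monotone in σ),
to an absolute tolerance far below 1e−6 mmHg; a test verifies the
returned root reproduces the 0.85 coverage to 1e−6 for every tabulated μ.
σ_max is even in μ and strictly decreasing in |μ|. Both Δ and p are
exposed via `Criterion2Constants`; all comparisons are inclusive and use
unrounded statistics unless *table mode* is requested.

### Relation to the published grid

The published 51-cell grid of σ_max (mean errors 0.0–5.0 by 0.1) is not
perfectly self-consistent: recomputing each cell from the defining
equation reproduces 35 cells exactly at 2 decimals and 13 more within one
final-digit rounding step, but three cells (μ = 3.6, 4.8, 5.0; printed
5.89, 5.01, 4.79 vs computed 5.91, 4.99, 4.81) disagree by about 0.02,
and the coverage probabilities implied by the printed cells scatter
irregularly between 0.8488 and 0.8509. No alternative closed form we
examined (one-sided bounds, floor rounding, interpolation between integer
rows, heavier-tailed error laws) explains the scatter, which points to
legacy rounding or transcription noise in the published table itself.
This package therefore always *computes* the ceiling from the equation
and never looks printed values up. Consequently a handful of thresholds
differ from their printed counterparts by one unit in the second decimal
(e.g. 6.93 vs 6.92 at μ = 0.5); every published pass/fail verdict is
unaffected. *Table mode* (`table_mode=True`) reproduces the printed-table
workflow — round μ to the nearest 0.1, evaluate the grid entry, report at
2 decimals — but inherits the same one-ulp differences because the grid
is computed, not copied.

### Degenerate inputs and tie-breaks

Criterion 1 requires ≥ 2 values (sample SD undefined below that);
criterion 2 requires ≥ 2 subjects with ≥ 3 pairs each (the cascade
guarantee) and is well defined at 2 subjects because all SDs use the n−1
denominator. σ_max is undefined for |μ| ≥ Δ and rejected there. Pass
comparisons at the boundary are inclusive (mean error of exactly 5, SD of
exactly 8, observed SD equal to the ceiling all pass).

## Workflow and cascade

Round validity applies the 4-mmHg rule jointly to SBP and DBP: a round is
one paired reading, and both arms' analyses must use the same retained
set. The cascade runs in a fixed order — device failure, inter-nurse
disagreement, subjects with < 3 surviving pairs, subjects with excessive
reference variability — and a record carries exactly the first reason
that removed it. Rounds failing both of the first two rules are counted
under device failure with a separate overlap tally, so the overlap can be
reported without disturbing conservation (retained + Σ excluded = total
at both levels, asserted in tests).

The variability rule is stated in the protocol only loosely ("differed by
more than 12/8 mmHg across 2 of the 4 rounds"). We interpret it as:
compute each retained round's reference, take the subject's median
reference per arm, and exclude the subject when two or more rounds
deviate from the median by > 12 mmHg (SBP) or > 8 mmHg (DBP). The rule is
isolated in one predicate inside `run_cascade` so an alternative reading
can be swapped in.

Sessions are expected to hold 4–8 rounds per subject; ragged real-world
files are accepted, and retained subjects with fewer than four valid
pairs are flagged in the ledger's warnings rather than rejected.

Sampling audits compute BP band fractions over the reference values of
retained measurements for general populations (low/high band bounds ≤ 100,
≥ 140, ≥ 160 SBP; ≤ 60, ≥ 85, ≥ 100 DBP; the ≥ 85 requirement is evaluated
as DBP ≥ 85 even though descriptive tables bin 61–85), and subject counts
per enrollment group (normotensive < 140/90; hypertensive without
proteinuria; pre-eclampsia = proteinuria with ≥ 140 or ≥ 90) for pregnant
cohorts.

## Bland–Altman

Measurement-level by default (matching how such studies plot per-country
panels), with `per_subject=True` to average within subjects first. Limits
of agreement are bias ± 1.96·SD with the conventional 1.96 factor. The
bias is definitionally the criterion-1 mean error on the same pairs
(asserted as a cross-module test). Repeated measurements per subject are
pooled without a repeated-measures correction — a deliberate match to
standard practice in these validation reports and a known limitation of
that presentation.

## The synthetic study generator

The generator exists so that every pipeline stage is testable without any
data download, and so that distribution-level claims can be checked
against *known* generating parameters. Per subject, true BP is drawn from
a mixture of correlated bivariate normal components; per round, a shared
auscultatory signal (truth + round noise, SD `observer_error_sd`) is read
by two nurses with independent errors (SD `inter_nurse_extra_sd`),
quantized to the 2-mmHg cuff gradation. The device reading, present with
probability 1 − `failure_probability` (failure statuses drawn from a
mixture defaulting to the pooled failure taxonomy reported by multi-site
studies: signal not captured 63.8 %, poor quality 19.0 %, irregular heart
rate 10.3 %, outlier 2.1 %, missing the remainder), is

    w·C_i + (1 − w)·(T_i + b_i) + ζ_ir ,

with calibration anchor C_i from a simulated one-time cuff calibration
(up to six attempts for two valid readings, never counted as validation
pairs), subject bias b_i ~ N(device_bias, between²) and within-subject
noise ζ ~ N(0, within²). Rounds repeat on invalidity up to eight, as in
the session workflow. A single `numpy` Generator seeded from one integer
makes studies bit-identical across runs.

This decomposition is the simplest structure under which criterion 1,
criterion 2 and the inter-nurse rule are all simultaneously meaningful;
it is a modeling choice of this package, not a described property of any
real device. Expected statistics follow a variance decomposition: with m
valid rounds per subject, pooled error variance ≈ B + W and
between-subject variance ≈ B + W/m, where W collects within-round noise
(device within-subject noise + reference noise: shared signal noise +
half the per-nurse error variance + quantization variance grad²/24) and B
the between-subject terms (anchored calibration noise w²·Var(C) plus the
shrunken bias spread (1−w)²·between²). The criterion-1 mean is
(1−w)·device_bias.

`scenario()` returns configurations calibrated, by inverting that
decomposition at m = 4, to the published per-site accuracy summaries
(means 0.5/0.8/3.3 SBP, 0.1/−0.4/−0.4 DBP; SDs 5.8/7.0/7.4 and
3.9/4.0/4.3; between-subject SDs 4.9/6.2/6.4 and 3.4/3.6/3.8) and to the
recruitment band structure of each site: the Tanzania-like and South
Africa-like cohorts satisfy their sampling requirements in a typical run,
while the Bangladesh-like mixture deliberately under-fills the
hypertensive bands, reproducing that site's documented recruitment
shortfall; `BN_cold` doubles the device-failure probability to emulate
the cold-weather signal-capture problem. Observer noise in scenarios is
set to 1.0 (shared) and 1.7 (per-nurse) mmHg — small enough to be
consistent with the published criterion-1/2 variance gap, which caps the
total within-round reference noise. A consequence is that simulated
inter-nurse exclusion rates sit below the rates real studies report, and
the strong co-occurrence of device failure with nurse disagreement seen
at one real site is not emulated (failures are independent across rounds
and of the nurses). Band-fraction audits on a finite cohort are binomial;
with ~105 subjects a typical scenario run passes all bands, but
individual seeds can land a band below its bound.

What passing simulator-backed tests shows: the pipeline's arithmetic,
ordering, conservation and statistical estimators behave correctly under
a known generating process matching the study's design (sample sizes,
round counts, error magnitudes). What it cannot show: anything about a
real device's accuracy, non-normal error structure, drift over a session,
or operator effects absent from the model.

## Problem sizes in the test suite

Distribution-level checks use 200 replicates of n = 100 subjects for
parameter recovery (criterion-1 mean within ±0.2 mmHg of the configured
bias 2.0; criterion-2 SD within ±0.3 of √(3² + 4²/4) = 3.61), 1,000
randomized small studies for cascade conservation/idempotence, and
10,000 simulated pairs for the 95 % ± 2 limits-of-agreement coverage
check; these sizes give Monte-Carlo standard errors several times smaller
than the asserted tolerances.

## Known limitations

* The printed permissible-SD grid cannot be reproduced beyond ±0.01 mmHg
  in 3 of 51 cells (see above); the package sides with the defining
  equation.
* Published summary statistics of the original study are inputs for
  desk-scale checks, not recomputable results, because the field data are
  not deposited.
* Bland–Altman pooling ignores within-subject correlation.
* The simulator's failure process is independent across rounds and sites
  share one failure-mode mixture; age distributions are uniform within
  the eligible range.
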