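# Methods

`diabetyping` implements an OGTT-based pipeline for pathophysiological
subtyping of type 2 diabetes (T2D), adjudication of diabetes
remission/reversal against structured medication records, and
longitudinal cohort summaries, together with a synthetic cohort
generator that makes every stage testable without patient data.

## Indices and unit conventions

All indices are computed from a five-point OGTT (t = 0, 30, 60, 90,
120 min) with plasma glucose in mmol/L and insulin in mU/L. The
formulas never state their units unambiguously in the clinical
literature, so the package fixes them explicitly:

| Index | Formula | Units |
|---|---|---|
| HOMA-IR | fG·fI / 22.5 | glucose mmol/L |
| HIRI | fG′·fI | glucose mg/dL (×18.0 exactly) |
| Matsuda | 10⁴ / √(fG′·fI·mG′·mI) | glucose mg/dL |
| Disposition (DI) | [AUC₀₋₃₀(insulin)/AUC₀₋₃₀(glucose′)] × Matsuda | glucose mg/dL |
| MISI | 100·(ΔG′/Δt)/mI | glucose mg/dL, Δt min |

fG/fI are the fasting values, mG/mI arithmetic means over all five
samples, AUCs trapezoids over [0, 30] min. With these conventions the
identity `HIRI = HOMA-IR × 22.5 × 18 = HOMA-IR × 405` holds exactly —
both read the same fasting sample — and it reproduces published
per-participant value pairs (e.g. HOMA-IR 11.8 ↔ HIRI 4779) to within
rounding, which is how the ×18.0 convention was validated.

### MISI conventions

The slope-over-insulin definition of MISI does not pin down which ΔG,
which Δt, or the sign. Two conventions are shipped:

* `span_slope` (default): 100 × (Gmin′ − Gmax′) / duration / mI, with
  the extrema taken over the five samples and the duration between them
  taken positive. The value is never positive; its magnitude is the
  glucose change per minute per unit insulin across the curve's full
  span. A steep decay with modest insulin (an insulin-sensitive
  pattern) gives a large negative value; a curve that keeps rising
  under high insulin gives a value near zero.
* `peak_decay`: the classic decay-rate variant, positive for a curve
  that falls off its peak, 0 (with a warning) for a monotonically
  rising or flat curve.

Neither is claimed to be the convention used in any particular study;
`span_slope` reproduces the uniformly negative values and magnitudes
typical of published T2D cohorts.

Consequence for classification direction: under `span_slope`, *muscle
insulin resistance corresponds to MISI near zero*, i.e. **above** the
cutoff. This follows both from the algebra (poor disposal ⇒ shallow
decay per unit insulin) and from published participant trajectories,
where MISI moves away from zero as muscle sensitivity improves and a
cohort-level MISI rise toward zero coincides with additional
combined-IR calls. The degenerate flat curve returns MISI = 0 with a
`misi_flat` flag and a warning.

## Subtyping

Three boolean flags — hepatic IR (HIRI above cutoff), muscle IR (MISI
above cutoff), impaired beta-cell function (DI below cutoff) — map
bijectively onto eight labels: healthy, HIR, MIR, CIR and the
impaired-beta-cell variants IB, IB-HIR, IB-MIR, IB-CIR. Equality with
a cutoff always resolves to the unimpaired side, so the healthy cell is
closed. HOMA-IR and Matsuda are carried in the panel but do not enter
the decision.

The numeric cutoffs used in the original clinical work were derived
from multi-study reference cohorts that are not publicly available and
were never published, so cutoffs here are configuration
(`CutoffConfig`, JSON on disk). `calibrate_cutoffs` provides a
transparent stand-in: per index, the threshold maximizing Youden's
J = sensitivity + specificity − 1 for separating labeled T2D from
healthy reference panels, with candidates at midpoints between adjacent
observed values and ties broken toward the midpoint of the tied
candidates. When the best J is below 0.2 — about the bias of a maximum
over thresholds on null data — the index is declared non-separating and
the pooled median is returned with a warning.

The packaged synthetic reference (`reference_panels`) contrasts the
healthy archetype with the fully impaired IB-CIR archetype, so each
index sees a clean two-class difference; on it, the three Youden
problems are all essentially separable (J ≈ 1).

## Remission and reversal

Per visit, from HbA1c (mmol/mol), fasting plasma glucose (mmol/L) and a
medication comparison against the trial-start visit:

* remission — FPG ≤ 6.9 and HbA1c < 48 and no glucose-lowering
  medication of any class;
* reversal — HbA1c ≤ 53 and FPG < 8.0 with reduced (or stopped)
  medication, or HbA1c < 48 and FPG ≤ 6.9 with unchanged medication;
* T2D otherwise.

Boundaries are strict exactly as written; remission precedes reversal.
"Reduced" is formalized as a lattice comparison on (drug class, daily
dose) sets: a strict subset of classes, or identical classes with every
dose ≤ baseline and at least one strictly lower. Mixed changes (one
dose up, another down) and any new class count as increased — the
conservative reading, which prevents gaming reversal by substitution.
Doses are compared only within identical (class, unit) pairs; unit
mismatches raise rather than attempt conversion. Only glucose-lowering
classes (metformin, sulphonylurea derivatives, insulin, GLP-1 agonists,
other) enter the adjudicator; blood-pressure and lipid drugs are
summary-only. The ≥ 1-year duration criterion of consensus remission
definitions is out of scope: adjudication happens at the 3- and 6-month
visits. The medication reference visit is configurable
(baseline by default).

## Cohort summaries

Per-visit arithmetic means and sample SDs (n − 1), with missing values
excluded pairwise and counted; a |z| > 3 standardized-residual outlier
mask (boundary kept); and two-sided paired t contrasts between visits,
optionally on log10-transformed values (the transform list is
configuration since which variables need it is data-dependent). No
multiple-testing correction is applied. Mixed-effects modelling with
post-hoc contrasts is deliberately not re-implemented: the outputs are
labeled paired contrasts, which cannot and do not reproduce
model-based p-values from any particular study.

## Synthetic cohort generator

The generator's purpose is statistical, not physiological: to produce
five-point curves whose index panels land on the correct side of
calibrated cutoffs for each named archetype, plus labs and medication
records with the dependency structure the adjudicator assumes.

Glucose follows a discrete balance on a 5-minute grid,

    G(t+Δ) = G(t) + [a(t) − k·I(t)·(G(t) − G_floor)]·Δ

with a fixed gut-appearance rate `a` over 0–60 min, insulin-dependent
disposal `k` (the muscle axis), and a floor 1.5 mmol/L below fasting
(hepatic output keeps fasting glucose elevated). Insulin is the
fasting level plus a triangular first-phase bump peaking at 30 min
whose amplitude scales with fasting glycemia and with `beta_cell_gain`
(the beta-cell axis: impaired beta cells blunt exactly this early
response) plus a late-phase term `late_secretion_gain` × excursion that
ramps in after 30 min. Multiplicative lognormal noise with CV 0.05
(default) is applied per sample. A difference equation rather than an
ODE solver: at this sampling density the added fidelity would be
invisible to the indices.

### Archetype parameterization

The three pathophysiology axes steer distinct parameters: hepatic IR →
elevated fasting glucose–insulin product; muscle IR → low `k` with
abundant insulin (glucose keeps climbing, MISI near zero); impaired
BCF → first-phase gain near zero (low DI). The four impaired-BCF
archetypes sit at overt-diabetic magnitudes (fasting glucose
~12 mmol/L, 2-h glucose ~13–18 mmol/L, fasting insulin ~24 mU/L for
the hepatic ones, HOMA-IR ≈ 12.8, Matsuda ≈ 1.5), matching a
long-standing-T2D primary-care population. The BCF-normal IR
archetypes (HIR, MIR, CIR) are compensated hyperinsulinemic
pre/early-diabetic states (fasting glucose 6–7 mmol/L): with overt
fasting hyperglycemia, the Matsuda collapse would push a BCF-normal
archetype's DI *below* that of normoglycemic impaired ones, making a
single DI cutoff impossible — and a still-compensating beta cell
cannot coexist with fasting glucose of 12 mmol/L anyway.

Two known artificialities: (1) muscle-IR archetypes carry a large
late-phase insulin response (delayed hypersecretion — a described
early-T2D pattern, but exaggerated here) because the MISI denominator
is what separates them from rising-curve non-muscle archetypes;
(2) the isolated-IB archetype is insulinopenic (fasting insulin
~6 mU/L) so that its fasting product stays below the hepatic cutoff.
Numeric archetype parameters were chosen so that every archetype's
noise-free panel clears each calibrated cutoff with a relative margin
of roughly 1.3× or better; at 5% measurement noise each archetype is
recovered ≥ 97% of the time.

Within the monotone-rising (diabetic) regime, increasing `k` shrinks
the glucose span and moves span-slope MISI toward 0, and decreasing
`beta_cell_gain` strictly decreases DI; these monotone read-outs are
property-tested. Outside that regime (healthy-like crash curves) MISI
is not globally monotone in `k` because the discrete sampling extrema
jump between time points.

### Visits, labs, medication

Study visits (baseline, month 3, month 6) apply effect multipliers to
fasting glucose, fasting insulin, beta-cell gain and disposal. The
default intervention profile (fg ×0.73 at month 3, ×0.87 at month 6;
fi ×0.73 then ×0.58; gain ×1.2 then ×1.1; disposal ×1.4 then ×1.6)
reproduces a marked 3-month improvement with partial glycemic relapse
at 6 months and only slight beta-cell recovery. Two per-participant
scalars add realistic heterogeneity: a responder scalar r (SD 0.4)
that scales every effect, and a right-skewed relapse scalar (mean 0.8,
SD 0.8, truncated at 0) that interpolates the month-6 state between
the participant's own month-3 state and the average relapse — so a
minority of strong responders reach and keep remission while the
cohort mean rebounds.

HbA1c is affine in a daily-glycemia proxy (midpoint of fasting and
OGTT-mean glucose): 14.6 + 3.65 × proxy + N(0, 2) mmol/mol,
coefficients chosen so the impaired baseline archetypes land near
68 mmol/mol and healthy near 36. This is a synthesis device, not a
glycation model. Baseline medication is assigned by archetype
(metformin for all T2D archetypes, plus sulphonylurea for combined-IR,
insulin for every third IB-CIR participant); follow-up visits
de-escalate deterministically when the simulated labs cross the
remission (stop all) or target (halve metformin, stop
secretagogues/insulin) thresholds. Medication-free participant-visits
are written as explicit `drug_class=none` marker rows so the
adjudicator can distinguish "unmedicated" from "record missing".

Seeding: one root seed; every draw comes from a
`numpy.random.default_rng([seed, stream, index])` counter-style key,
so any subset of participants/visits is reproducible independent of
generation order, and cohorts are byte-identical across runs.

What passing tests on this generator do **not** show: fidelity of real
OGTT kinetics (no incretin effect, no meal variability, no
within-participant day-to-day variance), realism of the archetype
frequencies, or transferability of the calibrated cutoffs to real
cohorts. They show that the pipeline's logic — indices, calibration,
classification, adjudication, counting — is correct and internally
consistent under a data-generating process with the assumed structure.

## Numerical choices and degenerate inputs

* Curves are validated at construction: strictly increasing times
  starting at 0, positive concentrations, matching lengths. The full
  panel requires exactly the canonical five times; HOMA-IR/HIRI need
  only t = 0. No imputation of missing samples — partial visits are
  flagged by the reader and skipped by `compute-indices`.
* Flat glucose curves score MISI 0 with a flag; AUC windows must start
  and end on sampling times (no extrapolation).
* Youden ties resolve to the midpoint of the tied candidates; a
  constant index falls back to its single value; J ≤ 0.2 falls back to
  the pooled median with a warning.
* Paired contrasts with zero-variance differences report p = 1 when
  the mean change is 0 ("no change") and p = 0 otherwise.
* The |z| > 3 outlier mask is a pure threshold; it does not recompute
  residuals, so iterating it requires re-fitting externally.

## Problem sizes

The packaged defaults — 200 panels per class for calibration, 150
curves per archetype for recovery checks, cohorts of 15–300, 200
replicates for the paired-test power simulation — were chosen as the
smallest sizes at which the binomial/Monte-Carlo error is well inside
the asserted margins.

## Known limitations

* The span-slope MISI conflates states: a compensated hyperinsulinemic
  pure-hepatic-IR phenotype has a small excursion and a large mean
  insulin, pushing its MISI toward the muscle-IR side; the generator's
  HIR archetype therefore needed a large meal excursion to separate.
  On real data this axis should be treated as the least reliable of
  the three.
* Calibrated cutoffs are only meaningful relative to the reference
  cohort that produced them; the packaged synthetic reference does not
  transfer to real populations.
* The adjudicator compares doses only within identical units; regimens
  recorded in mixed units must be normalized upstream.
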