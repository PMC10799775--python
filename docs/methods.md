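# Methods

## Event model

A procedure is a sequence of annotated gesture bouts `(gesture, start_s,
stop_s[, arm])` from the five-label taxonomy used for general surgical
gestures in simulated RARP: regular dissection, hemostatic control, clip
application (dissection modules) and needle handling, suturing
(anastomosis).  Bouts may overlap because up to three robotic arms are
annotated; zero-length bouts are rejected.  The procedure clock runs from
the first annotated start to the last annotated stop — leading and
trailing un-annotated recording is deliberately excluded, because idle
time is defined as the gaps *between* annotated phases, not as absence of
annotation.

## Phase decomposition

Active phases are the maximal disjoint intervals of the union of all
bouts; touching intervals merge.  Idle phases are the gaps between
consecutive active phases.  This makes active + idle = total an exact
identity, which the tests enforce against a brute-force occupancy-grid
oracle.  Per-gesture total times intentionally use raw bout durations
(before the union): two arms performing gestures simultaneously both
contribute to their own gesture totals, while phase metrics see a single
active interval.

Participant summaries average repetitions per module; the pooled
("overall") row is the equal-weight mean of the per-module means.  Equal
module weighting is the aggregation under which a pooled group row is an
exact average of its per-module rows; per-procedure weighting is available
via `overall="procedure_mean"`.  Group comparison uses the classical
equal-variance two-sample *t*-test (Welch by flag).

## Synthetic cohorts

The generator is an alternating renewal process per (group, module):

* number of active phases `n ~ Poisson(n_active_mean)` truncated at ≥ 1;
* active and idle durations lognormal, moment-matched to the target
  mean/SD (positive support and right skew typical of task times);
* each of the `n − 1` phase boundaries carries an idle gap with
  probability `p_gap`, calibrated in closed form so the expected idle
  fraction matches the target idle percentage:
  `p_gap = clip((f/(1−f)) · n·a / (g·(n−1)), 0, 1)` with `f` the target
  fraction, `a`/`g` the mean active/idle durations;
* gesture labels i.i.d. from a per-module mix (clip application only
  during neurovascular-bundle dissection; needle handling/suturing only
  in the anastomosis);
* one lognormal subject effect per participant (mean 1, CV
  `between_subject_cv`, default 0.25) multiplies every duration, shared
  across that participant's procedures;
* a per-repetition learning factor (default 0.85 novices, 0.95
  experienced) scales durations by `factor^(repetition−1)`.

Defaults are the published group × part-procedure summary rows (idle-phase
mean/SD, idle %, active-phase mean/SD, phase count N).  The default cohort
is 10 novice and 6 experienced completers, 3 modules × 3 repetitions; an
enrolment-style design with 4 non-completers is also bundled.

Three structural facts about this model matter when interpreting results:

1. The five summary marginals are mutually inconsistent under *any*
   alternating renewal process (e.g. 45 phases × 10 s + 44 gaps × 21 s =
   1374 s cannot coexist with a 1150 s total at 61.6 % idle): published
   rows are participant averages of per-procedure ratios, which do not
   compose multiplicatively.  The gap calibration prioritises the idle
   share and, in consequence, the total duration; the *extracted*
   active-phase count then falls below the Poisson mean, because
   boundaries without a gap produce touching phases that the union merges
   (expected extracted count `1 + (n−1)·p_gap`).
2. For the anastomosis rows the printed idle percentages (83/84 %) are
   unattainable at the printed phase counts and durations, so `p_gap`
   clips at 1 and the realised idle share tops out near 70 %.
3. With these defaults the z-composite separation between groups is
   d ≈ 1.5, so the contrasting-groups standard misclassifies boundary
   participants in most replicate cohorts (median sensitivity ≈ 80 %,
   specificity ≈ 83 %), and ICC(A,k) of total durations lands near
   0.74–0.86 — the novice learning factor creates a repetition effect that
   absolute agreement penalises.  Full discrimination as reported on real
   cohorts rests on qualitative gesture-usage differences (what novices do,
   not only how slowly) that a duration-scaling simulator does not encode;
   simulating kinematics or per-arm coordination is out of scope.  Passing
   tests on synthetic cohorts therefore validate the computational
   pipeline, not the clinical effect sizes.

## Reliability

ICC(A,k) from two-way ANOVA mean squares: `(MSR − MSE)/(MSR + (MSC −
MSE)/n)`.  Confidence intervals use the McGraw–Wong F-based method with a
Satterthwaite-approximated df, computed for the single-measure coefficient
and stepped up by Spearman–Brown; when the residual mean square is zero
the df takes its limiting value `(n−1)(k−1)`.  The default score is the
per-repetition total procedure duration (any feature column can be
selected).  Complete matrices are required — participants missing a
repetition must be excluded upstream, mirroring completer-only analysis.
The implementation is cross-checked in tests against an independent
sums-of-squares oracle (1e-10) and against `pingouin.intraclass_corr`.

## Standard setting

z-scores use the experienced group as reference, stratified by
(gesture, module) and pooled over the reference group's repetitions —
pooling chosen for stability with only 6 reference surgeons × 3
repetitions per cell.  Cells whose reference SD is zero (gesture unused in
a module) are excluded everywhere, with a warning.  The composite is the
mean over a participant's defined cells, negated so that experienced
surgeons centre near 0 and slower novices score negative; the cutoff is
also reported in SD units of the pass group.

The contrasting-groups cutoff is the intersection of the two fitted
normal densities between the group means (midpoint for equal SDs; root of
the log-density quadratic otherwise, verified against a bisection oracle).
With strongly unequal SDs the densities may not cross between the means;
the cutoff then falls back to the equal-standardised-distance point
`(μ₁σ₂ + μ₂σ₁)/(σ₁ + σ₂)`, which is always bracketed by the means and
converges to the crossing point as the SDs equalise.  Classification uses
a ≥-cutoff pass rule; sensitivity is the percentage of the fail group
below the cutoff and specificity the percentage of the pass group at or
above it.

## Progression PCA

Attempt-level features (six phase metrics + five gesture totals) are
z-standardised per fit; constant columns are dropped with a warning.  PCA
is fitted per module by default (pooled by flag) with 2 components.  The
"target" is the centroid of the experienced group's attempts in the
component plane — the minimal-assumption reading of progress arrows
pointing toward the expert cluster; distance to target is computed per
attempt, magnitude between consecutive repetitions.  Both metrics are
invariant to component sign flips (tested).  On default synthetic cohorts
the novice mean distance to target exceeds the experienced mean decisively
(p < 0.05); the magnitude difference is directional in most replicates but
its significance varies — novice steps combine systematic improvement with
the same sampling noise the experienced steps consist of.

## Snail tracks

Occupancy is computed per gesture on the procedure's normalised clock
([first start, last stop] → [0, 1]) with 200 bins by default, each cell
the covered fraction of its bin (same-gesture overlaps unioned first);
group tracks are element-wise means across procedures.  Normalised time is
used because procedures differ in length severalfold; absolute-time
averaging would conflate rhythm with speed.  Row sums conserve each
gesture's time share exactly.  Matrices are emitted as delimited text;
rendering them as coloured strips is left to the caller's plotting stack.

## Numerical and interface choices

* Lognormal moment matching: `σ² = ln(1 + cv²)`, `μ = ln(m) − σ²/2`; a
  zero SD degenerates to a constant duration.
* Deterministic generation: one `numpy` Generator per cohort, participants
  processed in sorted order; same seed → byte-identical event logs.
* Event-log text format writes times with shortest-repr floats so
  read∘write is the identity on event content; comma/tab autodetected.
* t-tests via `scipy.stats.ttest_ind`; both-groups-constant degenerate
  input reports p = 0 (distinct means) or t = 0, p = 1 (equal means).
* The `gesturelab` CLI (click) exposes each stage and `run-all`; the
  pipeline writes a manifest (config hash, seed, version) and skips stages
  whose preconditions fail, with the reason recorded.

## Problem sizes

The reproduction script uses 20 replicate completer cohorts
(10 + 6 participants × 9 procedures) for the classification target and
1000 procedures per group × module for the parameter-recovery targets —
enough that Monte-Carlo standard errors are well below the structural
deviations discussed above.

## Known limitations

* The generator models skill as multiplicative duration/count scaling;
  gesture-sequence structure (clustered hemostatic control, early vs late
  clip use) is not simulated, so snail-track group differences are muted
  relative to real cohorts.
* Within- vs between-subject variance decomposition is a modelling choice
  (no published decomposition exists); it is surfaced as
  `between_subject_cv` rather than asserted.
* The contrasting-groups fit assumes normal composite scores; with n = 16
  completers the fitted tails, and hence the cutoff, are noisy.
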