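# Methods

## The measurement model

A thermometric brassiere records the breast surface temperature once per
minute during a standardized evening session. After the sensor equilibrates
with the deep tissue, the trace flattens at the deep-breast temperature —
the same principle as deep-body thermometry. The day's *vascularity index*
is the deep-breast temperature minus the simultaneously measured oral
temperature (°C): the oral reading proxies arterial blood temperature, so
the subtraction removes each woman's hypothalamic set point and isolates
the breast-specific component. Values are negative (the breast is cooler
than the core); *less* negative means *more* vascular.

## Plateau extraction

The informal notion of a "peak plateau" is made operational as:

1. flag and exclude samples outside 25–42 °C;
2. discard the first 30 min of each session (warm-up / preliminary span;
   `discard_initial`);
3. smooth with a centered moving average (default 5 min, shrinking at the
   edges);
4. compute per-minute slopes of the smoothed trace (forward differences,
   divided by the minute gap so sparse traces are handled);
5. find maximal runs of consecutive slopes with magnitude ≤ `slope_tol`
   (default 0.02 °C/min) spanning ≥ `min_duration` (default 10 min);
6. report the run with the highest mean smoothed level, ties broken toward
   the latest run; the mean level over the run is the plateau temperature.

If no run qualifies the maximum of the smoothed trace is returned flagged
`no-plateau`; traces shorter than `min_duration` after the warm-up span are
flagged `short-trace` with no numeric value. The run-scan is equivalent to
exhaustive enumeration of all maximal qualifying windows (a property the
test suite checks against an independent brute-force implementation). The
defaults were chosen for physical plausibility — a sensor with a ~8 min
equilibration time constant is flat to well under 0.02 °C/min after 30
min — and are all exposed as parameters.

## Backwards synchronization

Each subject's calendar days are relabeled counting back from the menses
onset that terminates the studied cycle: onset day = +1, the previous day
−1, back to −28 (earlier days dropped); the day after onset is +2 (later
days dropped). Day 0 does not exist. For any arithmetic spanning onset
(cosinor time axis, moving averages), label ℓ maps to t = ℓ for ℓ < 0 and
t = ℓ − 1 for ℓ > 0, so −1 and +1 are adjacent and t = 0 is the onset day.
Left and right breast temperatures are averaged when both are present;
one-sided days use the available side. Cross-subject daily means carry
per-day n, which legitimately varies with missingness.

The 3-day moving average used for presentation takes a centered window on
the mapped axis, shrinking to two days at the series ends and skipping
absent days (only immediately adjacent days enter a window). This edge
policy keeps the smoothed series spanning the full −28…+2 window.

## Cosinor rhythmometry

The rhythm model is a single fixed-period cosine,
y(t) = M + A·cos(2π(t − φ)/τ) + e with τ = 28 d, fitted by ordinary least
squares on the linearized regressors cos(ωt) and sin(ωt). The period is
held at 28 d even though individual cycles span 19–39 d, because fitting
happens on the backwards-synchronized axis where the luteal phases align.
Amplitude and acrophase are recovered from the coefficients via
A = √(β_c² + β_s²) and φ = atan2(β_s, β_c)/ω; φ is reported in days after
menses onset on [0, 28). Rhythm detection is the zero-amplitude F test,
F = ((RSS₀ − RSS)/2)/(RSS/(n − 3)), with the conventions p = 1 for an
exactly constant series and p = 0 for an exactly fitted one. Fits require
≥ 4 distinct time points and a non-collinear design (times not all equal
modulo τ).

Group-level fits pool all subject-day points of a group rather than
averaging per day first, which keeps unequal per-day subject counts
honestly weighted; a daily-means variant is available
(`pool="daily-means"` / `cosinor_on_moving_average`). Phase comparisons use
the signed circular difference in (−τ/2, τ/2]; negative means
phase-advanced.

## Luteal-window statistics and prognostic scoring

Group comparisons run on the 11 cross-subject daily means of cycle days
−11…−1, summarized as mean ± sample SD (n − 1 denominator) and compared
with two-tailed unpaired t-tests. The pooled-variance Student test
(df = n₁ + n₂ − 2 = 20 for complete windows) is the default because it is
the variant under which the bundled reference daily values reproduce the
originally reported p-values (0.0062 controls vs survivors, 0.0006
non-survivors vs controls); Welch's test is available behind a flag.
Comparing daily *means* rather than subject-level values is deliberate: it
is the only reading reproducible from the printed data, and the bundled
table stores exactly those means. Note one known print anomaly: the
non-survivor column mean recomputes to −1.24 °C from its own daily values
although the source table prints −1.25; this package always reports the
recomputed value.

The Nottingham Prognostic Index is 0.2 × size(cm) + grade + nodal stage
(stage 1: 0 nodes, 2: 1–3, 3: ≥4), undefined for in-situ disease. Every
invasive row of the bundled pathology table reproduces its printed score
exactly except one (57 mm/G2/0 nodes, printed 4.15 vs computed 4.14,
consistent with an unrounded size upstream). Report rounding follows the
source tables: temperatures 2 dp, differences 3 dp, survival 1 dp, NPI 2 dp.

## The synthetic-cohort generator

The generator emulates the study conditions the analysis assumes, per
subject:

- cycle length L ~ uniform integer on [19, 39] d; luteal length uniform on
  [12, 14] d; records run from the previous menses onset (raw day 1)
  through onset +1 day, so a 39 d cycle yields 39 pre-onset days of which
  synchronization retains 28;
- a body-temperature set point drawn uniformly over a 2.36 °C range, added
  to breast *and* oral channels (it cancels in the vascularity index, which
  is the point of the normalization);
- oral temperature = 36.4 °C + set point + a 0.33 °C step after ovulation
  (the basal-body rise), ovulation at −(luteal length);
- a vascularity rhythm: cosine with amplitude 0.335 °C (half the 0.67 °C
  luteal vascularity rise, which together with the oral step gives the ~1 °C
  total luteal breast rise), period equal to the subject's own cycle length,
  peaking at the group acrophase (defaults 27.4 / 21.5 / 20.1 d after onset
  for controls / survivors / non-survivors). The subject's MESOR is solved
  so that the noise-free mean over days −11…−1 equals the group luteal
  level (defaults −1.42 / −1.65 / −1.25 °C) plus a subject-level offset —
  i.e. the level parameter is *defined* as the luteal-window mean, making
  the calibration exact by construction for any cycle length. An optional
  asymmetric (saw-tooth) shape with a slow rise and fast fall is available;
- progesterone: a Gaussian bump over a 30 pM/L baseline peaking at 300 pM/L
  on day −6 with 3 d width, hence rising from around day −12 — the source
  gives timing, not a functional form;
- independent Gaussian daily noise (default SD 0.15 °C per channel — left
  and right breasts differ only by this noise), a between-subject luteal
  level SD (default 0.15 °C; the source reports only across-day SDs of
  group means, so this is a package choice of a realistic between-woman
  spread), and 15% of subject-days missing uniformly at random;
- per-minute traces: saturating exponential from 32 °C toward the day's
  breast value with time constant 8 min over 90 min, plus 0.05 °C per-minute
  noise;
- pathology for cancer subjects: survivor node counts Bernoulli(1/18),
  non-survivor counts geometric with mean 1.0 (matching the reported group
  means 0.06 and 1.00), sizes lognormal around ~25 mm, grades weighted
  toward 2–3, one in six survivor tumours in-situ.

What the generator does *not* emulate: ambient/clothing effects, sensor
drift, structured (non-random) missingness, anovulatory cycles,
within-cycle autocorrelated noise, and any dependence of vascularity level
on pathology covariates. Passing recovery tests therefore demonstrates
that the pipeline is a consistent estimator of the structure it models, not
that real recordings are this well behaved.

## Problem sizes and runtime choices

The parameter-recovery experiment uses 50 cohorts of 18 subjects per group
(the study's cancer-group size) with default noise and missingness; the
plateau-oracle comparison uses 200 randomized traces of 45–120 min; the
grid-search cosinor oracle uses a 31–61-point grid per parameter on series
of 8–30 points. These sizes give stable Monte-Carlo estimates (ordering
recovery is essentially deterministic at n = 18/group; group acrophase mean
recovery errors are 0.3–0.7 d) while keeping the full suite around 15 s.

With subject rhythm periods of 19–39 d fitted by a fixed 28 d cosine, the
recovered group acrophase carries a small systematic bias (largest, ~0.6 d
early, for the control group whose peak lies at the edge of the −28…+2
window). This is inherent to the period mismatch of backwards-synchronized
fitting, not an estimator defect; it is why recovery is asserted on the
across-seed mean acrophase (well within 1.5 d) rather than per seed.

## Known limitations

- The plateau criterion is one defensible operationalization of an
  informally described procedure; raw-maximum behaviour is available as the
  `no-plateau` fallback but a slope-criterion/maximum hybrid archive match
  cannot be verified.
- Group MESORs of the original full-cycle daily series (and the progesterone
  MESORs) are not reproducible from printed data; the package validates the
  cosinor stage by exact recovery, an optimality oracle and synthetic
  parameter recovery instead.
- Survival analysis is deliberately descriptive (means/medians); no
  Kaplan–Meier or Cox modelling.
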