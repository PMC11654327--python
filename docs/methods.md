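# Methods

This note documents the generating model, the estimation procedure, the
accuracy metrics and the design choices behind `vescasim`, in the spirit of
a model-description vignette. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Generating model

One simulated OSCE consists of `n_students` (default 60) students in
`n_cohorts` (4) cohorts rotating through `n_stations` (12) stations, scored
on an integer scale `scale_min..scale_max` (6–27; range 21 points). Three
sequential processes produce the data:

**True performance.** For student *k* on station *i*:

    true_ki = grand_mean + ability_k + station_i + interaction_ki

with `ability ~ N(0, 1.13)`, `station ~ N(0, 1.52)`,
`interaction ~ N(0, 1.71)` and `grand_mean = 19.47` (all in raw score
points; the SDs correspond to 5.4%, 7.2% and 8.1% of the 21-point scale).
True scores are continuous and are never rounded or clamped; each student's
*true mean* over stations is the accuracy target.

**Observed live scores.** One examiner occupies each (station, cohort) slot
(48 examiners at defaults; 4 × `n_stations` in general, preserving examiner
density when station count varies). Examiner leniency is `N(0, 1.40)`
(positive leniency adds to scores; stringency is negative leniency). The
recorded mark is

    score = clamp(round(true_ki + leniency_j + ε), 6, 27),   ε ~ N(0, 2.35 / error_divisor)

Rounding is nearest-integer half-up. The residual ε absorbs everything not
modelled explicitly (time-of-day, contrast and halo effects, examiner ×
student interactions); `error_divisor` (1, 2, 4 or 8) shrinks it to probe
how random scoring noise limits adjustment. Examiner × station effects are
structurally absent because each examiner stays on one station.

**Video linking.** Per station, `n_videos` (default 4) distinct student
performances are drawn uniformly from all students and nominated as videos.
Every *participating* examiner of that station (participation flags are
independent Bernoulli(`participation`), default 0.80) scores every video of
their station with their own leniency and a fresh residual draw,
independent of the live residual for the same performance. Video records
carry the filmed student's identity and the scoring examiner's cohort; at
defaults they are ≈ 17.6% of all records.

**Baseline differences.** A between-school offset of `baseline_diff`
(fraction of the scale range; 0–20%) models systematically different
examiner standards: cohorts {1,2} form school A, {3,4} school B; school-A
students gain `baseline_diff × range / 2` ability while school-A examiners
lose the same amount of leniency, and school B receives the opposite signs.
Expected observed means are therefore equal across schools — the offset is
invisible in raw scores — while true ability and examiner severity each
differ by the full `baseline_diff × range` between schools. The per-school
shift convention (±half) is what makes the mean observed error ≈ 2.1 points
at a 20% difference on a 21-point scale.

## 2. The measurement model and its estimation

Adjustment fits the three-facet rating-scale Rasch model on
adjacent-category log-odds,

    log(P_nijk / P_nij(k-1)) = B_n − D_i − C_j − F_k,

by joint maximum likelihood: damped (step-capped at 1 logit) Newton–Raphson
updates alternate over student measures, station difficulties, cohort
severities and thresholds until the largest absolute change is below
`convergence_tol` (1e-3 logits) or `max_iterations` (100) is reached;
unconverged fits are flagged but their estimates are still used, as they
would be in practice. Facet updates use the diagonal expected-information
step `(observed − expected total) / Σ variance`; thresholds, whose
information matrix is strongly non-diagonal for adjacent categories, get a
joint Newton step with the exact (K−1)×(K−1) Hessian
`−Σ Cov(1{X≥k}, 1{X≥l})`.

Numerical and identification choices:

- **Categories.** The model is fitted on the distinct raw scores actually
  observed (typically ~20 of the 22 at defaults): unobserved extreme
  categories are dropped and unobserved interior categories merge with
  their lower neighbour. Fair averages are computed over the observed raw
  values, so adjusted scores return to the 6–27 scale.
- **Gauge.** Stations, cohorts and thresholds are mean-centred (with the
  compensating shift applied to student measures); student measures are
  free. Probabilities are computed with log-sum-exp normalisation.
- **Extreme totals.** Elements whose raw total is at the minimum or maximum
  possible are given a ±0.3-point total adjustment so their measures stay
  finite (the conventional rater-measurement default).
- **Connectivity.** Cohort severity differences are identifiable only if
  the bipartite person–cohort observation graph connects the cohorts, which
  requires cross-cohort video scores. With no videos (or no participants)
  the design is fully nested; `anchor_policy="auto"` then anchors all
  cohort severities at 0, which makes the 0-video condition well defined
  and reduces adjustment to a pure Rasch round trip. When some but not all
  cohorts are linked, severities are centred within each connected subset.
- **Video persons.** Video records enter the fit as separate person
  elements (one per filmed performance), not as extra observations of the
  live student. Video scores therefore inform severity, difficulty and
  threshold estimates but never a student's own measure — consistent with
  the linking design, in which video scores are not part of any student's
  result. Sharing the live element instead would let video-scorer noise,
  and the duplicated student×station interaction of a filmed performance,
  leak into filmed students' measures; the option is kept available as
  `MfrmConfig(separate_video_persons=False)` for comparison.

**Adjusted scores.** A student's adjusted score is the fair average: the
model-expected raw score at their measure with station difficulty and
cohort severity at 0. It is strictly increasing in the measure, and with
anchored severities it reproduces observed means to within a few
hundredths of a point (the round-trip noise measured by the 0-video test).

## 3. Accuracy metrics

Per student and replicate, against the continuous true mean:

- observed error A = |mean of live scores − true mean| (video scores are
  excluded from observed means),
- adjusted error B = |fair average − true mean|,
- adjustment C = |fair average − observed mean|,
- improved = (B < A), strictly — ties count as not improved.

"Error" is the absolute difference of per-student *means* (one observed
mean vs one true mean), matching the single overall adjusted score per
student; the analytic value at defaults,
√((1.40² + 2.35²)/12)·√(2/π) ≈ 0.63, provides an independent cross-check of
the whole generation pipeline. A condition pools all students across
replicates: ErR is the ratio of pooled mean errors (not the mean of
per-replicate ratios) and pAcc the pooled improved fraction; reported SDs
are pooled student×replicate SDs.

**Adjustment-size thresholds.** Students are binned by C as a percentage of
the scale range ([0,1%), …, [8,9%), ≥9%) and by accuracy change (A − B) in
2%-wide bins; interior accuracy-change bins are closed on the non-positive
side so an exact tie lands on the "not improved" side. The reported
threshold is the smallest adjustment bin holding at least `min_bin_count`
(20) pooled students such that it and every equally supported higher bin
reach pAcc ≥ 0.8. The support rule exists because near-empty tail bins
(a handful of students) would otherwise certify or block a threshold on
sampling noise; 20 students bounds the binomial SE of a bin's pAcc at
roughly 0.09.

## 4. Study grids, seeding and problem sizes

- Study 1: videos {0,2,4,6,8} × participation {0.50,0.65,0.80,1.00} at 0%
  baseline (20 conditions).
- Study 2: baseline {0,5,10,20}% × stations {6,12,18} (12 conditions).
- Study 3: `error_divisor` {2,4,8} at otherwise default parameters.

Marginal summaries for one factor are simple means of condition-level ErR /
pAcc across the other factor's levels.

Each replicate's RNG stream derives solely from (master seed, condition id,
replicate index) via `numpy` `SeedSequence` spawn keys, so results are
bitwise reproducible and independent of scheduling or parallelism
(`joblib` can distribute conditions). Replicate presets: `paper` = 1000,
`desk` = 200. The package's routine runs, the test suite and the
acceptance script use 100–200 replicates per condition; at that size the
Monte-Carlo standard error of a condition ErR is well under 0.05, which is
the comparison band used throughout.

## 5. What the generator does and does not emulate

The generator reproduces the structure of a real distributed OSCE —
bounded integer marksheets, nested examiner cohorts, sparse video linking,
participation dropout, hidden between-school offsets — with all effects
additive, normal and unidimensional. It does not emulate: multi-domain
item-level scoring (scores are single 6–27 sums), examiner × station or
examiner drift/contrast/halo effects (folded into ε), non-normal or skewed
ability distributions, or correlation between participation and stringency.
Passing tests therefore demonstrate correct behaviour *under this
generating model*, not under every pathology of real rating data.

Two structural consequences are worth knowing when interpreting results.
First, severity adjustment can at best remove the *centred participating*
cohort means: the common severity level of all examiners is unidentifiable,
and non-participating examiners contribute no linking information, so even
an oracle adjustment leaves a floor of residual error. Second, because
severity-estimation noise is roughly constant across station counts while
observed error shrinks with more stations, ErR at 0% baseline drifts
slightly above 1 as OSCEs get longer — gently, in these simulations.

## 6. Known limitations

- JMLE carries the usual incidental-parameter bias; no bias correction is
  applied (deliberately, to mirror standard rater-measurement practice).
  The tiny-instance oracle test checks agreement with direct likelihood
  maximisation, not unbiasedness.
- Fit statistics (infit/outfit), standard-error calibration and
  bias/interaction analyses are out of scope.
- With very sparse linking (2 videos, 50% participation) a few percent of
  replicates do not reach the 1e-3 convergence tolerance within 100
  iterations; they are flagged and included, and their severity estimates
  are correspondingly noisy.
- The rating-scale (shared-threshold) formulation is used throughout; a
  partial-credit variant (per-station thresholds) is not implemented.
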