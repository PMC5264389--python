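# Methods

## The measurement and its screening

A trial records one subject's perceived intensity of one odorant on a
0–100 scale at 4 Hz for 120 s (481 samples), with subjects instructed to
start at level 6 of 10, i.e. intensity 60. Habituation appears as the
decay of this trace.

Three artifacts contaminate such recordings, and each gets its own rule:

- **Absence.** Subjects who missed sessions have incomplete odorant
  panels; all of their curves are dropped. When a session map
  (odorant → session) is supplied, a subject counts as absent only if
  some session has *zero* curves left — this keeps the rule idempotent
  after individual curves have been removed for other reasons. Without a
  session map the rule falls back to "any incomplete panel".
- **Chaotic rating.** Some subjects track their breathing rather than
  their percept, producing high-frequency alternation. The detector
  smooths each curve with a 1-s moving average, then counts *direction
  reversals* with a zigzag filter: a reversal is a direction change whose
  swing exceeds an amplitude deadband (default 2 intensity units), which
  makes the count immune to ordinary rating noise. A curve is chaotic
  above 0.5 reversals/s; a subject is excluded wholesale when more than
  half of their curves are chaotic. (The study removed chaotic *subjects*
  but delayed *curves*; that asymmetry is preserved.)
- **Response delay.** The response onset is the first deviation from the
  start level exceeding 2 intensity units (2 % of scale) sustained for 2
  consecutive samples — the sustain requirement rejects one-sample
  jitter. Curves with onset later than 17 s (14 % of the record) are
  dropped individually.

Retained curves are normalized on the intensity axis by their first
sample, anchoring every curve at 1.0 before habituation; all curves start
at the same instructed level, so this anchors the onset rather than the
range (max- or z-normalization would distort flat, non-habituating
curves).

## Clustering and the habituation space

Normalized curves are clustered with squared-Euclidean k-means (Lloyd
iterations, k-means++ seeding, 50 restarts, best objective kept; empty
clusters are re-seeded at the worst-fit point; fixed seed, default 1).
The solver is hand-written so that the library carries no hidden
dependence on another implementation's tie-breaking; scikit-learn's
KMeans is used as an independent cross-check in the tests only. The
number of clusters is guided by the mean silhouette (Euclidean distance)
over a user-chosen k range; on curve families of genuinely different
decay rates the profile peaks at the family count, and k = 3 is the
working default.

With k = 3 the centroids are labelled by the mean of their final 30 s:
highest terminal intensity → *low habituation*, lowest → *high
habituation*. Ties fall back to total area under the curve; an exact tie
is refused rather than broken arbitrarily. Because cluster boundaries are
soft for real data, curves are *not* assigned to clusters downstream;
each curve is summarised by its city-block distance
d = Σₜ |I(t) − C(t)| to each labelled centroid, preserving all the
variability. The per-odorant medians of (d_low, d_mid, d_high) place each
odorant in a 3-D habituation space; a large coordinate means low
similarity to that habituation profile. Distances are computed on
normalized curves (the same representation that was clustered).

## Odorant comparisons

Each coordinate is modelled as distance ~ odorant (fixed) + subject
(random intercept) + error, fitted with statsmodels' MixedLM. Variance
components default to REML: with the between-subject variance estimated
at zero, the Wald F then coincides with the one-way fixed-effects ANOVA F,
and the type-I error of the omnibus test is calibrated in small samples
(an ML fit, the convention of the original analysis environment, is
available via `reml=False`; at study scale the two are practically
indistinguishable). The omnibus Wald F for the odorant factor uses
residual-based denominator degrees of freedom
n − n_odorants − n_subjects + 1. All C(n_odorants, 2) pairwise contrasts
are tested with t statistics on the same df and Benjamini–Hochberg
adjusted; significance is adjusted p < 0.05. The optimizer falls back
through bfgs → lbfgs → powell → nm because the boundary (zero subject
variance) can make a single method's step singular.

## Design matrices

X has one row per odorant and 15 source variables: 8 numeric molecular
descriptors (accessible surface area, carbon-chain length, logP, double
bonds, conformers, molecular weight, vapour pressure, odor activity
value), the 4 sensory scales (intensity, pleasantness, familiarity,
trigeminality; 9-level ratings averaged over subjects per odorant), and 3
categoricals (chemical family, 7 levels; olfactory family, 10; session of
presentation, 4). Categoricals are expanded to a disjunctive table with
one indicator per level, each indicator divided by the variable's level
count so a many-level family cannot outweigh a numeric column — on this
schema 12 + 7 + 10 + 4 = 33 columns. Both X and Y are autoscaled
(mean-centred, unit sd, n−1 denominator; the denominator is exposed for
bit-compatibility experiments). Level rescaling happens before
autoscaling, as part of matrix construction. A zero-variance column is an
error at this stage, naming the column.

## PLS, component choice, VIP

The regression is a from-scratch PLS2. For each component the predictor
weight vector w is the dominant left singular vector of the deflated
cross-product S = X′Y (computed by direct SVD of the p×m matrix — the
algebraic fixed point that NIPALS iterates to, and equivalent to the
kernel formulation's eigenproblem), followed by t = Xw, p = X′t/t′t,
q = Y′t/t′t and deflation X ← X − tp′. Components stop early if S or t
vanishes (rank exhausted). Scores are orthogonal, weights unit-norm, and
the decomposition matches scikit-learn's NIPALS up to component signs at
1e−8 (the reference must be run at a tiny tolerance, since its stopping
rule is on the squared weight change). Coefficients at any truncation a
are B_a = W(P′W)⁻¹Q′ restricted to the first a components. Each
component's sign is flipped so its largest-|w| predictor is positive —
purely presentational, and all reported quantities are invariant to it.

The number of components is chosen by leave-one-out RMSEP: for each
held-out sample the model is refit, *with centring and scaling
re-estimated inside the fold* so no information leaks; rmsep[a, r] is the
root mean squared prediction error of response r at a components, on the
original Y scale. Per response the argmin is taken (ties → fewest
components); the global A is the maximum over responses. Indicator
columns that become constant inside a fold (single-member category
levels) are centred but not scaled — they carry no information in that
fold and must not crash it.

Explained X variance per component is 100·(t′t)(p′p)/‖X‖²; explained Y
variance is the incremental R² of the a-component model over the
(a−1)-component model (a redundancy index would be an alternative
reading; incremental R² is used throughout). VIP pools the explained Y
variance over the three responses, SSₐ = (t′ₐtₐ)(q′ₐqₐ):
VIPⱼ = √(p Σₐ SSₐ wⱼₐ² / Σₐ SSₐ), so Σⱼ VIPⱼ² = p identically.

Interpretation thresholds follow chemometric convention: responses with
|loading| > 0.2, predictors with |loading.weight| > 0.3, and VIP > 1
flagged as important. The direction table is phrased against the
*similarity orientation* of the responses: a response is a distance, so a
predictor whose weight carries the sign opposite to the lowhab loading on
its key component pushes odorants *toward* the low-habituation profile —
"less habituation when it increases". The key component is the one
contributing most to the predictor's VIP. These statements are invariant
to component sign flips by construction.

## The synthetic cohorts

The generator exists because the original ratings are unavailable; its
defaults are the study's design. A clean trial is

  I(t) = L·[p + (1 − p)·e^(−λ(o)t)] + b_s·(1 − e^(−λ(o)t)) + ε(t)

with L = 60 (start level), plateau fraction p = 0.3, rating noise
ε ~ N(0, 1.5²) intensity units, and a subject plateau shift
b_s ~ N(0, 5²) that ramps in with the decay (so every curve still starts
exactly at L) and induces the subject random effect the mixed models
estimate. The odorant decay rate is log-linear in autoscaled descriptors,
λ(o) = 0.02·exp(Σⱼ βⱼ zⱼ(o)) 1/s, with vapour pressure (+0.35),
molecular weight (−0.25) and double bonds (−0.20) as default drivers —
a volatility-driven truth in the spirit of the structure–odor literature,
spanning roughly λ ∈ [0.006, 0.2] so that every odorant responds well
before the 17-s delay criterion. A single exponential to a plateau is the
minimal family spanning low/mid/high habituation shapes; no functional
form is claimed for real percepts.

Contamination reproduces the exclusion taxonomy with known truth: absent
subjects attend 1–3 of the 4 sessions; chaotic subjects emit a ±8
square wave flipping once per second around a mild decay (amplitude and
flip rate are co-calibrated with the zigzag detector: the alternation
survives the 1-s smoothing, ordinary noise does not); delayed curves hold
*exactly* the start level for a delay drawn uniformly from 18–110 s —
during a delay the subject is not touching the device, so the trace
carries no noise — then jump to the currently perceived intensity, which
makes the drawn delay recoverable to within one sample. The default
cohort is 58 recruited / 3 absent / 5 chaotic subjects and 69 delayed
curves spread over ~13 subjects (1–9 each), which reproduces the study's
bookkeeping: 1760 fully-attended curves, 229 excluded, 1531 retained.
(The published participant counts disagree internally — 51 participants
vs 33 + 25 recruited vs 58 in the abstract; 58 recruited with 55
attending is the reading consistent with 1760 − 229 = 1531 and is used
here, flagged as an inference.) Published OAV values are confidential, so
a synthetic OAV (log-linear in vapour pressure with lognormal scatter) and
a synthetic session blocking (blocks of 8 in table order) stand in; both
are labelled synthetic at their definition sites.

Sensory ratings are drawn from discretized linear models on autoscaled
descriptors with subject offsets, rounded to the 9-level scales;
trigeminality tracks intensity closely and pleasantness opposes it,
reproducing the collinearity expected among these attributes — which is
precisely the regime PLS is chosen for.

What the generator does **not** emulate: sniff dynamics and breathing
artifacts in non-chaotic subjects, dishabituation between trials,
non-exponential (e.g. biphasic) percept decay, drifting baselines, and
real descriptor–percept relationships. Passing tests therefore certify
the pipeline's logic, numerics and calibration — not any claim about how
real odorants habituate.

## Test problem sizes

The suite favours small, fully checkable problems: PLS correctness on 50
random problems (n 12–28, p 4–12, m 1–3) against scikit-learn plus a
brute-force leave-one-out oracle at n = 9; driver recovery on 100 seeded
cohorts of 16 subjects × 32 odorants with an orthogonalized descriptor
panel (3 drivers at |β| = 0.4, 10 nuisance columns) — orthogonal columns
remove chance in-sample confounding between drivers and nuisance, so the
property isolates pipeline recovery rather than random-design
identifiability; mixed-model calibration on 200 null datasets of 6
odorants × 12 subjects; clustering sanity on 100 cohorts of three decay
families (λ = 0.004 / 0.03 / 0.25, 15 curves each). The exclusion
bookkeeping runs on the full default cohort (~1800 curves).

## Known limitations

- The omnibus F uses a fixed residual-df formula; Satterthwaite or
  Kenward–Roger df would be preferable for severely unbalanced data.
- VIP pools explained variance over the three responses (the adapted
  convention for multi-response fits); a per-response reading requires
  fitting against a single response.
- The chaos detector's threshold is calibrated against the generator's
  alternation model; real breathing artifacts may need a different
  amplitude deadband.
- The habituation-space coordinates are strongly negatively/positively
  coupled by construction (distances to three fixed curves), so the three
  mixed models are not independent tests.
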