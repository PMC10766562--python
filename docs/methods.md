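# Methods

## Model

A cohort is a set of subjects, each with visits (t, y): t ≥ 0 in years
from symptom onset, y on a bounded instrument (ALSFRS-R 0–48 by
default). Before fitting, every trajectory receives an onset anchor
(0, y_max) — an imputed maximum-score observation at symptom onset.
The anchor encodes the clinical fact that function was intact at onset
and identifies the early part of the curve even when the first clinic
visit comes late.

Each mixture component is a GP over time with

* mean m(t) = b + s·t with intercept b fixed at y_max (the anchor pins
  the curve there) and slope s constrained ≤ 0 — the first half of the
  monotonic inductive bias;
* squared-exponential kernel σ_f²·exp(−Δt²/(2ℓ²)) (smooth trajectories
  without discontinuities), or, for the linear-kernel benchmark, the
  homogeneous linear kernel σ_f²·t·t′, which passes through the onset
  origin consistent with anchoring;
* iid Gaussian observation noise σ_n².

The partition of subjects follows a Dirichlet process with
concentration α (default 1.0). The collapsed Gibbs conditional for a
subject is CRP-weighted: an existing cluster k gets weight
n_k · p(y_subject | cluster k's pooled data, hyperparameters); a new
cluster gets α · p(y_subject | prior). The second half of the
monotonic bias is the admissibility rule: a cluster is struck from the
conditional (weight exactly 0) when the subject's first measured score
exceeds the cluster's posterior mean at that time by more than a
margin. The margin defaults to 5 points on the 48-point scale, scaled
proportionally for other instruments; the rule prevents a near-ceiling
subject from joining a cluster that has already declined past them,
while the new-cluster option is always admissible so the conditional
is always proper.

### Inference

Fitting alternates (a) one Gibbs sweep over subjects in seeded random
order, resampling each assignment from the collapsed conditional with
empty clusters removed immediately, and (b) per-cluster type-II
maximum-likelihood (MAP, see priors) re-optimization of
(σ_f², ℓ, σ_n², s) by L-BFGS-B on the log scale with analytic
gradients, warm-started from the current values and never accepted if
the objective would decrease. The log joint — CRP partition term plus
per-cluster GP marginal likelihoods plus hyperparameter log-priors —
is recorded after each phase; the returned model is the
maximum-log-joint state over the whole trace, which is robust to
late-chain wander. Default budget: 50 sweeps, early stop after 5
consecutive sweeps without an assignment move. Everything is
deterministic given the seed.

Numerical choices: a jitter of 1e−6·σ_f² is added to training Gram
diagonals (well below score resolution); ℓ is bounded to [0.05, 20] yr
and variances to [1e−4, y_max²]; the slope to [−2·y_max, 0] per year.
Cluster posteriors cache a Cholesky factor of the pooled-data Gram
matrix; predictive likelihoods for assignment use the conditional
Gaussian identity p(y_new | y_cluster) rather than two marginal
likelihoods, which is algebraically identical and cheaper.

### Hyperparameter priors

Weakly informative log-normal priors act on ℓ (median 1 yr), σ_f²
(median (span/4)²) and σ_n² (median (span/16)²), all with sd 1.0 on
the log scale — spanning the plausible clinical regimes of decline
timescale, trajectory amplitude and scoring error. They are on by
default (`MoGPConfig(use_priors=False)` disables them): without them a
singleton cluster can drive its noise variance to the floor and
survive on an inflated marginal likelihood. The specific numeric
medians are this package's own defaults.

The new-cluster option in the conditional is scored with the prior
hyperparameters at their central values (signal sd span/4, ℓ = 1 yr,
noise sd span/16, slope −0.175·span/yr, intercept y_max) rather than
by per-proposal optimization, which would cost an optimizer run per
subject per sweep for negligible benefit.

### Prediction for unseen subjects

Membership of a held-out subject is scored over existing admissible
clusters by log n_k plus the predictive log-likelihood of the
subject's visits under the cluster posterior — the DP posterior
predictive — and never creates a new cluster. The reported confidence
is the softmax-normalized probability of the chosen cluster. If no
cluster is admissible, the cluster whose mean at the subject's first
visit is closest is returned with a low-confidence flag.

## Quality control and data conventions

Subjects are excluded, in order, if they have fewer than 3 complete
visits (operationalized as a non-missing total score; item-level data
are not modelled), a first visit more than 7 years after symptom
onset, or a rise of more than 6 points between consecutive visits
(declines of any size pass — only implausible improvements indicate
data-entry errors). Duplicate timestamps are averaged with a warning;
a measured visit at exactly t = 0 blocks anchoring and must be shifted
or dropped by the caller. Times are years from onset throughout;
readers convert months/days via the column map. Scores are modelled on
their native scale, never normalized, so errors are in instrument
points.

## Benchmarks

* **SM** — per-patient least squares through the anchor:
  s = Σtᵢ(yᵢ − y_max)/Σtᵢ², fit on measured visits.
* **SG** — per-patient two-parameter logistic
  y_max/(1 + exp((t − d50)/dx)), least squares over a coarse grid
  (d50 ∈ {0.5, 1, 2, 4, 8} yr × dx ∈ {0.1, 0.5, 1, 2} yr) then local
  refinement; fit on measured visits, the anchor being implicit in the
  functional form (y(0) ≈ y_max whenever d50 ≫ dx). The fitted curve
  is monotone decreasing for all admissible parameters.
* **LKM** — the identical mixture engine with the kernel swapped for
  the homogeneous linear kernel, so MoGP–LKM differences isolate the
  nonlinearity allowance from the clustering machinery.

## Evaluation experiments

Per-patient error is the RMSE between measured (never anchor) visits
and the model's predicted trajectory — the assigned/predicted cluster
mean for mixtures, the fitted curve for SM/SG. The interpolation
harness retains a fraction (25/50/75%) of each subject's visits as
training data — the fraction names the *provided* share, rounded
half-up with a floor of two visits, no special protection for the
baseline visit — and scores the withheld complement; subjects need
≥ 10 visits. The censoring harness trains on visits within a horizon
(0.25–2 yr) after each subject's first measured visit (baseline, not
onset) and scores visits beyond it; subjects need ≥ 4 visits and at
least one post-horizon visit. The transfer harness uses 60/40
train–test splits repeated 5 times: a reference model fit on the
reference cohort's training split is compared, on each target cohort's
test split, against a study-specific model and against a control in
which the reference model's predicted labels are permuted across test
subjects; mean errors carry normal-approximation 0.95 CIs across
subjects and a paired one-sided Wilcoxon over split means. Distribution
comparisons use the two-sample two-sided Kolmogorov–Smirnov test and
the one-sided Wilcoxon signed-rank test (direction: the first model
improves); identical paired samples are reported as p = 1 because all
differences vanish and there is no evidence of improvement.
Meta-clustering of components runs k-means (k = 4 by default) on
standardized (first-year slope, log ℓ), with group labels ordered by
slope magnitude. Cluster enrichment of a binary attribute uses the
hypergeometric upper tail.

## Survival

Survival time runs from symptom onset; subjects without a recorded
death are censored at their last recorded visit. Kaplan–Meier fitting
and logrank tests are delegated to lifelines, with the product-limit
curve recomputed as a cumulative product over the integer risk table
so hand-checkable instances come out exact. All unordered cluster
pairs are tested; Benjamini–Hochberg adjustment is applied across
pairs, and pairs with fewer than two events in total are reported as
non-evaluable (excluded from the differential-pair fraction's
denominator) rather than given p = 1.

## Synthetic cohorts

The generator is the ground-truth source for every experiment. Each
cluster has a template: linear y_max + s·t; sigmoid
y_max/(1 + exp((t − d50)/dx)); convex/concave power law
y_max·(1 − (t/T)^γ) with γ > 1 / γ < 1; stable (shallow linear). All
templates start at (or asymptotically near) y_max and are monotone
non-increasing; scores are clipped to the instrument bounds after
noise. Visit schedules mimic irregular clinics: an onset-to-baseline
delay, then exponential inter-visit gaps at a configurable rate
(default 3/yr), uniform follow-up (default 1.8–2.2 yr), per-visit
dropout (default 2%), rejection-resampled to a 4-visit minimum.
Observation noise is iid Gaussian (default sd 1.5 points) truncated at
2.5 sd — rater error on a bounded instrument does not mis-total by
6+ points; truncation shrinks the marginal sd by ~3.5% — so the
default cohort passes the QC filters at ≥ 99%. Survival is linked to
progression by log T = a − b·(first-year template decline) + sd·ε
(defaults a = 1.6, b = 0.08, sd = 0.3, administrative horizon 6 yr,
censoring at the last visit), which makes faster-declining clusters
die earlier on average. Visit schedules are independent of survival —
a deliberate simplification; real cohorts lose fast progressors from
follow-up (informative attrition), so passing tests here say nothing
about robustness to that.

The default four-cluster study cohort (30 subjects each; fast linear
s = −16, slow linear s = −4, sigmoidal cliff d50 = 1, dx = 0.2 yr,
concave T = 5, γ = 0.45; noise sd 1.5; ~6 visits over 2 yr) spans the
qualitative shape families seen in observational ALS populations. The
forecasting cohorts stagger onset-to-baseline delays over 0.2–1.5 yr
with longer follow-up (2.5–3.5 yr, 4 visits/yr), so that a fixed
horizon after baseline still leaves the decline phase visible through
late-presenting subjects — the mechanism by which pooled cluster means
can forecast a cliff an individual's censored record has not shown.

What the generator does not emulate: treatment effects and
interventions (NIV/PEG), item-level scores, informative attrition,
rater drift, and calendar-date bookkeeping. Synthetic recovery results
therefore validate the machinery (identifiability at realistic noise
and sparsity), not clinical generalizability.

## Known limitations

Hyperparameters are point estimates (type-II ML/MAP), not integrated
over; inference is a maximum-a-posteriori search along a Gibbs chain
rather than a full posterior; α is fixed rather than resampled; the
admissibility margin is a fixed rule rather than a learned quantity;
no sparse-GP approximations are used, so cohorts beyond a few thousand
pooled visits per cluster would need larger compute budgets.
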