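# trajgp

Clustering of sparse, irregularly sampled, monotonically declining
clinical trajectories with a Dirichlet-process mixture of Gaussian
processes (MoGP), for researchers modelling progression of ALS and
related neurodegenerative diseases from longitudinal functional scores
(ALSFRS-R totals 0–48, its domain subscores 0–12, percent-predicted
forced vital capacity 0–100, and similar bounded instruments).

## The model

Each subject contributes visits (tᵢ, yᵢ) with t in years from symptom
onset, plus an imputed **onset anchor** (0, y_max) pinning every
trajectory at the healthy end of the scale. A mixture component k is a
Gaussian process

&nbsp;&nbsp;&nbsp;&nbsp;f ~ GP(m(t), k(t, t')),&nbsp;&nbsp;
m(t) = y_max + s·t (s ≤ 0),&nbsp;&nbsp;
k(t, t') = σ_f² exp(−(t − t')²/(2ℓ²)),

with observation noise σ_n². The mean-function slope s captures the
component's overall decline rate; the length-scale ℓ its stability
(short ℓ = abrupt, e.g. a "functional cliff"; long ℓ = steady). A
Dirichlet process prior with concentration α lets the number of
components be learned from the data. Inference is collapsed Gibbs
sampling over cluster assignments (existing cluster ∝ n_k · predictive
likelihood, new cluster ∝ α · prior predictive) interleaved with
type-II maximum-likelihood updates of each component's
hyperparameters, keeping the maximum-log-joint state. A **monotonic
admissibility constraint** forbids assigning a subject whose first
measured score sits more than a margin (default 5 ALSFRS-R points)
above the cluster mean at that time.

Alongside the main model the package implements the standard
comparison models — the patient-specific anchored slope (SM, closed
form s = Σtᵢ(yᵢ − y_max)/Σtᵢ²), a patient-specific two-parameter
sigmoid y(t) = y_max/(1 + exp((t − d50)/dx)) (SG), and the same
mixture with a linear kernel (LKM) — plus evaluation harnesses
(interpolation of withheld visits, forecasting beyond right-censoring
horizons, reference-vs-study-specific transfer with a shuffled-label
control), per-cluster Kaplan–Meier survival curves with pairwise
logrank tests under Benjamini–Hochberg FDR correction, hypergeometric
cluster enrichment, and a synthetic-cohort generator with linear,
sigmoidal, convex, concave and stable decline shapes and linked
survival times.

## Worked example

```python
from trajgp import MixtureOfGPs, add_onset_anchor, apply_qc_filters
from trajgp.simulate import default_cohort_spec, generate_cohort

trajs, truth = generate_cohort(default_cohort_spec(seed=1))
kept, report = apply_qc_filters(trajs)
print(f"retained {report.n_retained}/{report.n_input} subjects after QC")
anchored = [add_onset_anchor(tr) for tr in kept]
results = MixtureOfGPs(anchored).fit(seed=1)
print(results.summary())
```

prints

```
retained 119/120 subjects after QC
Mixture of Gaussian processes (se kernel)
subjects: 119   clusters: 4   alpha: 1   seed: 1   log joint: -1876.71
 cluster  n  first_year_slope  length_scale  mean_slope  noise_sd
       0 30            24.108         0.516     -19.088     1.112
       1 30             3.942         3.102      -3.915     1.364
       2 30            23.349         0.393     -15.103     1.372
       3 29            15.894         1.700     -15.109     1.422
```

The generator drew four 30-subject groups (fast linear, slow linear,
sigmoidal cliff, concave); QC removed one subject for a >6-point score
rise. The fit recovers four clusters matching the generative groups.
`first_year_slope` is the decline implied by the cluster mean over the
first year, (48 − mean(1 yr))/1 yr, in points/year; the sigmoidal-cliff
cluster pairs a steep first-year slope (24.1) with a short length-scale
(0.52 yr), while the slow linear cluster shows a shallow slope (3.9)
and a long length-scale (3.1 yr). Membership of new subjects:

```python
pred = results.predict(anchored[0])   # cluster 3, confidence 1.000
```

The same workflows are available from the shell:

```bash
trajgp simulate --seed 1 --out sim/
trajgp fit --input sim/cohort.csv --seed 1 --out fit/
trajgp evaluate --experiment censor --input sim/cohort.csv --out eval/
```

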