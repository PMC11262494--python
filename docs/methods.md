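# Methods

## The model

The analysis compares two randomized arms across a value tree of
time-to-first-event endpoints. Benefits are ischemic endpoints (acute limb
ischemia, major amputation of vascular cause, myocardial infarction,
ischemic stroke, cardiovascular death); risks are TIMI major bleeding
endpoints. To avoid double-counting deaths, every endpoint except the
fatal one is defined as nonfatal, and a fatal occurrence is attributed
only to the model's fatal endpoint: model 1 uses the composite of
cardiovascular death and fatal TIMI major bleeding, model 2 uses all-cause
death. Death ends observation for all endpoints; nonfatal events do not
censor other endpoints, so endpoints are analysed marginally and a patient
can contribute a first event to several of them.

**Unweighted layer.** For endpoint *i* and arm *a*, the incidence rate is
r_ia = 10 000·d_ia/PY_ia with d the first-event count and PY the
patient-years at risk (each patient contributes min(first event, censoring)
converted at 365.25 days/year). The contrast is Δr_i = r_i,active −
r_i,control with a Wald 95% CI using the Poisson variance d/PY² per arm:
se_i = 10 000·√(d_a/PY_a² + d_c/PY_c²). The published analysis cites a
Wald method without reproducing the formula; the normal approximation with
Poisson variance is the implementation here, and a parametric-bootstrap
test (Poisson resampling of counts, 10⁵ replicates) bounds its error at
moderate counts to under 2% of the interval width. NNT/NNH is
10 000/|Δr_i| patient-years per event prevented or caused (infinite, not
an error, at Δr = 0).

**Weighted layer (MCDA).** Each endpoint's weight is w_i = 1 − u_i, the
complement of its mean health state utility value; the fatal endpoint has
u = 0, w = 1 exactly. The score difference is the linear additive value
ΔS = Σ_i w_i·Δr_i, with no range normalization and no value-function
curvature — a deliberate simplification of canonical MCDA that makes ΔS
interpretable as utility death equivalents per 10 000 patient-years and
makes every downstream property (contribution additivity, tornado bar
widths) exactly linear. Weights are carried at full precision; one-decimal
display is formatting only.

**Monte Carlo.** Each run redraws all rate differences and weights
independently and recomputes ΔS. Two rate-sampling paths exist because the
data arrive in two forms:

* *gamma-by-counts* (patient-level path): each arm's rate is drawn from
  Gamma(shape = d, rate = PY), which matches the Poisson estimator's
  mean and variance; a zero-count arm uses shape 0.5 (a Jeffreys-style
  fallback) so the draw is not a point mass at zero.
* *normal-by-ci* (aggregate path): the rate difference is Gaussian with
  mean at the printed point estimate and SD = CI width/3.92.

Weight draws follow the configured family: beta matched to the weight
mean/SD by moments (requires sd² < m(1−m)), normal truncated to [0, 1]
(raw location/scale, so the realised mean shifts slightly at heavy
truncation), or fixed. The summary reports the mean ΔS, the percentile
(2.5th/97.5th) CI — chosen over normal-theory intervals to match the
distributional presentation of the results — and P(ΔS < 0), the
probability that benefits outweigh risks. The empirical CDF is
left-continuous (P(X < x)) so that CDF(0) *is* that probability, including
in degenerate all-fixed runs. Independence across endpoints and between
arms is assumed throughout (a stated limitation of the underlying
analysis); a correlation structure is a documented extension point, not
implemented. Whether the original analysis sampled per-arm rates or rate
differences directly is not recorded in the available text; both paths are
implemented and labelled, and no claim is made about which produced the
published figures.

**Sensitivity.** The tornado analysis moves one nonfatal endpoint's weight
at a time to mean ± 2 SD, clamped to [0, 1] (the source is silent on
weights leaving the unit interval; clamping only ever shrinks a bar), with
all other weights at their means. The fatal endpoint is excluded — its
weight is 1 by definition. By linearity the pre-clamping bar width is
exactly 4·SD_j·|Δr_j|.

**Temporal B–R.** "KM rates" are interpreted as Kaplan–Meier cumulative
incidences at each grid time, so ΔS(t) = Σ_i w_i·(F_a,i(t) − F_c,i(t))·10⁴
is per 10 000 *patients* by time t — a per-population scale, deliberately
distinct from the per-10 000-patient-year scale of the main score. The
default grid is day 90 to day 1100 in 91-day steps, configurable. The CI
method is not specified in the source; the default here is Monte Carlo over
Gaussian perturbations of each cumulative incidence with its Greenwood
variance, clipped to [0, 1], combined with the weight distributions, with
delta-method normal bands as a labelled alternative. The KM estimator
itself is implemented directly (product-limit with Greenwood variance,
simultaneous-death tie convention) and is cross-checked against lifelines
to 1e-10 in the test suite; between-arm difference curves are truncated
where either arm falls below a 10% at-risk fraction (Pocock's restriction,
floor configurable).

## Data scopes

ITT keeps all randomized patients and censors at the administrative
cutoff. On-treatment keeps dosed patients and censors at
min(cutoff, last dose + 2 days); an event exactly at the boundary is
included (the source says "plus 2 days" without specifying openness; the
closed convention is used). The on-treatment event set is a subset of the
ITT set by construction, and the suite asserts it.

## The synthetic trial generator

The generator emulates exactly the structure the analysis assumes:
exponential per-endpoint event times drawn independently within a patient,
uniform 1-year enrollment with a common calendar cutoff 31/12 + 0.5 years
after study start (giving follow-up uniform over 25–37 months, median 31),
exponential permanent discontinuation at 0.14/year, and death truncating
all observation. Default hazards equal the published ITT rates converted
to events per patient-year for the seven model-1 endpoints; per-endpoint
fatal fractions are free parameters defaulting to 0 for nonfatal endpoints
(the published rates are already net of fatal attribution) and 1 for the
death streams; the non-cardiovascular death hazard (needed only so model
2's all-cause endpoint is complete) defaults to 60 per 10 000 PY in both
arms, making all-cause mortality ≈1.25× cardiovascular mortality.
RNG substreams are spawned per patient, so enlarging a trial leaves
earlier patients' data bit-identical.

What the generator does *not* emulate: covariates (age, clopidogrel use)
and hence real subgroup structure, non-proportional or time-varying
hazards, recurrent events, correlation between endpoint processes beyond
death truncation, and any treatment-effect change after discontinuation.
Passing tests on synthetic data therefore demonstrate the correctness of
the estimators and plumbing under the analysis's own assumptions — not
robustness to the violations of those assumptions that real trial data
may exhibit.

## Weight uncertainty defaults

The published table reports mean weights only; the weight SDs and
distribution families used in the original Monte Carlo live in
supplementary material that is not available here. The package default is
a beta distribution with utility SD 0.10 for nonfatal endpoints (HSUV
dispersions in cost-effectiveness registries typically fall in 0.05–0.15)
and a fixed weight of 1 for the fatal endpoint. Consequently the
net-benefit probability computed at the desk (≈66% for the ITT model-1
inputs at 10⁶ runs) sits slightly above the published 64.4%: fixing or
under-dispersing weights narrows the ΔS distribution, and with a negative
mean that raises P(ΔS < 0). The suite checks both the closed-form
agreement (fixed weights vs Φ(−μ/σ)) and the direction of this bias.

## Numerical choices and problem sizes

* Days→years conversion at 365.25; rates scaled ×10 000.
* Percentile CIs need ≥40 runs (else an explicit error); the density
  tabulation needs ≥1000 draws.
* Desk default 10⁶ Monte Carlo runs (binomial SE of P < 0.0005); 5×10⁶
  mirrors the original run count and is a flag away.
* Test-suite problem sizes were chosen for statistical resolution at
  interactive cost: rate-recovery at 10 000 patients/arm, CI coverage over
  500 Poisson trials at expected counts 60 vs 40, KM cross-checks at
  100–500 patients.
* The on-treatment headline results (−68.1 per 10 000 PY, P = 98.7%) are
  not reproducible from the available inputs — their per-endpoint
  on-treatment rates were not published — and are therefore covered by
  structural invariants (scope subset, exposure ordering) on synthetic
  data rather than numeric reconstruction.

## Known limitations

Linear value functions without range constraints; endpoint independence;
HSUVs applied as instantaneous weights rather than integrated over time in
the health state (no QALY-style time integration); no Cox/hazard-ratio
estimation (rate differences are the contrast of interest); aggregate
inputs cannot feed the temporal analysis (no patient-level KM information
exists in a printed table, and the pipeline refuses the combination
explicitly).
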