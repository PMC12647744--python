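# Methods

`rmctrial` implements the quantitative machinery of a single-arm phase II
trial of nivolumab plus ipilimumab in renal medullary carcinoma (RMC),
together with the transcriptomic similarity analysis used to quantify
"myeloid mimicry" of tumor cells and the quantification formulas of the
accompanying preclinical experiments. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Bayesian sequential monitoring

The design treats each patient's 12-week objective response and each
extreme-toxicity event (TOX, any event requiring removal from the trial)
as Bernoulli outcomes with rates θ_R and θ_T. Both rates carry Beta
priors, so all posteriors are conjugate: Beta(a, b) plus r successes and
q failures gives Beta(a + r, b + q).

Stopping rules (both cutoffs strict, mirroring the protocol's ">"
statements):

* **Toxicity** — stop if Pr(θ_T > 0.30 | data) > 0.95, prior
  Beta(0.6, 1.4). 0.30 is the TOX rate assumed for standard therapy.
* **Futility** — stop if Pr(θ_R < 0.30 | data) > 0.90, prior
  Beta(0.5, 0.5). 0.30 sits slightly above the response rate expected on
  alternative treatments.

The design uses a *community of priors*: the futility monitor carries an
enthusiastic (Jeffreys-like) prior so that a futility stop convinces an
optimist, while the final analysis carries the skeptical Beta(0.6, 1.4)
so a positive result convinces a skeptic.

Accrual proceeds in cohorts of 10 up to a maximum of 30 evaluable
patients. Toxicity is evaluated after every treated patient (a TOX may
occur at any time); futility only at cohort boundaries, when 12-week
response is assessed. Both schedules are configurable. Patients leaving
after treatment but before the 12-week evaluation count as
non-responders; never-treated patients are excluded (the protocol
replaced them). Unconfirmed responses count as non-responses for
monitoring.

Boundary tables are derived by exhaustive enumeration: for each n the
rule is evaluated at every possible event count 0..n, and the critical
count is the smallest triggering TOX count (stop if observed ≥ bound) or
the largest triggering response count (stop if observed ≤ bound). The
derived futility bounds are r ≤ 1 at n = 10, r ≤ 3 at 20 and r ≤ 5 at 30,
and they are identical under the enthusiastic and the skeptical prior —
the design's prior-sensitivity claim, which the test suite re-derives.

The final test declares success when Pr(θ_R > θ_H | data) > 0.80, where
θ_H ~ Beta(13, 32) is the posterior of the historical comparator
(13/45 = 29% on conventional chemotherapy) and θ_R carries the skeptical
prior. Pr(θ_A > θ_B) for independent Beta variables is computed by
adaptive quadrature of ∫ f_A(x) F_B(x) dx to absolute tolerance 1e-10
(`scipy.integrate.quad`); Monte Carlo sampling is kept only as a test
oracle. With 12/30 responses the probability is 0.833, just clearing the
bar, matching the design requirement of "12 or more responses"; 11/30
gives 0.755 and fails.

### Operating characteristics

`ocsim` simulates per-patient response and TOX as independent Bernoulli
draws (the protocol specifies no joint model), runs each stream through
the monitor, and reports stop frequencies, final-test success frequency
and expected sample size with one seeded generator per run. For
single-look designs the stop probability is a finite binomial sum, which
the tests use as an exact oracle. No operating-characteristic figures are
asserted against external values; validation is property-based
(exact-enumeration agreement, monotonicity in the true rates).

## RECIST 1.1 and hyperprogression

Tumor burden is the sum of longest diameters (SLD) of the baseline
target lesions. Timepoint categories follow RECIST 1.1, which the
protocol invokes without restating: PD at ≥ 20% increase from nadir with
≥ 5 mm absolute increase or any new lesion; PR at ≥ 30% decrease from
baseline; CR when all target lesions disappear; otherwise SD; NE when a
baseline target lesion is unmeasured at follow-up. Non-target lesions
enter only through the new-lesion flag (a simplification of "unequivocal
progression"). Best overall response takes the best category before the
first PD; confirmation requires a repeat qualifying assessment ≥ 4 weeks
later (the conventional window — the source only distinguishes confirmed
from unconfirmed), and an unconfirmed PR does not count toward the
objective response rate. ORR is the confirmed CR+PR fraction and DCR the
CR+PR+SD fraction.

Hyperprogression is PD within the first 8 weeks after treatment start
(closed window, weeks as the time coordinate) with an absolute SLD
increase ≥ 10 mm versus baseline, plus (i) ≥ 40% SLD increase versus
baseline and/or (ii) ≥ 20% increase with new lesions in ≥ 2 different
organs. The 10 mm gate is read as applying to the target-lesion SLD, not
per lesion; this is flagged for sensitivity analysis since the source
wording ("the measurable lesions") admits both readings. New-lesion
organs accumulate over the window up to the qualifying PD timepoint.
The waterfall value reported per patient is the signed percent SLD
change of greatest absolute magnitude, which captures deep responses and
hyperprogressive growth alike.

## Survival endpoints

PFS and OS are product-limit (Kaplan–Meier) estimates with Greenwood
variance, log-log transformed pointwise 95% bands, and the median CI by
Brookmeyer–Crowley inversion of the band — the conventional defaults of
standard survival software, which the source names only implicitly.
Estimation is delegated to `lifelines`; the Greenwood variance is
assembled from the fitted risk table as
S(t)² Σ d_i / (n_i (n_i − d_i)). Events precede censorings at tied
times. Medians or bounds are reported as not estimable (∞) when the
curve or band never reaches 0.5 — the same "NE" pattern as the trial's
reported OS interval. Patient-level event times are published only
graphically, so the trial's printed medians are validated indirectly:
synthetic exponential cohorts recover ln 2/λ within 2% at n = 10⁴, and
the pointwise band covers the true survival ≈ 95% of the time over 1000
replicates at n = 50.

## Myeloid-mimicry similarity panel

Inputs are library-size-normalized cells × genes matrices with
compartment (tumor/myeloid) and condition (baseline/postNI) labels;
upstream processing (clustering, annotation, malignant-cell calling) is
out of scope and assumed done. On the top 3000 highly variable genes,
six metrics compare each tumor cell with the per-condition myeloid
centroid (per-gene mean): Euclidean and Manhattan distance, Bray–Curtis
dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), Lovell-style phi proportionality
var(log(x+ε) − log(y+ε))/var(log(x+ε)) with pseudocount ε = 1, cosine
and Pearson similarity. The centroid target keeps the computation
deterministic and O(cells); whether the original analysis used
centroids, sampled cells or all pairs is not stated, so the choice is
documented here and an all-pairs comparison can be run by passing
individual myeloid rows as references. Metrics are computed on the
normalized scale (not log) except phi, which is defined on logs.

Conditions are contrasted per metric by log2 of the ratio of medians
(medians are robust to the heavy right tails of distance distributions)
and a two-sided Wilcoxon rank-sum test. Increased post-treatment
mimicry appears as negative dissimilarity LFCs and positive similarity
LFCs.

**HVG selection.** Genes are ranked by the variance of analytic Pearson
residuals: each entry is residualized against the rank-one expectation
from its cell total and gene abundance, scaled by a negative-binomial
variance function (θ = 100) and clipped at ±√n_cells, with ties broken
by gene id. A binned log1p dispersion statistic (Seurat-style) was
evaluated first and rejected: its log transform saturates for abundant
lineage markers, and on synthetic mixtures it recovered barely 70 of 100
designated variable genes where the residual-variance statistic recovers
99–100. Pearson-residual selection is equally standard practice and is
deterministic here.

## Preclinical formulas

Direct implementations with input validation: CTCF = integrated density
− cell area × mean background fluorescence (≥ 5 background readings
enforced; negative values retained and left to the caller to flag);
body-weight change (BWᵢ − BW₀)/BW₀ × 100; TGI% = 100 − 100·ΔV_trx/ΔV_veh
(allowed to exceed 100% for regressions; undefined at zero vehicle
growth); caliper volume L·W²/2; qRT-PCR fold change 2^−ΔΔCt.

## Synthetic data: what it emulates and what it does not

* **Trial outcomes** — i.i.d. Bernoulli response/TOX streams under
  configurable true rates. Emulates the design's probability model
  exactly, by construction; it cannot test departures such as drift in
  patient mix or correlated outcomes.
* **Lesion timelines** — baseline SLD uniform on 40–120 mm split over
  two target lesions, assessments at weeks 0/6/12. Responders shrink to
  −35% then −40% (confirmed PR); hyperprogressors alternate between a
  +50% phenotype (criterion i) and a +25%-plus-new-lesions-in-two-organs
  phenotype (criterion ii); stable patients stay at +10%. The 40 mm
  floor guarantees the 10 mm absolute gate for hyperprogressors, so the
  noiseless generator (default, `noise_sd = 0`) makes the labels an
  exact oracle: classifier sensitivity and specificity of 1.0 on these
  cohorts demonstrates the rule logic, not robustness to measurement
  noise, missed visits or atypical trajectories. New-lesion organs come
  from {lung, liver, bone, node, kidney}, sites the disease actually
  involves.
* **Survival** — exponential event times with independent exponential
  censoring; the closed-form median ln 2/λ is the recovery oracle. Real
  PFS/OS need not be exponential; only the estimator, not the disease,
  is being tested.
* **Expression** — tumor and myeloid archetypes share a log-normal base
  program; 100 designated marker genes (drawn from the expressed upper
  half of baseline abundance — lineage markers are not rare transcripts)
  carry ~9× fold differences (log-normal folds, mean 2.2, sd 0.3 on the
  log scale) split between the two programs. Tumor cells express
  (1−α)·T + α·M with α = 0.1 at baseline and 0.4 post-treatment by
  default; counts are gamma-Poisson with dispersion 0.1 (droplet-typical)
  at library size 2000, then normalized to 10⁴ per cell.
  `dispersion ≤ 0` yields noiseless expected profiles, giving the exact
  limit case α = 1 → distances 0. The generator has no batch effects,
  no ambient RNA, no clonal structure and a single myeloid state, so a
  detected mimicry signal here shows the panel's sensitivity to mean
  mixing shifts — not that the metrics are immune to those confounders.

## Problem sizes in the default suite

Exhaustive boundary enumeration runs to n = 30 (the design maximum).
Monte Carlo checks use 10⁶ draws per Beta pair (50 pairs), 10⁴ trial
replicates for the single-look OC comparison, 10⁴ survival records for
median recovery, 1000 replicates of n = 50 for band coverage, and 100
seeded replicates of the 800-cell × 2000-gene expression generator for
the similarity-panel power check (each replicate runs the full
HVG-selection → panel → contrast pipeline).

## Known limitations

Patient-level trial data are not public, so the realized medians
(PFS 1.38, OS 8.23 months) and the 5/10 hyperprogression count are
reproduced structurally (same machinery, synthetic inputs), not
numerically from raw data. The boundary tables are validated by internal
consistency and by the trial's realized halt, as the protocol's printed
supplementary tables are not reproduced in the source text. The RECIST
implementation omits lymph-node short-axis rules and iRECIST
pseudo-progression handling; hyperprogression uses the burden-based
definition only, not tumor-growth-rate variants.
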