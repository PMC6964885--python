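# Methods

This note documents the models, algorithms and design choices behind
`partworth`, in the spirit of a statistical package's methods appendix.  It
describes what each component assumes, which knobs matter, and what the
synthetic-data results do and do not demonstrate.

## Attribute schema and coding

The default schema describes maintenance-therapy profiles for Crohn's
disease with six attributes: chance of remission for at least one year
(20/50/80 per 100), chance of a side effect requiring discontinuation
(WDAE; 1/15/30 per 100), dosing regimen (six options from daily tablets to
combined tablets + infusions), and three binary drawbacks (initial
prednisone course, possible low blood counts / liver reaction, small risk
of serious infection / certain cancers), each with "No" preferred.

Coding rules determine the 10-column part-worth vector:

- *linear* attributes contribute one column, `x = level − center`.  Centers
  default to the level mid-range (remission 50, WDAE 15.5) so coefficients
  are utilities per percentage point — the unit the marginal rate of
  substitution needs.
- *categorical* attributes with `L` levels contribute `L − 1` effects-coded
  columns; the omitted level is −1 on all of them, so level utilities sum
  to zero within the attribute.
- *binary* attributes contribute one effects column (first level +1, second
  −1).

Linearity of the two outcome attributes is an input assumption of the
model, not something the package re-verifies.

## Choice-design generation

Commercial "balanced overlap" designs balance level frequencies while
deliberately letting some levels repeat across the alternatives of a task,
which reduces the number of trade-offs a respondent must process.  The
exact commercial algorithm is proprietary, so the package commits to a
documented, auditable heuristic with the same goals:

1. per survey version, draw each attribute's column as a maximally even
   multiset of levels, randomly shuffled (level balance deviation ≤ 1 by
   construction);
2. hill-climb with within-attribute cell swaps — which preserve level
   counts exactly — against a penalty `10 · (duplicate alternatives) +
   |overlap − target|`, where overlap is the fraction of task × attribute
   cells in which ≥ 2 alternatives share a level.

The overlap target defaults to 0.6.  An achievability floor exists: any
attribute with fewer levels than alternatives must overlap in every task
(pigeonhole), so with three alternatives the three binary attributes pin
the floor at 0.5 for the default schema; the optimizer converges to the
closest achievable rate.  Accidentally dominated alternatives in main
tasks are reported by the audit but not forbidden — screening them out
would distort level balance, and mild dominance is unavoidable in balanced
designs.

Warm-up tasks use simplified trade-offs: unordered attributes are held
constant across alternatives and exactly one alternative is weakly worse
than a competitor on every ordered attribute and strictly worse on at
least one (verified by the same dominance test the validity module uses).
Warm-ups never enter estimation.

## Synthetic respondents

The generator draws part-worth vectors from a finite mixture of
multivariate normals — the same population structure the hierarchical and
latent-class models assume — and simulates choices by multinomial logit.
The default population has a 55% benefit-driven class (remission slope
0.10 per point; mild risk aversions) and a 45% risk-averse class
(remission slope 0.03; strong prednisone and infection/cancer aversions,
−0.90 and −1.00 on the effects scale), with within-class standard
deviations of 0.015–0.3 per coordinate.  These magnitudes are package
choices for realistic fixtures: they give cohort-level MRS values in the
low teens of remission points and a clearly separable two-class structure,
the regime this kind of study reports.  They are not estimates of any real
cohort.

Injected pathological respondents (straight-liners who always choose one
screen position; choosers who always take the best available level of one
attribute, ties broken at random) exist so the validity detectors can be
tested against known ground truth; detectors must recall them perfectly by
construction.

Because simulated respondents are exactly the model's data-generating
process, passing recovery tests demonstrates correctness of the estimation
machinery — not robustness to the misspecification, inattention, learning
or fatigue present in real survey data.  Warm-up failure rates in
particular depend on preference strength: strongly preference-driven
cohorts fail ≈ never, while weak or injected-pathological respondents
produce non-zero failure rates.

## Hierarchical Bayesian estimation

The model: choice `j` in task `t` with probability
`softmax_j(x_tj' β_i)`; `β_i ~ N(μ, Σ)`; priors `μ ~ N(0, 100 I)` and
`Σ ~ InverseWishart(ν₀ = p + 3, S₀ = I)`.  The priors are proper and
weakly informative on the scale of coded part-worths (typically |β| < 2).

Sampling is Metropolis-within-Gibbs:

- per-respondent random-walk Metropolis on `β_i`, with a multivariate
  normal proposal shaped by the current `Σ` and a per-respondent scalar
  step size adapted during burn-in toward 23% acceptance (Robbins–Monro
  update every 50 iterations);
- `beta_scans` (default 3) Metropolis scans per cycle — extra scans
  decorrelate the individual-level block and markedly improve mixing of
  `μ` and `Σ` per stored draw at modest cost;
- conjugate Gibbs draws of `μ` (multivariate normal) and `Σ`
  (inverse-Wishart with `ν₀ + n` degrees of freedom).

The documented full-scale profile is 3 chains × 350,000 monitoring
iterations after 150,000 burn-in, matching common practice for
production-scale runs of this model; package tests and the acceptance
script use desk-scale profiles (3 × 5,000 after 2,500 at n = 150, and
smaller), which typically recover a known population mean with Pearson
r of 0.92-0.98 and mix below the 1.2 potential-scale-reduction level.
The correlation is computed over all ten coded components; the five
dosing effects are near zero in the generating population, so their
sampling noise dominates the metric's seed-to-seed spread.  All chain randomness
descends from one seed via spawned generators, so runs are bit-for-bit
reproducible.

Convergence is assessed with the classic Gelman–Rubin potential scale
reduction factor computed per scalar parameter from parallel chains
(`var⁺ = ((n−1)/n)W + B/n`, `R̂ = sqrt(var⁺/W)`), without chain splitting
by default to match the original formulation; a split-chain variant is
available via a flag.  Sampling noise can push `var⁺` fractionally below
`W`, so reported values are floored at 1 (identical chains give exactly
1).  Chains with zero internal variance are flagged degenerate rather than
given a value.  The conventional convergence threshold 1.10 is exposed as
`PSRF_THRESHOLD`.

## Preference summaries

All summaries default to draws of the population mean `μ` (cohort-level
reporting with credible intervals); a `pool_individuals` flag switches to
pooled per-respondent draws.

- **Scaled utilities**: per draw, compute zero-centred level utilities for
  every attribute (linear attributes evaluated at their design levels),
  then multiply by `10 / max |level utility|` for that draw.  Scaling per
  draw (rather than scaling posterior medians) makes each draw's extreme
  exactly ±10 and keeps the reported maximum at 10 by construction;
  medians and equal-tailed 2.5/97.5 percentiles are taken afterwards.
  Scaling is a positive monotone transform, so within-attribute level
  ordering is preserved.
- **Relative importance**: per draw, each attribute's utility range as a
  percentage of the summed ranges; sums to 100 on every draw, hence the
  posterior-mean point estimates also sum to 100 exactly.
- **MRS**: per draw, the utility gap between an attribute's preferred
  level and the target level divided by the remission slope per point (for
  an effects-coded binary, `2|β| / β_remission`).  The ratio is undefined
  where the slope crosses zero; a warning is attached when that happens in
  more than 1% of draws.

## Latent-class mixtures

Within-class homogeneous multinomial logit, mixed over respondents:
`L_i = Σ_k π_k Π_t P(choice_it | β_k)`.  EM with responsibility-weighted
MNL maximization in the M-step (BFGS with analytic gradient, warm-started,
capped at 50 inner iterations — a generalized EM step, so the
log-likelihood is provably non-decreasing and is asserted so at every
iteration).  Multi-start (default 20 random starts; tests use fewer on
well-separated data) guards against local optima; convergence is declared
at relative log-likelihood change below 1e-6.  A class whose share drops
below `1/(10n)` is perturbed and refloored rather than left empty.

BIC = −2·LL + q·ln(N) with q = K·p + (K−1) free parameters and N the
number of respondents — the mixture is over respondents, not choice
observations.  Assignment takes the maximum-probability class (ties to the
lowest index, flagged) and reports the fraction of respondents whose
maximum membership probability falls below 0.90.

## Validity audits

- *Dominated warm-ups*: fail if the dominated option was chosen in ≥ 1
  warm-up; missing answers make a respondent not assessable.
- *Straight-lining*: flag when any single screen position's share of main
  tasks exceeds 9/13 (configurable; the rule is descriptive in the source
  literature, so the threshold is a parameter).
- *Attribute dominance*: a respondent is dominant on an ordered attribute
  if in every main task their chosen alternative attains the task's best
  available level.  Shared-best levels count as attaining — under
  deliberate-overlap designs a strict-uniqueness rule would undercount.
  Dosing has no better-direction and is never evaluated.

## Treatment-scenario engine

Each candidate therapy carries its published remission and WDAE summaries
(median and 95% CrI from a network meta-analysis) plus fixed dosing and
risk flags.  The published intervals are reconstructed as normal
distributions on the log-odds scale — mean `logit(median)`, sd
`(logit(hi) − logit(lo)) / (2 × 1.959964)` — which respects the (0, 1)
support and the asymmetry of the printed intervals.  The actual posterior
draws behind those summaries are not available, so remission and WDAE are
sampled independently within and across treatments; any correlation in the
underlying evidence network is lost, which will mildly misstate the joint
tails.

The first-choice simulation runs `n_draws` (default 10,000) iterations:
one shared outcome draw per treatment per iteration, one independently
drawn posterior part-worth vector per patient from that patient's own
draws, argmax utility with exact ties broken uniformly at random (via a
vanishing 1e-9 jitter).  Sharing outcome draws across patients within an
iteration treats the evidence uncertainty as common to the cohort while
preference uncertainty stays individual — a stated assumption, since the
source analyses do not disambiguate.  Cohort preference is reported two
ways (modal-choice share and mean choice probability) because "preferred
by X% of patients" is ambiguous between them.  Pairwise matrices run the
same simulation per unordered pair and set `P(B,A) = 1 − P(A,B)` by
construction.

Sampled outcomes beyond the designed attribute ranges (e.g. a WDAE draw
above 30%) are linearly extrapolated with a logged warning by default; a
clamp mode is available.  Sensitivity scenarios are named transformations
of the profile list: `no_prednisone_biologics` (drop the initial
prednisone course for the four biologic-based therapies) and
`antitnf_blood_liver` (add the blood/liver risk to the two anti-TNF
agents).

## Pipeline and reproducibility

`run_pipeline` chains design → simulate → fit → summarize → lca →
validity → scenarios.  One global seed deterministically spawns
independent per-stage seeds; every output is text (CSV/JSON) written with
deterministic formatting, and the manifest records per-stage seeds, the
convergence summary and SHA-256 checksums — two runs with the same config
are byte-identical.  A stage failure halts with a structured error and
retains partial outputs.

## Problem sizes

The bundled tests and the acceptance script use desk-scale sizes chosen to
exercise every property at comfortable statistical power: 150 respondents
× 13 tasks for hierarchical recovery (3 chains × 5,000 monitoring / 2,500
burn-in draws), 300 respondents for two-class recovery, 40,000 simulated
random choosers against the exact 3¹³ trinomial enumeration, and 10,000
Monte-Carlo draws for the six-treatment scenario engine.

## Known limitations

- The reconstruction of outcome distributions from interval summaries is
  logit-normal by assumption; heavy-tailed or skewed NMA posteriors would
  deviate.
- The sampler is random-walk based; for much larger attribute spaces a
  gradient-based sampler would mix better.
- Latent-class membership is unconditioned on covariates; regressing
  characteristics on membership is left to standard tools.
- Synthetic cohorts cannot certify behaviour on real data (see above);
  the package's recovery guarantees are about the estimators, not about
  survey quality.
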