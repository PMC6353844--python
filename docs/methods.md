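# Methods

This note explains the scientific choices behind `logiprofile`: how the
dynamics are defined and simulated, how each omics data type is reduced to
node constraints, and how the implementation is validated. Everything
stated as a number here is computed by the test suite or the scripts in
this repository.

## 1. Dynamics: asynchronous Boolean networks as Markov chains

A logical model assigns each node `i` a Boolean rule `B_i` over the node
states. We use the *asynchronous, continuous-time* interpretation: the
model state `s ∈ {0,1}^n` evolves as a continuous-time Markov chain in
which a single node flips at a time. A node is *enabled* when its rule
value disagrees with its current value; it then flips after an exponential
waiting time with rate `k_up(i)` (for 0→1) or `k_down(i)` (for 1→0). All
rates default to 1, so the generic model's behavior is determined by the
logic alone; personalization acts by changing rates and initial
probabilities, never the rules.

Initial states are drawn node-wise independently: node `i` starts active
with its configured `istate` probability. A state with no enabled
transition is absorbing; trajectories that reach one keep that state for
the rest of the horizon.

**Simulation.** Trajectories are sampled with the Gillespie algorithm:
draw the total enabled rate `R`, advance time by `Exp(R)`, flip one
enabled node chosen proportionally to its rate. An ensemble of
trajectories yields, per time bin, the time-weighted frequency of each
node being active and of each model state; time-weighting within bins is
unbiased for jump processes, unlike sampling at bin edges. Each trajectory
receives an independent RNG stream spawned from one master seed, so
results are reproducible and independent of execution order.

**Asymptotic read-out.** Phenotype scores are the time-average of the
per-bin estimates over the final 10% of the simulated horizon (default
horizon 50 time units, 100 bins). Late-window averaging approximates the
attractor distribution while damping bin noise.

**Exact oracle.** For models of at most 12 nodes the full master equation
is solved directly: the sparse generator matrix over all `2^n` states is
built from the same enabled-transition definition, and the transient
distribution from the product-Bernoulli initial condition is obtained with
a Krylov matrix-exponential action. The sampler is validated against this
independent solution (see §6).

## 2. Expression processing

Continuous expression must become either a normalized value in [0, 1]
(soft constraints) or a Boolean (strict constraints). Both require a
per-gene model of the cohort distribution.

**Admissibility.** Genes that carry no usable signal are dropped first: a
gene is admissible when its amplitude (max − min across the cohort) is at
least one tenth of the median amplitude over all genes *and* at least 5%
of its values are non-zero.

**Classification.** Each admissible gene is assigned one of three shapes:

* *Bimodal*, when three criteria agree: Hartigan's dip test rejects
  unimodality (p < 0.05), the Bimodality Index of an equal-variance
  two-Gaussian fit exceeds 1.5, and the Fisher excess kurtosis is below 1.
  Requiring all three keeps the call conservative: the dip test alone is
  sensitive to heavy ties, and kurtosis alone to outliers.
* otherwise *zero-inflated*, when the global mode of a kernel-density
  estimate lies within the lowest 10% of the observed value range;
* otherwise *unimodal*.

The dip statistic is computed by a direct port of Hartigan's algorithm
(the package carries its own implementation, cross-checked value-for-value
against an independent reference implementation); p-values come from a
Monte-Carlo null of uniform samples of the same size, cached per sample
size and fixed-seeded. The Bimodality Index of a mixture with weights
`(π, 1−π)`, means `μ1 ≤ μ2` and common σ is
`BI = sqrt(π(1−π)) · (μ2−μ1)/σ`.

**Normalization.** Each class gets the transform that respects its shape:

* *Bimodal*: the posterior probability of the upper Gaussian component.
  With equal variances the log posterior ratio is linear in `x`, so this
  is a logistic function of `x` — smooth, monotone, and exactly the
  mixture model's own membership call.
* *Unimodal*: the sigmoid `1/(1 + exp(−λ(x − median)))` with
  `λ = ln(3)/MAD`. The slope constant is chosen so that one median
  absolute deviation above/below the median maps to exactly 0.75/0.25 —
  the transform's fixed anchor points. When more than half the values tie
  at the median (MAD = 0) the spread falls back to IQR/1.349, the
  normal-consistent equivalent; genes with zero spread by both measures
  are discarded.
* *Zero-inflated*: linear rescaling over the [1st, 99th] percentile range,
  clipped outside, preserving the asymmetric mass at zero.

**Binarization.** Bimodal genes binarize by posterior > 0.5. For the other
classes only confident tails are called: normalized values ≥ 0.75 become
1, ≤ 0.25 become 0, and the middle half is left missing (NaN) rather than
forced — a missing constraint is preferable to a wrong frozen state.

Fits can be estimated on the whole cohort or on a designated reference
(healthy) subset and then applied to tumor samples, which anchors
"high/low" at the healthy distribution.

## 3. Genomic functional inference

Mutations and CNA are reduced to per-gene Boolean effects
(1 = present/gain of function, 0 = absent/loss of function) by a cascade
ordered from most to least direct evidence:

1. truncating classes (nonsense, frameshift insertion/deletion, splice
   site, translation start site) → 0;
2. missense variants found in a user-supplied known-variant table → the
   table's gain/loss call;
3. remaining missense variants in genes annotated oncogene → 1, tumor
   suppressor → 0.

Routes 2–3 additionally require a deleteriousness label (SIFT deleterious,
or PolyPhen probably/possibly damaging) to filter passengers; truncating
variants need no such label. GISTIC copy-number calls contribute only at
high confidence: +2 → 1, −2 → 0; ±1 and 0 are ignored.

When one gene in one sample accumulates several effects, mutation evidence
overrides CNA, and within mutations truncating > known variant > gene
role. Conflicting effects at equal precedence drop the gene for that
sample with a warning, again preferring no constraint over a wrong one.
The resolution is deterministic and independent of record order.

## 4. Personalization

A correspondence table maps model nodes to gene symbols; a node may map to
a gene family (e.g., AKT → AKT1, AKT2), in which case discrete effects
propagate only when unanimous (conflicts drop the node) and continuous
values are averaged over the genes with data.

Six named strategies state which data feed which channel: mutations alone
or with CNA as strict variants (cases 1–2), CNA softened (case 3), RNA as
soft variants alone or on top of strict mutations/CNA (cases 4–6). When a
node receives several candidates, strict beats soft; within strict,
mutation > CNA > binarized expression; within soft, protein > RNA > CNA.

* **Strict variant** for value `v`: `istate = v` and the opposing rate is
  zeroed, so the node provably never leaves `v` in any trajectory.
* **Soft variant** for normalized value `norm`: `istate = norm`,
  `k_up = AF^(2(norm−0.5))`, `k_down = 1/k_up` (`AF = 100`). The rates are
  reciprocal by construction, symmetric under `norm → 1−norm`, and span
  `[1/AF, AF]`; `norm = 0.5` leaves the node generic.

Patients missing any data type a strategy requires are excluded (counted
and logged). Per-patient simulation seeds are derived as
`master_seed XOR crc32(patient_id)`, so a patient's result does not depend
on which other patients are in the cohort.

## 5. Cohort analysis

Each personalized settings object is simulated on the shared model; the
asymptotic probabilities of declared read-out nodes form a patients ×
phenotypes table, with the unpersonalized model simulated alongside as the
wild-type reference. Downstream:

* **Stratification** by cohort median of each phenotype (ties go to the
  low group); for two phenotypes the four-way combined label
  (e.g., `high_Proliferation/low_Apoptosis`) is added.
* **Correlation** with external per-patient scores by Spearman rank, with
  a seeded percentile-bootstrap 95% confidence interval.
* **Survival export**: group labels joined onto a (patient, time, event)
  table, ready for Kaplan–Meier/log-rank/Cox routines in any survival
  package; the survival statistics themselves are deliberately out of
  scope.

## 6. Validation strategy

All validation data are generated in-package from fixed seeds with known
ground truth:

* **Sampler vs. exact solution.** Ensemble node probabilities on the
  bundled 3- and 10-node models are compared with the bin-averaged master
  equation at five checkpoints and must agree within four Monte-Carlo
  standard errors (5,000 trajectories).
* **Estimator stability.** Ten independently seeded 1,000-trajectory
  wild-type runs must move asymptotic node probabilities by less than 0.01
  (median standard deviation across nodes). Wild type fixes the
  environmental input nodes; with inputs resampled per trajectory the
  bound is unattainable for any sampler, since a node copying a
  Bernoulli(0.5) input has irreducible seed-to-seed deviation
  `sqrt(0.25/1000) ≈ 0.016`.
* **Expression recovery.** On a 1,000-sample synthetic cohort with ten
  genes per generated class, classification must recover ≥ 90% of each
  class. The dip implementation is additionally pinned to reference
  statistic values frozen from an independent implementation.
* **Genomic recovery.** Synthetic mutation/CNA profiles deterministically
  traverse every cascade route; inference must reproduce each expected
  call and abstain on each route designed to yield none, exactly.
* **Strict dominance.** Every strictly personalized node must hold its
  assigned value with probability exactly 0 or 1 at every time bin of a
  full ensemble.
* **Closed-form anchors.** The unimodal sigmoid at median ± MAD equals
  0.75/0.25 to machine precision; soft-variant rates at `norm = 1` equal
  (100, 0.01) exactly; 10,000 initial-state draws at `istate = 0.6` land
  within two percentage points of 60%.

`scripts/acceptance.py` recomputes the anchor numbers from scratch through
the installed package and writes them as JSON (see the README).
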