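# Methods

This note documents the models and procedures implemented in `kinrates`,
the choices made where the design was genuinely open, and what the
synthetic-data studies do and do not demonstrate.

## Data model

The unit of analysis is a *meaning* — one of ten consanguineal kin
categories (B, D, F, M, MB, MZ, MZD, MZS, S, Z, read left-to-right through
the genealogy, e.g. MZD = mother's sister's daughter) or an open-class
(Swadesh-style) comparison meaning. For each meaning, the word forms used
across languages are partitioned into cognate classes, and that partition,
viewed as a map language → class, is a multistate phylogenetic character.
Languages lacking a term are coded missing (`?`); by default trees are
pruned per meaning to the languages with data, which is equivalent for the
likelihood (a missing tip contributes a vector of ones) but faster.
Language labels are matched to tree leaves by exact equality after Unicode
NFC normalization and case folding, with a user-supplied alias map for
residual mismatches.

## Cognate coding

Forms are compared as segmental strings: the transcription column when
present, otherwise the NFC-case-folded orthography with an optional
longest-match-first digraph substitution table. Full grapheme-to-phoneme
conversion is deliberately out of scope — it is a project of its own and
orthogonal to the analysis logic; the transcription column is the supported
route for phonetically coded data.

Pairwise distance is unit-cost Levenshtein divided by the longer string's
length (so it lies in [0, 1]); the Levenshtein core is delegated to
`edlib`. Clustering is flat agglomerative average linkage (UPGMA): merge
the closest pair of clusters until the minimum inter-cluster average
distance exceeds the threshold θ, default **0.4**. Single and complete
linkage are available behind a flag for sensitivity analysis. Because
average linkage is monotone, this is equivalent to cutting the dendrogram
at θ, which is how the independent scipy oracle verifies it. Ties are
broken by the lexicographically smallest member label of the candidate
pair, making the partition independent of input order and platform.
Synonyms (one language, several forms for a meaning) default to keeping
the first listed form; expert overrides can reassign any (language, form)
occurrence, are recorded with provenance, and re-densify class labels.

## Replacement-rate model

A meaning's character evolves on a rooted dated tree under a single-rate,
frequency-scaled CTMC (an F81-style generalization of the Mk model):
q_ij = μπ_j for i ≠ j. Two choices of π are implemented:

- `empirical` (default): π fixed at the observed tip-state frequencies, no
  pseudocounts — the direct reading of scaling state probabilities to the
  empirical frequencies;
- `uniform`: π_j = 1/k, the equal-frequency Mk model.

The reported quantity is the normalized global replacement rate, the
stationary expected flux R = −Σ_i π_i q_ii = μ(1 − Σπ²), converted from the
internal per-10-kyr time unit at reporting only (branch lengths stay in
years end-to-end in the I/O layer).

The transition kernel has the closed form p_ij(t) = π_j + (δ_ij − π_j)e^(−μt),
verified against the matrix exponential to 1e−10. The likelihood is
Felsenstein pruning with per-node rescaling; it is verified against
exhaustive summation over all ancestral-state assignments on small trees.
The pruning recursion and the samplers are numba-compiled over flattened
postorder arrays; all random numbers are pre-generated from a seeded
`numpy` generator outside the kernels, so identical (data, seed, schedule)
give bit-identical chains.

### A calibration caveat: empirical π on replacement-process data

On data generated by the replacement (infinite-alleles) process — every
event creates a brand-new class — the empirical-π model is misspecified in
a consequential way: as μ → ∞ its likelihood tends to the multinomial
probability of the tip data under π̂, which is exactly the distribution π̂
was fitted to. The resulting high plateau keeps substantial posterior mass
at large rates and biases posterior means upward at low true rates (and
makes the saturated regime prior-dominated). The equal-frequency Mk model
has a much lower plateau and is well calibrated on such data; the
parameter-recovery studies therefore run with `pi_mode="uniform"`, while
`empirical` remains the default for descriptive analyses. Rank order of
meanings by rate is robust to this choice.

### MCMC

Metropolis–Hastings on log μ with a Gaussian proposal. The step size
adapts toward a 0.2–0.4 acceptance rate in windows of 50 rate moves during
burn-in only and is frozen afterwards, preserving detailed balance of the
retained portion. Tree uncertainty: with probability 0.5 an iteration
proposes replacing the current tree by one drawn uniformly from the
posterior sample (MH-accepted); a deterministic sequential-chunk visitation
mode exists for comparison, and a fixed-tree mode for oracle tests. The
prior is exponential with mean 1.0 on μ in per-10-kyr units (uniform(0,100)
alternative); the prior and seed are recorded in every output.

The reference schedule is 10,010,000 iterations, burn-in 10,000, sampling
every 1,000 — 10,000 retained draws per chain; three chains per meaning are
pooled after a split-chain Gelman–Rubin check (pass threshold PSRF < 1.1).
Tests and examples use a scaled-down schedule (110,000 / 10,000 / 100,
1,000 draws) that keeps the same bookkeeping invariants at desk scale.

Joint analysis of replicate characters sharing one rate is supported
(`mcmc_rate_joint`): the shared parameter is R itself, each character
contributing its likelihood at μ_c = R/(1 − Σπ_c²); constant characters
carry no signal under the model and are skipped.

### Marginal likelihood

Stepping-stone sampling with K = 100 stones of 1,000 iterations each,
powers at Beta(0.3, 1) quantiles β_k = (k/K)^(1/0.3) (standard practice;
only the stone count and length are fixed by the reference procedure). Each
stone is warm-started from the previous one with a short internal warm-up.
The estimator sums log mean L^(β_{k+1}−β_k) over stones; on fixed-tree
problems it agrees with adaptive quadrature of ∫L(μ)p(μ)dμ within 0.1 log
units. The marginal likelihoods are computed and stored for auditing; no
downstream model comparison depends on them.

## Usage frequency (clfpm)

Frequency per million is 1e6 × count / corpus size. Zero counts are treated
as missing rather than smoothed: the study list consists of common words,
and +1 smoothing would distort centering across corpora of very different
sizes (a Laplace mode exists behind a flag). Log frequencies are centered
within each corpus over all study words present in it — kin and Swadesh
jointly, so both classes share one frequency scale — and then averaged,
unweighted per corpus (not per corpus type), over the corpora available
for each (language, meaning). Swadesh meanings that duplicate kin
categories (mother, father, husband, wife) are excluded from the combined
analysis. Within-corpus centering makes clfpm invariant to rescaling all
counts and sizes by a common factor.

## Regression

The response is the per-meaning mean rate. "Generalized logistic
regression" with a strictly positive continuous outcome is internally
contradictory, so the default is a linear mixed model on log(mean rate),
with a logit-on-max-normalized-rate alternative behind a flag; both are
reported when they disagree in sign. Fixed effects are clfpm × lexical
class with kin as the baseline level: the `clfpm` coefficient is the
kin-term frequency slope and `clfpm_x_swadesh` is the interaction (how
much shallower the core-vocabulary slope is). Fits are maximum likelihood
(not REML) so AICs are comparable across random-effect structures;
candidates are by-language intercepts, by-language intercepts + clfpm
slopes, and crossed language + meaning intercepts, compared by AIC with
likelihood-ratio tests where nested, preferring the simpler structure
within 2 AIC. In the pipeline's own regress stage the meaning-intercept
candidate is excluded by default: the outcome is constant within meaning,
so a free meaning intercept absorbs the frequency effect wholesale and
nulls the slope. Inference is reported as estimate, standard error and
Wald t.

## Synthetic-data generator

The generator emulates the statistical shape of the study:

- **Trees**: Yule (pure-birth) topologies rescaled to ultrametric depth
  8,700 years, 47 languages by default; a posterior-like sample is faked by
  multiplying every branch by i.i.d. lognormal(0, sd_log = 0.1) noise.
  (Real posterior samples vary in topology; the jittered sample varies only
  branch lengths. This suffices to exercise the tree-moving MCMC but does
  not test topology-driven uncertainty.)
- **Characters**: events are a Poisson process along branches. In the
  default infinite-alleles mode every event creates a new class, so the
  event intensity *is* the observable replacement rate R; in f81 mode
  events redraw from π and the intensity is R/(1 − Σπ²), making the
  estimator exactly well-specified. This explicit matching is what makes
  "true R" the same observable quantity the estimator reports.
- **Word forms**: replacement events draw an entirely new random form
  (length 4–8 over a 21-segment alphabet); between events forms accumulate
  single-segment substitutions at 0.02 per segment per 1,000 years. This
  gives the clustering step realistic within-class variation but no real
  phonology, sound laws, or borrowing.
- **Frequencies**: per meaning, latent log fpm = a + b·log R\* + N(0, σ)
  with defaults a = 3.0 (≈20 occurrences per million at R\* = 1 — common-
  word territory), b = −0.58, σ = 0.3; counts are Poisson(fpm × size/1e6)
  across 34 corpora in 21 languages of three types with log-uniform sizes
  1M–100M tokens. The log-linear coupling is a testing device for the
  pipeline, not a mechanistic claim.
- **True rates**: deterministic log-spaced grids, kin 0.3–3 and open-class
  0.8–10 per 10 kyr, so kin meanings are on average slower and (under the
  negative coupling) more frequent. Recovery studies use kin 0.5–8.

Ground truth (rates, classes, latent frequencies) is written to separate
files that the observable readers never touch.

What passing on synthetic data shows: the estimator chain is internally
consistent — it recovers the generator's rates, ranks, signs and effect
sizes at realistic sizes. What it does not show: robustness to real
phonological change, borrowing, topology uncertainty, corpus register
effects, or expert-judgement coding — none of which the generator
emulates.

## Problem sizes of the validation studies

The self-validation battery (`kinrates.validation`, run by
`scripts/acceptance.py` and the acceptance tests) uses: 1,000 random cases
for the likelihood and transition-kernel oracles; one fixed 10-leaf tree
for the stepping-stone-vs-quadrature check; 500 random matrices (n ≤ 6)
for the clustering oracle; 50 characters per rate level {0.5, 2, 8}/10 kyr
on one 47-leaf tree with the scaled-down schedule for rate recovery; 200
tables of 2,000 rows for regression recovery (binomial noise on a coverage
estimate is ±2% at this size); and 20 independent
end-to-end studies (47 languages, 25 trees, 20 meanings, one chain per
meaning). The whole battery completes in roughly ten minutes on one CPU.

## Numerical choices and edge cases

- Per-node rescaling of partial likelihoods prevents underflow; impossible
  data return −∞ and are flagged, never silently clipped.
- k = 1 (constant) characters have zero observable flux: the rate draws are
  exactly 0 and the meaning is dropped from the log-scale regression with a
  warning.
- (total − burn-in) must divide by the thinning interval; schedules are
  validated at construction.
- NEXUS standard matrices use 47 case-insensitive symbols (0-9, A-Z and
  eleven non-reserved punctuation characters) with `?` for missing — enough
  for one class per language at the default study size; ground-truth
  classes are additionally stored as plain CSV with no symbol cap.
- Stepping-stone stones are warm-started sequentially; the prior stone
  (β = 0) is sampled by the same MH kernel for uniformity.
- Seeds: every stochastic API takes an integer seed or Generator; the
  pipeline derives per-stage seeds from the master seed by hashing and
  records them in the manifest.

## Known limitations

- The jittered tree sample has a single topology (see above).
- The empirical-π model's plateau bias on replacement-process data (see
  the calibration caveat); posterior means at high rates are prior-
  sensitive where the data saturate.
- The regression treats per-meaning mean rates as error-free observations;
  posterior uncertainty in the rates is not propagated.
- No borrowing/contact, sound-class alignment, or ancestral-state output;
  reversible-jump and covarion models are out of scope.
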