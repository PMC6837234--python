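# kinrates

Do frequently used words resist replacement? `kinrates` implements the full
analysis chain for testing this on a *closed semantic class* — kinship terms
— across a language family: it codes word forms into cognate classes, infers
each meaning's rate of lexical replacement on a sample of dated phylogenies,
converts corpus counts into comparable usage frequencies, and regresses rate
on frequency and lexical class. A first-class synthetic-data module generates
complete studies with known ground truth, so every stage is testable without
any external data.

The package is aimed at quantitative historical linguists and cultural-
evolution researchers who work with word lists, dated language trees and
corpus frequencies.

## The model

Each meaning *m* (e.g. *mother's sister*, code MZ) is a multistate character:
language → cognate class. On a rooted tree with branch lengths in years, the
character evolves by a continuous-time Markov chain with a single base rate
μ and frequency-scaled transitions,

    q_ij = μ π_j   (i ≠ j),    q_ii = −μ (1 − π_i),

with π the state frequencies (empirical tip frequencies by default; an
equal-frequency Mk variant is available). The reported quantity is the
normalized **global rate of replacement** — the stationary expected flux

    R = −Σ_i π_i q_ii = μ (1 − Σ_i π_i²),

scaled to events per 10,000 years. The likelihood is computed by Felsenstein
pruning with the closed-form kernel p_ij(t) = π_j + (δ_ij − π_j)e^(−μt);
the posterior of R is sampled by Metropolis–Hastings on log μ while the
chain also moves across a posterior sample of trees, integrating out
phylogenetic uncertainty. Marginal likelihoods come from a stepping-stone
sampler (100 stones × 1,000 iterations, Beta(0.3, 1) power spacing);
convergence is checked with the split-chain Gelman–Rubin PSRF.

Cognate classes are built by flat average-linkage (UPGMA) clustering of
normalized Levenshtein distances at a 0.4 threshold, with expert overrides.
Usage is measured as **clfpm** — natural-log frequency per million tokens,
centered within each corpus and averaged across corpora per word per
language. The final step fits a linear mixed model

    log R ~ clfpm × lexical_class + (random effects),

with the random-effect structure chosen by AIC; the kin-baseline `clfpm`
coefficient is the frequency slope and `clfpm_x_swadesh` measures how much
shallower the core-vocabulary (Swadesh) slope is.

## Worked example

`examples/02_rate_inference.py` simulates a 47-language dated tree (root at
8,700 years), evolves one character at a known rate of 2 replacements per
10 kyr, and re-estimates it:

```
simulated character: 19 cognate classes from 24 events
posterior mean rate: 2.44 per 10 kyr (true 2.0)
95% credible interval: [1.42, 3.86]
Gelman-Rubin PSRF over 3 chains: 0.999 (converged)
stepping-stone log marginal likelihood: -91.59 (100 stones x 1000 iterations)
```

The credible interval brackets the true rate and the PSRF near 1 shows the
three chains mixed over the same posterior. The other example scripts cover
cognate coding (`01`), frequency processing and the mixed-effects regression
(`03`), and the full pipeline on a synthetic study (`04`), e.g.:

```
Spearman correlation (true vs estimated): 0.96
fitted frequency slope: -0.87 (generator coupling is negative: frequent meanings replace slower)
```

## Pipeline CLI

For shell use, the same stages are exposed as a thin CLI:

```bash
kinrates run-all --config config.yaml --outdir run1 --seed 3
kinrates rates --outdir run1 --schedule 110000/10000/100   # rerun one stage
```

Each stage writes standard formats (CSV, Newick/NEXUS) plus a manifest with
config hash, seeds and wall times, so deterministic stages reproduce
byte-for-byte and seeded stochastic stages draw-for-draw.

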