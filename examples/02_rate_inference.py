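"""Bayesian replacement-rate estimation on a dated tree.

Simulates a 47-language ultrametric tree rooted 8,700 years ago, evolves one
cognate character at a known rate of 2 replacements per 10,000 years, and
estimates that rate by MCMC over three chains, reporting the posterior mean,
credible interval, Gelman-Rubin diagnostic and stepping-stone marginal
likelihood.
"""
import numpy as np

import kinrates as kr

TRUE_RATE = 2.0  # replacements per 10,000 years

tree = kr.simulate_tree(47, root_age=8700.0, seed=11)
sample = kr.jitter_tree_sample(tree, m=25, sd_log=0.1, seed=12)
char, n_events = kr.simulate_character(tree, TRUE_RATE, seed=13, meaning="B")
print(f"simulated character: {char.k} cognate classes from {n_events} events")

chains = [
    kr.mcmc_rate(char, sample, schedule=kr.TEST_SCHEDULE, seed=100 + i,
                 pi_mode="uniform")
    for i in range(3)
]
report = kr.gelman_rubin([c.rates for c in chains])
summary = kr.summarize(chains)
print(f"posterior mean rate: {summary.mean:.2f} per 10 kyr (true {TRUE_RATE})")
print(f"95% credible interval: [{summary.ci_low:.2f}, {summary.ci_high:.2f}]")
print(f"Gelman-Rubin PSRF over 3 chains: {report.psrf:.3f} "
      f"({'converged' if report.passed else 'NOT converged'})")

ss = kr.stepping_stone(char, tree, seed=14)
print(f"stepping-stone log marginal likelihood: {ss.log_ml:.2f} "
      f"({ss.n_stones} stones x {ss.iters_per_stone} iterations)")
# The credible interval should bracket the true rate; PSRF near 1 means the
# three chains agree. The marginal likelihood is stored for model auditing.
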