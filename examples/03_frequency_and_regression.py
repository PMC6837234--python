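"""From corpus counts to the rate ~ frequency x class regression.

Processes a miniature corpus-count table into centered log frequency per
million (clfpm), then fits the mixed-effects model on a synthetic regression
table generated at the study's reported effect sizes (frequency slope -0.58
for kin terms, interaction +0.18 for the shallower core-vocabulary slope).
"""
import pandas as pd

import kinrates as kr
from kinrates.regression import fit_model, select_random_effects
from kinrates.simulate import simulate_regression_table

counts = kr.CorpusCounts(
    pd.DataFrame(
        [
            ("Swedish", "mor", "M", "sv_spoken", "spoken", 5200, 4_000_000),
            ("Swedish", "moster", "MZ", "sv_spoken", "spoken", 310, 4_000_000),
            ("Swedish", "mor", "M", "sv_web", "web", 41_000, 60_000_000),
            ("Swedish", "moster", "MZ", "sv_web", "web", 2_100, 60_000_000),
        ],
        columns=["language", "form", "meaning", "corpus_id", "corpus_type",
                 "count", "corpus_size"],
    )
)
clfpm = kr.compute_clfpm(counts)
print("clfpm per (language, meaning) - centered within corpus, averaged across:")
print(clfpm.to_string(index=False))
# 'mother' is used more than 'maternal aunt' in both corpora, so its clfpm is
# positive and the aunt's negative; the corpus-size difference cancels out.

table = simulate_regression_table(
    n_languages=20, n_meanings=100, beta_freq=-0.58, beta_int=0.18, seed=42
)
selection = select_random_effects(table)
fit = selection.best
print(f"\nmixed model log(rate) ~ clfpm * class, "
      f"random effects: {fit.random_structure}")
print(fit.fixed.round(3).to_string())
print("\nAIC comparison across random-effect structures:")
print(selection.table.round(1).to_string(index=False))
# The clfpm row estimates the kin-term frequency slope (truth -0.58); the
# clfpm_x_swadesh row is the interaction (truth +0.18): core-vocabulary
# items respond less steeply to usage frequency than kin terms.
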