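"""Mixed-effects regression of replacement rate on usage frequency and
lexical class.

The response is the per-meaning mean replacement rate (per 10 kyr); the
predictors are aggregated centered log frequency per million (clfpm) and
lexical class (kin vs swadesh, kin as the baseline level), plus their
interaction. Because a strictly positive rate is not a binomial outcome, the
default model is a linear mixed model on log(mean_rate); a logit link on the
max-normalized rate is available as an alternative. Random-effect structures
are compared by AIC (maximum likelihood, not REML) with likelihood-ratio
tests where nested.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .types import ValidationError

log = logging.getLogger(__name__)

OUTCOME_TRANSFORMS = ("log", "logit")

#: Candidate random-effect structures, simplest first.
DEFAULT_CANDIDATES = (
    "language_intercept",
    "language_intercept_slope",
    "language_meaning_intercepts",
)

#: Number of variance/covariance parameters per candidate (for tie-breaking).
_RE_NPARAMS = {
    "language_intercept": 1,
    "language_intercept_slope": 3,
    "language_meaning_intercepts": 2,
}


@dataclasses.dataclass
class FitResult:
    """Fixed effects and fit statistics of one mixed-model fit.

    ``fixed`` has one row per fixed effect: estimate, standard error, t
    (Wald). Effect names: intercept, clfpm (the kin-baseline frequency
    slope), class_swadesh (level shift), clfpm_x_swadesh (the interaction:
    how much shallower the swadesh slope is)."""

    fixed: pd.DataFrame
    random_structure: str
    outcome_transform: str
    aic: float
    loglik: float
    converged: bool
    n_obs: int
    model: object = dataclasses.field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.fixed.loc[name, "estimate"])

    def se(self, name: str) -> float:
        return float(self.fixed.loc[name, "se"])


def build_regression_table(
    rates: Union[Mapping[str, float], pd.DataFrame],
    clfpm_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-meaning mean rates with per-(language, meaning) clfpm rows.

    ``rates`` maps meaning -> mean rate per 10 kyr (or is a DataFrame with
    ``meaning``/``mean_rate`` columns). Meanings lacking a rate are dropped
    with a warning; the inner-join statistics are logged."""
    if isinstance(rates, pd.DataFrame):
        rate_df = rates[["meaning", "mean_rate"]].copy()
    else:
        rate_df = pd.DataFrame(
            {"meaning": list(rates.keys()), "mean_rate": list(rates.values())}
        )
    if rate_df["meaning"].duplicated().any():
        raise ValidationError("duplicate meanings in the rate table")
    need = {"language", "meaning", "lexical_class", "clfpm"}
    missing_cols = need - set(clfpm_table.columns)
    if missing_cols:
        raise ValidationError(f"clfpm table missing columns {sorted(missing_cols)}")
    dropped = sorted(set(clfpm_table["meaning"]) - set(rate_df["meaning"]))
    if dropped:
        log.warning("%d meanings lack a rate and are dropped: %s…",
                    len(dropped), dropped[:5])
    out = clfpm_table.merge(rate_df, on="meaning", how="inner")
    if out.empty:
        raise ValidationError("empty join between rates and clfpm table")
    if out.duplicated(subset=["language", "meaning"]).any():
        raise ValidationError("duplicated (language, meaning) rows after join")
    if out["clfpm"].isna().any():
        raise ValidationError("missing clfpm values in joined table")
    if (out["mean_rate"] <= 0).any():
        raise ValidationError("mean_rate must be strictly positive")
    log.info("regression table: %d rows, %d languages, %d meanings",
             len(out), out["language"].nunique(), out["meaning"].nunique())
    return out.reset_index(drop=True)


_RENAME = {
    "Intercept": "intercept",
    "clfpm": "clfpm",
    "C(lexical_class)[T.swadesh]": "class_swadesh",
    "clfpm:C(lexical_class)[T.swadesh]": "clfpm_x_swadesh",
}


def _outcome(table: pd.DataFrame, transform: str) -> pd.Series:
    if transform == "log":
        return np.log(table["mean_rate"])
    # logit on the max-normalized rate (in (0, 1))
    p = table["mean_rate"] / (table["mean_rate"].max() * 1.0001)
    return np.log(p / (1 - p))


def fit_model(
    table: pd.DataFrame,
    outcome_transform: str = "log",
    random_structure: str = "language_intercept",
) -> FitResult:
    """Fit outcome ~ clfpm * lexical_class with the given random effects.

    Maximum-likelihood (non-REML) fit so AICs are comparable across
    random-effect structures; the optimizer is deterministic. Non-convergence
    is flagged on the result rather than raised."""
    if outcome_transform not in OUTCOME_TRANSFORMS:
        raise ValidationError(f"outcome_transform must be in {OUTCOME_TRANSFORMS}")
    if random_structure not in _RE_NPARAMS:
        raise ValidationError(f"unknown random_structure {random_structure!r}")
    df = table.copy()
    classes = sorted(df["lexical_class"].unique())
    if len(classes) < 2:
        raise ValidationError(
            "interaction clfpm:lexical_class is inestimable: lexical_class has a "
            f"single level {classes}; the clfpm_x_swadesh term is aliased"
        )
    df["y"] = _outcome(df, outcome_transform)
    formula = "y ~ clfpm * C(lexical_class)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random_structure == "language_intercept":
            model = smf.mixedlm(formula, df, groups=df["language"])
        elif random_structure == "language_intercept_slope":
            model = smf.mixedlm(
                formula, df, groups=df["language"], re_formula="1 + clfpm"
            )
        else:  # crossed language + meaning intercepts via variance components
            model = smf.mixedlm(
                formula,
                df,
                groups=np.ones(len(df)),
                re_formula="0",
                vc_formula={"language": "0 + C(language)", "meaning": "0 + C(meaning)"},
            )
        fit = None
        for method in ("bfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=500)
            except np.linalg.LinAlgError:
                continue
            if fit.converged and np.isfinite(fit.llf):
                break
        if fit is None:
            raise ValidationError(f"all optimizers failed for {random_structure}")
    names = [_RENAME.get(n, n) for n in fit.fe_params.index]
    fixed = pd.DataFrame(
        {
            "estimate": fit.fe_params.values,
            "se": fit.bse_fe.values,
            "t": fit.fe_params.values / fit.bse_fe.values,
        },
        index=pd.Index(names, name="effect"),
    )
    if not np.all(fixed["se"] > 0):
        log.warning("non-positive standard errors in fit (%s)", random_structure)
    k_params = len(fit.fe_params) + _RE_NPARAMS[random_structure] + 1  # + residual var
    llf = float(fit.llf)
    aic = 2 * k_params - 2 * llf
    converged = bool(fit.converged) and np.isfinite(llf)
    if not converged:
        log.warning("mixed model did not converge (%s)", random_structure)
    return FitResult(
        fixed=fixed,
        random_structure=random_structure,
        outcome_transform=outcome_transform,
        aic=float(aic),
        loglik=llf,
        converged=converged,
        n_obs=len(df),
        model=fit,
    )


#: Nesting relations among the default candidates, for likelihood-ratio tests.
_NESTED_IN = {
    "language_intercept": ("language_intercept_slope", "language_meaning_intercepts"),
}


@dataclasses.dataclass
class SelectionResult:
    """Outcome of AIC-guided random-effect selection."""

    best: FitResult
    table: pd.DataFrame  # candidate, aic, delta_aic, loglik, converged
    lrt: pd.DataFrame  # nested pair tests: statistic, df, p


def select_random_effects(
    table: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    outcome_transform: str = "log",
) -> SelectionResult:
    """Fit every candidate random-effect structure and keep the lowest AIC.

    Ties within 2 AIC go to the structure with fewer parameters. Where
    candidates are nested, likelihood-ratio tests are reported alongside."""
    if not candidates:
        raise ValidationError("candidate set is empty")
    fits: dict[str, FitResult] = {}
    for cand in candidates:
        try:
            fits[cand] = fit_model(table, outcome_transform, cand)
        except (ValidationError, np.linalg.LinAlgError) as e:
            log.warning("candidate %s failed: %s", cand, e)
    converged = {c: f for c, f in fits.items() if f.converged}
    if not converged:
        raise ValidationError("no candidate random-effect structure converged")
    best_aic = min(f.aic for f in converged.values())
    # prefer the simplest structure within 2 AIC of the minimum
    viable = [c for c, f in converged.items() if f.aic - best_aic < 2.0]
    best_name = min(viable, key=lambda c: (_RE_NPARAMS[c], converged[c].aic))
    rows = [
        {
            "candidate": c,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "loglik": f.loglik,
            "converged": f.converged,
        }
        for c, f in fits.items()
    ]
    lrt_rows = []
    for simple, complexes in _NESTED_IN.items():
        if simple not in converged:
            continue
        for cx in complexes:
            if cx not in converged:
                continue
            stat = 2 * (converged[cx].loglik - converged[simple].loglik)
            df_diff = _RE_NPARAMS[cx] - _RE_NPARAMS[simple]
            p = float(stats.chi2.sf(max(stat, 0.0), df_diff))
            lrt_rows.append(
                {"simple": simple, "complex": cx, "statistic": stat, "df": df_diff, "p": p}
            )
    return SelectionResult(
        best=converged[best_name],
        table=pd.DataFrame(rows).sort_values("aic").reset_index(drop=True),
        lrt=pd.DataFrame(lrt_rows),
    )
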