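"""Random-intercept mixed models, BIC Bayes factors, and FDR control.

Hypotheses are tested by comparing nested maximum-likelihood fits of linear
mixed models with a random intercept per participant: the likelihood-ratio
statistic chi^2 = 2 (logLik_full - logLik_null) is referred to a chi-square
distribution, and a Bayes factor is approximated from the BIC difference,

    BF_10 = exp((BIC_null - BIC_full) / 2),        BF_01 = 1 / BF_10.

Effect sizes are standardized marginal f^2 values built from the marginal
R^2 of Nakagawa & Schielzeth — the variance of the fixed-effect predictions
over the total of fixed, random-intercept, and residual variance:

    f^2 = (R2m_full - R2m_null) / (1 - R2m_full).

Estimation is maximum likelihood (never REML), since both the LRT and the
BIC comparison require comparable likelihoods across fixed-effect
specifications.  BIC uses the number of observations (rows), counting fixed
effects plus the two variance components as parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


class ModelSpecError(ValueError):
    """Models violate the comparison contract (non-nested, different data)."""


@dataclass
class ModelFit:
    """A converged ML fit of a random-intercept linear mixed model."""

    params: pd.Series          # fixed-effect estimates b
    bse: pd.Series             # standard errors
    llf: float                 # ML log-likelihood
    k: int                     # parameter count (fixed + 2 variance comps)
    n: int                     # observation count (rows)
    bic: float                 # k ln(n) - 2 logLik
    group_var: float           # random-intercept variance
    resid_var: float           # residual variance
    fixed_pred: np.ndarray     # fixed-effects predictions per row
    converged: bool
    formula: str = ""

    @property
    def marginal_r2(self) -> float:
        """Nakagawa-Schielzeth marginal R^2 of the fixed effects."""
        vf = float(np.var(self.fixed_pred))
        return vf / (vf + self.group_var + self.resid_var)


def fit_random_intercept(data: pd.DataFrame, formula: str,
                         groups: str = "participant") -> ModelFit:
    """ML fit of ``formula`` with a random intercept per ``groups`` level.

    Rows with missing values in the model variables are dropped.  A fit that
    fails to converge is returned flagged rather than raised, except for
    singular designs, which raise an estimation error.
    """
    data = data.dropna(subset=_formula_columns(formula, data)).reset_index(drop=True)
    if data[groups].nunique() < 2:
        raise ModelSpecError("need at least 2 grouping levels")
    model = MixedLM.from_formula(formula, groups=groups, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ModelSpecError("singular fixed-effects design")
    n = int(model.exog.shape[0])
    k = int(model.exog.shape[1]) + 2   # fixed effects + RE var + residual var
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        fe = res.fe_params
        llf = float(res.llf)
        bse = res.bse.loc[fe.index]
        group_var = float(np.squeeze(res.cov_re))
        resid_var = float(res.scale)
        converged = bool(res.converged)
    except np.linalg.LinAlgError:
        # The random-intercept variance collapsed to the boundary and the
        # Hessian is singular there; the ML solution at sigma_b^2 = 0 is
        # ordinary least squares with the ML residual variance.
        import statsmodels.api as sm
        ols = sm.OLS(model.endog, model.exog).fit()
        fe = pd.Series(ols.params, index=model.exog_names)
        llf = float(ols.llf)
        bse = pd.Series(ols.bse, index=model.exog_names)
        group_var, resid_var = 0.0, float(ols.ssr / n)
        converged = True
    return ModelFit(
        params=fe,
        bse=bse,
        llf=llf, k=k, n=n,
        bic=k * np.log(n) - 2.0 * llf,
        group_var=group_var,
        resid_var=resid_var,
        fixed_pred=np.asarray(model.exog @ np.asarray(fe)),
        converged=converged,
        formula=formula,
    )


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c in formula]


@dataclass
class ComparisonResult:
    """Likelihood-ratio and Bayes-factor comparison of nested model fits."""

    name: str
    chi2: float
    df: int
    p: float
    b: float               # coefficient of the added effect (NaN if >1 df)
    se: float
    bf10: float
    bf01: float
    f2: float
    passes_bh: bool | None = None   # set by attach_bh across a family


def compare_models(full: ModelFit, null: ModelFit,
                   name: str = "") -> ComparisonResult:
    """Compare a full model against the nested null it extends.

    chi^2 = 2 (logLik_full - logLik_null) on df = k_full - k_null;
    BF_10 = exp((BIC_null - BIC_full)/2).  The reported b/SE are those of
    the single added fixed effect when df = 1.
    """
    if full.n != null.n:
        raise ModelSpecError(
            f"models fitted on different data (n={full.n} vs {null.n})")
    if full.k < null.k:
        raise ModelSpecError("null must be nested in full (fewer parameters)")
    df = full.k - null.k
    chi2 = max(2.0 * (full.llf - null.llf), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if (chi2 > 0 and df > 0) else 1.0
    # BF from BIC difference; clip the exponent for numerical safety
    expo = np.clip((null.bic - full.bic) / 2.0, -700, 700)
    bf10 = float(np.exp(expo))
    added = [nm for nm in full.params.index if nm not in null.params.index]
    if len(added) == 1:
        b, se = float(full.params[added[0]]), float(full.bse[added[0]])
    else:
        b, se = float("nan"), float("nan")
    return ComparisonResult(name=name, chi2=float(chi2), df=df, p=p,
                            b=b, se=se, bf10=bf10, bf01=1.0 / bf10,
                            f2=marginal_f2(full, null))


def marginal_f2(full: ModelFit, null: ModelFit) -> float:
    """Proportional increase in marginally explained variance.

    f^2 = (R2m_full - R2m_null) / (1 - R2m_full); returns NaN (flagged)
    if R2m_full reaches 1 numerically.
    """
    r2f, r2n = full.marginal_r2, null.marginal_r2
    if r2f >= 1.0 - 1e-12:
        return float("nan")
    return max((r2f - r2n) / (1.0 - r2f), 0.0)


def bh_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR flags at level ``q``.

    Returns a boolean array; rejecting p_i implies rejecting every smaller
    p (monotone).  Empty input yields an empty array.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def attach_bh(results: list[ComparisonResult], q: float = 0.05
              ) -> list[ComparisonResult]:
    """Set ``passes_bh`` across a family of comparisons (in place)."""
    flags = bh_adjust([r.p for r in results], q=q)
    for r, f in zip(results, flags):
        r.passes_bh = bool(f)
    return results


@dataclass
class PowerResult:
    power: float
    mc_se: float       # Monte-Carlo standard error
    n_sims: int
    beta: float        # injected group effect on the outcome scale


def _simulate_lmm_dataset(rng: np.random.Generator, beta: float,
                          n_groups: tuple[int, int], n_per: int,
                          sigma_b: float, sigma_e: float) -> pd.DataFrame:
    n1, n2 = n_groups
    n = n1 + n2
    ids = np.repeat(np.arange(n), n_per)
    grp = np.repeat(np.r_[np.zeros(n1), np.ones(n2)], n_per)
    u = np.repeat(rng.normal(0.0, sigma_b, n), n_per)
    y = beta * grp + u + rng.normal(0.0, sigma_e, ids.size)
    return pd.DataFrame({"y": y, "group": grp, "participant": ids})


def effect_for_f2(f2: float, n_groups: tuple[int, int],
                  sigma_b: float = 1.0, sigma_e: float = 1.0) -> float:
    """Group effect beta whose generating marginal f^2 equals ``f2``.

    For a binary indicator with observation-level variance p(1-p),
    var(fixed predictions) = beta^2 p (1-p) and the null explains nothing,
    so f^2 = beta^2 p(1-p) / (sigma_b^2 + sigma_e^2); invert for beta.
    """
    if f2 < 0:
        raise ValueError("f2 must be non-negative")
    n1, n2 = n_groups
    p = n1 / (n1 + n2)
    return float(np.sqrt(f2 * (sigma_b ** 2 + sigma_e ** 2) / (p * (1 - p))))


def power_simulation(f2: float = 0.15, n_groups: tuple[int, int] = (37, 50),
                     n_per: int = 2, n_sims: int = 500, alpha: float = 0.05,
                     seed: int = 0, sigma_b: float = 1.0,
                     sigma_e: float = 1.0) -> PowerResult:
    """Simulation-based power of the group LRT in a random-intercept LMM.

    Generates ``n_sims`` datasets with two groups of participants, ``n_per``
    repeated observations each, and a group fixed effect calibrated
    analytically to the target generating marginal f^2; fits full and null
    models by ML and counts likelihood-ratio rejections at ``alpha``.
    With f^2 = 0 this estimates the type-I error rate.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    beta = effect_for_f2(f2, n_groups, sigma_b, sigma_e)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        df = _simulate_lmm_dataset(rng, beta, n_groups, n_per,
                                   sigma_b, sigma_e)
        full = fit_random_intercept(df, "y ~ group")
        null = fit_random_intercept(df, "y ~ 1")
        if compare_models(full, null).p < alpha:
            rejections += 1
    power = rejections / n_sims
    return PowerResult(power=power,
                       mc_se=float(np.sqrt(power * (1 - power) / n_sims)),
                       n_sims=n_sims, beta=beta)
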