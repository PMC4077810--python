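"""Field statistics: biomass, herd demography and ordinal body condition.

Herbaceous biomass comes from a disc pasture meter (DPM), whose mean
settling height X (cm, over 50 drops) converts to standing biomass via the
calibration Y = -1633 + 1791*sqrt(X) kg/ha, or — at inundated sites — from
four 0.25 m2 quadrats of cut grass whose summed dry weight (g, i.e. g/m2
over 1 m2 total) is multiplied by 10 to give kg/ha.

Demography is summarised as per-herd young:adult-female, calf:adult-female
and adult-male:adult-female ratios; between-year comparisons use binomial
or quasibinomial logistic regression.  Body condition scores (ordinal 1-5)
are modelled with a proportional-odds cumulative-logit model, optionally
with a Laplace-approximated herd random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

DPM_INTERCEPT = -1633.0
DPM_SLOPE = 1791.0


# --------------------------------------------------------------------------
# Biomass
# --------------------------------------------------------------------------


def dpm_biomass(mean_settling_height_cm):
    """Biomass (kg/ha) from the mean settling height of 50 DPM drops.

    Values below the calibration range come out negative and should be
    flagged downstream, not clamped.
    """
    x = np.asarray(mean_settling_height_cm, dtype=float)
    if (x < 0).any():
        raise ValueError("settling height must be non-negative")
    y = DPM_INTERCEPT + DPM_SLOPE * np.sqrt(x)
    return float(y) if y.ndim == 0 else y


def quadrat_biomass(four_weights_g) -> float:
    """Biomass (kg/ha) from the summed dry weight of exactly four quadrats."""
    w = np.asarray(four_weights_g, dtype=float)
    if w.shape != (4,):
        raise ValueError("exactly four quadrat weights are required")
    if (w < 0).any():
        raise ValueError("quadrat weights must be non-negative")
    return float(10.0 * w.sum())


def biomass_table(records) -> pd.DataFrame:
    """Flatten FieldRecords into one biomass estimate per site.

    Returns columns site_id, habitat, year, method, biomass_kg_ha and a
    below_calibration flag for negative DPM values.
    """
    rows = []
    dpm = records.dpm
    if len(dpm):
        hcols = [c for c in dpm.columns if c.startswith("height_")]
        for _, r in dpm.iterrows():
            y = dpm_biomass(np.mean([r[c] for c in hcols]))
            rows.append(
                {
                    "site_id": r["site_id"],
                    "habitat": r["habitat"],
                    "year": r["year"],
                    "method": "dpm",
                    "biomass_kg_ha": y,
                    "below_calibration": y < 0,
                }
            )
    quad = records.quadrats
    if len(quad):
        for _, r in quad.iterrows():
            y = quadrat_biomass([r["w1"], r["w2"], r["w3"], r["w4"]])
            rows.append(
                {
                    "site_id": r["site_id"],
                    "habitat": r["habitat"],
                    "year": r["year"],
                    "method": "quadrat",
                    "biomass_kg_ha": y,
                    "below_calibration": False,
                }
            )
    return pd.DataFrame(rows)


def biomass_year_model(samples: pd.DataFrame):
    """Two-factor linear model of log biomass on year x habitat.

    Sites flagged below calibration (or non-positive) are excluded.  The
    interaction is tested by the change in fit between the additive and
    interaction models (F test).

    Returns a dict with the fitted result and the interaction test.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = samples.loc[samples["biomass_kg_ha"] > 0].copy()
    if df["habitat"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need at least 2 habitats and 2 years with positive biomass")
    df["log_biomass"] = np.log(df["biomass_kg_ha"])
    additive = smf.ols("log_biomass ~ C(year) + C(habitat)", data=df).fit()
    full = smf.ols("log_biomass ~ C(year) * C(habitat)", data=df).fit()
    cmp = anova_lm(additive, full)
    return {
        "model": full,
        "additive": additive,
        "interaction_F": float(cmp["F"].iloc[1]),
        "interaction_df": (int(cmp["df_diff"].iloc[1]), int(cmp["df_resid"].iloc[1])),
        "interaction_p": float(cmp["Pr(>F)"].iloc[1]),
        "n_excluded": int((samples["biomass_kg_ha"] <= 0).sum()),
    }


# --------------------------------------------------------------------------
# Demography
# --------------------------------------------------------------------------


def demographic_ratios(herds: pd.DataFrame):
    """Per-herd demographic ratios and their year-level mean +/- SD.

    Herds with zero adult females are excluded with a warning.  Returns
    (per_herd, summary) DataFrames; summary rows are (ratio, year, mean,
    sd, n_herds).
    """
    ok = herds["adult_female"] >= 1
    if (~ok).any():
        warnings.warn(
            f"excluding {(~ok).sum()} herd(s) with zero adult females", stacklevel=2
        )
    df = herds.loc[ok].copy()
    af = df["adult_female"]
    df["young_per_adult_female"] = df["young"] / af
    df["calf_per_adult_female"] = df["calf"] / af
    df["adult_male_per_adult_female"] = df["adult_male"] / af
    ratios = [
        "young_per_adult_female",
        "calf_per_adult_female",
        "adult_male_per_adult_female",
    ]
    rows = []
    for ratio in ratios:
        for year, grp in df.groupby("year"):
            rows.append(
                {
                    "ratio": ratio,
                    "year": year,
                    "mean": grp[ratio].mean(),
                    "sd": grp[ratio].std(ddof=1),
                    "n_herds": len(grp),
                }
            )
    return df, pd.DataFrame(rows)


def ratio_year_test(
    successes, totals, year, family: str = "binomial"
) -> dict:
    """Compare a per-herd count ratio between two years by logistic GLM.

    Fits (successes | totals) ~ year.  ``binomial`` reports a Wald z test;
    ``quasibinomial`` scales the variance by the Pearson dispersion and
    reports a t test on n - 2 df.
    """
    import statsmodels.api as sm

    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    year = np.asarray(year)
    if (totals < 1).any():
        raise ValueError("totals must be at least 1")
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family: {family}")
    years = np.unique(year)
    if len(years) != 2:
        raise ValueError("exactly two years required")
    x = sm.add_constant((year == years[1]).astype(float))
    endog = np.c_[successes, totals - successes]
    fit = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    n = len(successes)
    if family == "binomial":
        z = coef / se
        from scipy.stats import norm as norm_dist

        p = 2 * norm_dist.sf(abs(z))
        return {"effect": coef, "stat": z, "p": float(p), "df": np.inf,
                "dispersion": 1.0, "family": family, "fit": fit}
    pearson = float(fit.pearson_chi2) / (n - 2)
    t = coef / (se * np.sqrt(pearson))
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(abs(t), df=n - 2)
    return {"effect": coef, "stat": float(t), "p": float(p), "df": n - 2,
            "dispersion": pearson, "family": family, "fit": fit}


# --------------------------------------------------------------------------
# Ordinal body-condition model
# --------------------------------------------------------------------------


@dataclass
class BCSModel:
    """Fitted proportional-odds model for 1-5 body condition scores."""

    cutpoints: np.ndarray
    coefficients: dict[str, float]
    llf: float
    lr_tests: dict[str, tuple[float, int, float]]  # term -> (LR, df, p)
    herd_sd: float | None = None
    n_obs: int = 0

    def category_probs(self, eta: float) -> np.ndarray:
        cum = expit(self.cutpoints - eta)
        return np.diff(np.r_[0.0, cum, 1.0])


def _expand_bcs(bcs: pd.DataFrame) -> pd.DataFrame:
    """One row per animal (score, category, year, herd) from count columns."""
    rows = []
    for _, r in bcs.iterrows():
        for k in range(1, 6):
            n = int(r[f"bcs_{k}"])
            if n:
                rows.extend(
                    {"score": k, "category": r["category"], "year": r["year"],
                     "herd_id": r["herd_id"]}
                    for _ in range(n)
                )
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame):
    cats = sorted(df["category"].unique())
    years = sorted(df["year"].unique())
    cols = [f"category[{c}]" for c in cats[1:]] + [f"year[{y}]" for y in years[1:]]
    X = np.zeros((len(df), len(cols)))
    for i, c in enumerate(cats[1:]):
        X[:, i] = (df["category"] == c).to_numpy(dtype=float)
    for i, y in enumerate(years[1:]):
        X[:, len(cats) - 1 + i] = (df["year"] == y).to_numpy(dtype=float)
    return X, cols


def _fit_fixed(df: pd.DataFrame, drop: str | None = None):
    """Proportional-odds fit via statsmodels OrderedModel; returns (llf, res, cols)."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X, cols = _design(df)
    keep = [i for i, c in enumerate(cols) if drop is None or not c.startswith(drop)]
    kept = [cols[i] for i in keep]
    observed = sorted(df["score"].unique())
    if len(observed) < 5:
        warnings.warn(
            f"only BCS categories {observed} observed; unobserved ones collapsed",
            stacklevel=2,
        )
    endog = pd.Series(
        pd.Categorical(df["score"], categories=observed, ordered=True), name="score"
    )
    exog = pd.DataFrame(X[:, keep], columns=kept)
    mod = OrderedModel(endog, exog if kept else None, distr="logit")
    res = mod.fit(method="bfgs", disp=False)
    return float(res.llf), res, kept


def bcs_ordinal_fit(
    bcs: pd.DataFrame, random_herd: bool = False
) -> BCSModel:
    """Fit BCS ~ demographic category + year as a cumulative-logit model.

    With ``random_herd`` a herd-level random intercept is integrated out
    by a per-herd Laplace approximation.  Likelihood-ratio tests for the
    category and year terms are computed by term deletion (fixed-effects
    fits in both cases).
    """
    df = _expand_bcs(bcs)
    if df["score"].nunique() < 2:
        raise ValueError("need at least two observed BCS categories")
    if df["year"].nunique() < 2:
        raise ValueError("need at least two years")
    observed = sorted(df["score"].unique())
    llf_full, res_full, cols = _fit_fixed(df)
    lr_tests = {}
    for term, df_term in (("category", df["category"].nunique() - 1),
                          ("year", df["year"].nunique() - 1)):
        llf_red, _, _ = _fit_fixed(df, drop=term)
        lr = 2 * (llf_full - llf_red)
        lr_tests[term] = (lr, df_term, float(chi2_dist.sf(lr, df_term)))

    n_beta = len(cols)
    n_cut = len(observed) - 1
    params = np.asarray(res_full.params)
    beta = params[:n_beta]
    # OrderedModel parameterises thresholds as (t0, log-increments)
    raw = params[n_beta:]
    cutpoints = np.r_[raw[0], raw[0] + np.cumsum(np.exp(raw[1:]))]
    coefs = dict(zip(cols, beta))
    herd_sd = None
    llf = llf_full
    if random_herd:
        cutpoints, coefs, herd_sd, llf = _fit_laplace(
            df, cols, np.r_[cutpoints, beta, np.log(0.3)]
        )
    return BCSModel(
        cutpoints=np.asarray(cutpoints),
        coefficients=coefs,
        llf=llf,
        lr_tests=lr_tests,
        herd_sd=herd_sd,
        n_obs=len(df),
    )


def bcs_loglik(params: np.ndarray, scores: np.ndarray, X: np.ndarray,
               n_cut: int) -> float:
    """Log-likelihood of the fixed-effects proportional-odds model.

    ``params`` is (cutpoints ascending, beta).  Used both by the Laplace
    fit and as an independent objective for cross-checks.
    """
    theta = params[:n_cut]
    if np.any(np.diff(theta) <= 0):
        return -np.inf
    beta = params[n_cut:]
    eta = X @ beta if X.shape[1] else np.zeros(len(X))
    upper = np.where(scores <= n_cut, theta[np.minimum(scores - 1, n_cut - 1)], np.inf)
    lower = np.where(scores >= 2, theta[np.maximum(scores - 2, 0)], -np.inf)
    p = expit(upper - eta) - expit(lower - eta)
    return float(np.sum(np.log(np.maximum(p, 1e-300))))


def _fit_laplace(df, cols, start):
    """Laplace-approximated herd random-intercept fit."""
    X, _ = _design(df)
    scores = df["score"].to_numpy()
    herd_codes, herd_idx = np.unique(df["herd_id"], return_inverse=True)
    n_cut = df["score"].nunique() - 1
    n_beta = X.shape[1]

    def herd_ll(b, theta, beta, rows):
        eta = X[rows] @ beta + b if n_beta else np.full(rows.sum(), b)
        s = scores[rows]
        upper = np.where(s <= n_cut, theta[np.minimum(s - 1, n_cut - 1)], np.inf)
        lower = np.where(s >= 2, theta[np.maximum(s - 2, 0)], -np.inf)
        p = np.maximum(expit(upper - eta) - expit(lower - eta), 1e-300)
        return np.sum(np.log(p))

    def neg_marginal(params):
        theta = params[:n_cut]
        if np.any(np.diff(theta) <= 0):
            return 1e10
        beta = params[n_cut:n_cut + n_beta]
        sigma = np.exp(params[-1])
        total = 0.0
        for h in range(len(herd_codes)):
            rows = herd_idx == h
            grid_obj = lambda b: -(herd_ll(b, theta, beta, rows)
                                   - 0.5 * b**2 / sigma**2)
            from scipy.optimize import minimize_scalar

            opt = minimize_scalar(grid_obj, bounds=(-5 * sigma, 5 * sigma),
                                  method="bounded")
            b_hat = opt.x
            eps = 1e-4
            hess = (grid_obj(b_hat + eps) - 2 * grid_obj(b_hat)
                    + grid_obj(b_hat - eps)) / eps**2
            hess = max(hess, 1e-8)
            total += (-opt.fun - 0.5 * np.log(sigma**2 * hess))
        return -total

    res = minimize(neg_marginal, start, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-4})
    theta = res.x[:n_cut]
    beta = res.x[n_cut:n_cut + n_beta]
    sigma = float(np.exp(res.x[-1]))
    return theta, dict(zip(cols, beta)), sigma, float(-res.fun)
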