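"""Cross-transect model of size-spectrum slope on log10 cPPMR x SST.

Fits ``slope ~ log10_cppmr * sst_c`` with random intercepts for year and for
site nested within year (the lme4 ``(1|Year/Site)`` structure), by REML for
reported fits and ML for model comparisons.  Provides the drop-one
interaction test, fixed-effect trendline predictions across temperatures,
and an AIC comparison over the candidate predictor sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import MixedFit, RandomTerm, fit_mixed

FIXED_NAMES = ["intercept", "log10_cppmr", "sst_c", "log10_cppmr:sst_c"]


@dataclass
class SlopeModelFit:
    """Fitted slope ~ cPPMR x SST mixed model."""

    result: MixedFit
    coefficients: pd.DataFrame  # estimate, se, ci_low, ci_high, p
    site_year_variance: float
    year_variance: float
    residual_variance: float
    icc: float
    n_obs: int
    n_sites: int
    n_years: int
    marginal_r2: float
    conditional_r2: float
    aic: float

    @property
    def singular(self) -> bool:
        return self.result.singular

    @property
    def converged(self) -> bool:
        return self.result.converged


def _design(df: pd.DataFrame, interaction: bool = True,
            predictors: tuple = ("log10_cppmr", "sst_c")):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for p in predictors:
        cols.append(df[p].to_numpy(float))
        names.append(p)
    if interaction and len(predictors) == 2:
        cols.append(
            df[predictors[0]].to_numpy(float)
            * df[predictors[1]].to_numpy(float)
        )
        names.append(f"{predictors[0]}:{predictors[1]}")
    return np.column_stack(cols), names


def _terms(df: pd.DataFrame) -> list[RandomTerm]:
    year = df["year"].astype(str).to_numpy()
    site_in_year = np.char.add(
        np.char.add(year, ":"), df["site"].astype(str).to_numpy()
    )
    return [
        RandomTerm.from_labels("year", year),
        RandomTerm.from_labels("site:year", site_in_year),
    ]


def fit_slope_model(
    data: pd.DataFrame, method: str = "reml"
) -> SlopeModelFit:
    """Fit slope ~ log10_cppmr * sst_c + (1 | year / site).

    ``data`` needs columns slope, log10_cppmr, sst_c, site, year with finite
    values.  Boundary (zero) variance estimates are tolerated and flagged
    singular.  Wald CIs and normal-approximation p-values are reported.
    """
    required = {"slope", "log10_cppmr", "sst_c", "site", "year"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data["site"].nunique() < 2:
        raise ValueError("need >= 2 sites")
    x = data[["log10_cppmr", "sst_c"]].to_numpy(float)
    if not np.all(np.isfinite(x)) or not np.all(
        np.isfinite(data["slope"].to_numpy(float))
    ):
        raise ValueError("slope, log10_cppmr and sst_c must be finite")

    X, names = _design(data)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(
            f"nearly collinear predictors (condition number {cond:.3g})",
            stacklevel=2,
        )
    fit = fit_mixed(
        data["slope"].to_numpy(float), X, _terms(data), method=method,
        fe_names=names,
    )
    tau_year = fit.vc.get("year", 0.0)
    tau_sy = fit.vc.get("site:year", 0.0)
    sigma2 = fit.sigma2
    total = tau_year + tau_sy + sigma2
    icc = (tau_year + tau_sy) / total if total > 0 else 0.0

    var_f = float(np.var(X @ fit.params))
    denom = var_f + tau_year + tau_sy + sigma2
    marg = var_f / denom if denom > 0 else 1.0
    condi = (var_f + tau_year + tau_sy) / denom if denom > 0 else 1.0

    return SlopeModelFit(
        result=fit,
        coefficients=fit.fe_table(),
        site_year_variance=tau_sy,
        year_variance=tau_year,
        residual_variance=sigma2,
        icc=float(icc),
        n_obs=len(data),
        n_sites=int(data["site"].nunique()),
        n_years=int(data["year"].nunique()),
        marginal_r2=marg,
        conditional_r2=condi,
        aic=fit.aic,
    )


def drop_interaction_test(data: pd.DataFrame) -> dict:
    """Likelihood-ratio / AIC test of the cPPMR x SST interaction.

    Both the full and the reduced (additive) model are refit under ML —
    REML likelihoods are not comparable across fixed-effect structures.
    Returns delta AIC (reduced - full) and the chi-square LRT p-value.
    """
    if data["log10_cppmr"].nunique() < 2 or data["sst_c"].nunique() < 2:
        raise ValueError(
            "interaction test needs variation in both predictors"
        )
    y = data["slope"].to_numpy(float)
    terms = _terms(data)
    X_full, n_full = _design(data, interaction=True)
    X_red, n_red = _design(data, interaction=False)
    full = fit_mixed(y, X_full, _terms(data), method="ml", fe_names=n_full)
    red = fit_mixed(y, X_red, terms, method="ml", fe_names=n_red)
    lrt = 2.0 * (full.loglik - red.loglik)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return {
        "aic_full": full.aic,
        "aic_reduced": red.aic,
        "delta_aic": red.aic - full.aic,
        "lrt_stat": float(lrt),
        "p_value": p,
        "interaction_droppable": p >= 0.05,
    }


def predict_trendlines(
    fit: SlopeModelFit,
    sst_values=(15.0, 21.0, 29.0),
    cppmr_grid=None,
    sst_fitted_range: tuple | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effects slope predictions on a log10 cPPMR grid per SST.

    Random effects are set to zero; the CI comes from the fixed-effect
    covariance.  Rows outside the fitted SST range are flagged
    ``extrapolated`` (with a warning) rather than refused.
    """
    if cppmr_grid is None:
        cppmr_grid = np.linspace(2.5, 5.5, 31)
    cppmr_grid = np.asarray(cppmr_grid, dtype=float)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    any_extrap = False
    for sst in sst_values:
        extrap = False
        if sst_fitted_range is not None:
            extrap = not (sst_fitted_range[0] <= sst <= sst_fitted_range[1])
            any_extrap |= extrap
        for lc in cppmr_grid:
            c = np.array([1.0, lc, sst, lc * sst])
            est = float(c @ fit.result.params)
            se = float(np.sqrt(c @ fit.result.cov_params @ c))
            rows.append(
                {
                    "sst_c": sst,
                    "log10_cppmr": lc,
                    "predicted_slope": est,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                    "extrapolated": extrap,
                }
            )
    if any_extrap:
        warnings.warn(
            "some SST values lie outside the fitted range; predictions "
            "flagged as extrapolated",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def compare_predictor_sets(data: pd.DataFrame) -> pd.DataFrame:
    """ML AIC comparison over {cPPMR only, SST only, additive, interaction}.

    All four models are fit on the identical row set with the same random
    structure; the winner (lowest AIC) is flagged.
    """
    if data[["slope", "log10_cppmr", "sst_c"]].isna().any().any():
        raise ValueError("comparison requires a complete, identical row set")
    y = data["slope"].to_numpy(float)
    specs = {
        "cppmr_only": dict(predictors=("log10_cppmr",), interaction=False),
        "sst_only": dict(predictors=("sst_c",), interaction=False),
        "additive": dict(
            predictors=("log10_cppmr", "sst_c"), interaction=False
        ),
        "interaction": dict(
            predictors=("log10_cppmr", "sst_c"), interaction=True
        ),
    }
    rows = []
    for label, spec in specs.items():
        X, names = _design(data, **spec)
        fit = fit_mixed(y, X, _terms(data), method="ml", fe_names=names)
        rows.append({"model": label, "aic": fit.aic, "loglik": fit.loglik})
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["winner"] = table["delta_aic"] == 0.0
    return table.sort_values("aic", kind="mergesort").reset_index(drop=True)


def summary_text(fit: SlopeModelFit) -> str:
    """Human-readable model summary in the layout of a journal table."""
    lines = [
        "Size-spectrum slope ~ log10 cPPMR * mean SST + (1 | Year/Site), REML",
        "",
        f"{'Predictor':<28}{'Estimate':>10}{'CI':>22}{'p':>10}",
    ]
    for name, row in fit.coefficients.iterrows():
        ci = f"{row.ci_low:.2f} - {row.ci_high:.2f}"
        p = "<.001" if row.p < 0.001 else f"{row.p:.3f}"
        lines.append(f"{name:<28}{row.estimate:>10.2f}{ci:>22}{p:>10}")
    lines += [
        "",
        f"sigma^2           {fit.residual_variance:.3f}",
        f"tau00 Site:Year   {fit.site_year_variance:.3f}",
        f"tau00 Year        {fit.year_variance:.3f}",
        f"ICC               {fit.icc:.2f}",
        f"N sites           {fit.n_sites}",
        f"Observations      {fit.n_obs}",
        f"Marginal R2 / Conditional R2   "
        f"{fit.marginal_r2:.3f} / {fit.conditional_r2:.3f}",
    ]
    return "\n".join(lines)
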