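"""Biomass-weighted mixed model of prey mass and PPMR derivation.

The core model regresses log10 individual prey mass on log10 predator mass,
trophic guild, and their interaction, with random intercepts for predator
genus and for individual fish nested within genus, and per-prey biomass
weights (heavier prey contribute more to a predator's energy intake, so they
carry more weight in the fit).  Fitting is by REML.

The predator-prey mass ratio (PPMR) of a predator of mass m in guild T is
``m / m_prey_hat`` where ``m_prey_hat = 10^yhat`` is the model's prey-mass
prediction; predictions can include genus and individual random effects or
fixed effects only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from ._mixed import MixedFit, RandomTerm, fit_mixed
from .prey import GUILDS


class PredictionMode(str, Enum):
    """Which random effects enter a prey-mass prediction."""

    full = "full"  # genus + individual
    genus_only = "genus_only"
    fixed_only = "fixed_only"


def _design(
    log_mass: np.ndarray, guild: np.ndarray, guild_levels: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept, log10 mass, guild offsets (treatment
    coding, first level as reference) and mass x guild interactions."""
    cols = [np.ones(len(log_mass)), log_mass]
    names = ["intercept", "log10_predator_mass"]
    for g in guild_levels[1:]:
        d = (guild == g).astype(float)
        cols.append(d)
        names.append(f"guild[{g}]")
    for g in guild_levels[1:]:
        d = (guild == g).astype(float)
        cols.append(d * log_mass)
        names.append(f"log10_predator_mass:guild[{g}]")
    return np.column_stack(cols), names


@dataclass
class GuildPPMRModel:
    """Fitted guild-level prey-mass model."""

    result: MixedFit
    guild_levels: list[str]
    weight_scheme: str
    random_structure: tuple
    n_obs: int
    n_predators: int
    n_genera: int
    marginal_r2: float
    conditional_r2: float
    coef: dict = field(default_factory=dict)

    @property
    def reference_guild(self) -> str:
        return self.guild_levels[0]

    @property
    def reml_loglik(self) -> float:
        return self.result.loglik

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def residual_variance(self) -> float:
        return self.result.sigma2

    @property
    def vc(self) -> dict:
        return self.result.vc

    def total_slope(self, guild: str) -> float:
        """Per-guild slope of log10 prey mass on log10 predator mass."""
        self._check_guild(guild)
        s = self.coef["log10_predator_mass"]
        if guild != self.reference_guild:
            s += self.coef[f"log10_predator_mass:guild[{guild}]"]
        return float(s)

    def total_slope_ci(self, guild: str, alpha: float = 0.05):
        """Wald CI of the per-guild total slope (linear contrast)."""
        from scipy import stats

        self._check_guild(guild)
        names = self.result.fe_names
        c = np.zeros(len(names))
        c[names.index("log10_predator_mass")] = 1.0
        if guild != self.reference_guild:
            c[names.index(f"log10_predator_mass:guild[{guild}]")] = 1.0
        est = float(c @ self.result.params)
        se = float(np.sqrt(c @ self.result.cov_params @ c))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return est, est - z * se, est + z * se

    def guild_intercept(self, guild: str) -> float:
        self._check_guild(guild)
        b = self.coef["intercept"]
        if guild != self.reference_guild:
            b += self.coef[f"guild[{guild}]"]
        return float(b)

    def _check_guild(self, guild: str) -> None:
        if guild not in self.guild_levels:
            raise ValueError(
                f"unknown guild {guild!r}; model fitted on {self.guild_levels}"
            )

    def to_json(self) -> str:
        payload = {
            "coefficients": self.coef,
            "guild_levels": self.guild_levels,
            "reference_guild": self.reference_guild,
            "random_structure": list(self.random_structure),
            "variance_components": self.vc,
            "residual_variance": self.residual_variance,
            "weight_scheme": self.weight_scheme,
            "n_obs": self.n_obs,
            "n_predators": self.n_predators,
            "n_genera": self.n_genera,
            "reml_loglik": self.reml_loglik,
            "aic": self.aic,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "total_slopes": {
                g: self.total_slope(g) for g in self.guild_levels
            },
        }
        return json.dumps(payload, indent=2)

    def coef_table(self) -> pd.DataFrame:
        return self.result.fe_table()


_TERM_COLUMNS = {"genus": "genus", "individual": "predator_id"}


def fit_ppmr_model(
    data: pd.DataFrame,
    weight_scheme: str = "normalized",
    random_structure: tuple = ("genus", "individual"),
    method: str = "reml",
) -> GuildPPMRModel:
    """Fit the biomass-weighted prey-mass mixed model.

    ``data`` needs columns predator_id, genus, guild, predator_mass_g,
    wet_mass_g and (unless recomputed here) weight.  Guild offsets use the
    alphabetically first guild present as reference; per-guild total slopes
    are reference-invariant and exposed via :meth:`GuildPPMRModel.total_slope`.
    """
    required = {"predator_id", "genus", "guild", "predator_mass_g",
                "wet_mass_g"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    guild_levels = sorted(data["guild"].unique())
    if len(guild_levels) < 2:
        raise ValueError("need >= 2 guilds to fit guild contrasts")
    if data["genus"].nunique() < 2:
        raise ValueError("need >= 2 genera for the genus random intercept")

    if weight_scheme == "none":
        weights = None
    elif weight_scheme in ("raw", "normalized"):
        if "weight" in data.columns:
            weights = data["weight"].to_numpy(float)
        else:
            weights = data["wet_mass_g"].to_numpy(float)
        if weight_scheme == "normalized":
            totals = data.groupby("predator_id")["wet_mass_g"].transform("sum")
            weights = data["wet_mass_g"].to_numpy(float) / totals.to_numpy(float)
    else:
        raise ValueError("weight_scheme must be 'raw', 'normalized' or 'none'")

    y = np.log10(data["wet_mass_g"].to_numpy(float))
    log_mass = np.log10(data["predator_mass_g"].to_numpy(float))
    guild = data["guild"].to_numpy()
    X, names = _design(log_mass, guild, guild_levels)

    terms = []
    for t in random_structure:
        col = _TERM_COLUMNS.get(t, t)
        if col not in data.columns:
            raise ValueError(f"random term {t!r}: column {col!r} missing")
        terms.append(RandomTerm.from_labels(t, data[col].to_numpy()))
    if not terms:
        raise ValueError("at least one random term is required")

    fit = fit_mixed(y, X, terms, weights=weights, method=method,
                    fe_names=names)

    marg, cond = nakagawa_r2(fit, X)
    coef = dict(zip(names, (float(v) for v in fit.params)))
    return GuildPPMRModel(
        result=fit,
        guild_levels=guild_levels,
        weight_scheme=weight_scheme,
        random_structure=tuple(random_structure),
        n_obs=len(data),
        n_predators=int(data["predator_id"].nunique()),
        n_genera=int(data["genus"].nunique()),
        marginal_r2=marg,
        conditional_r2=cond,
        coef=coef,
    )


def nakagawa_r2(fit: MixedFit, X: np.ndarray) -> tuple[float, float]:
    """Marginal and conditional R^2 for a mixed model.

    Marginal: fixed-effect variance over total (fixed + random + residual);
    conditional adds the random-intercept variances to the numerator.
    """
    var_f = float(np.var(X @ fit.params))
    var_r = float(sum(fit.vc.values()))
    total = var_f + var_r + fit.sigma2
    if total <= 0:
        return 1.0, 1.0
    return var_f / total, (var_f + var_r) / total


def compare_random_structures(
    data: pd.DataFrame,
    candidates: dict,
    weight_scheme: str = "normalized",
    method: str = "reml",
) -> pd.DataFrame:
    """Fit candidate random structures under identical fixed effects.

    ``candidates`` maps a label to a tuple of random terms, e.g.
    ``{"genus_only": ("genus",), "genus/id": ("genus", "individual")}``.
    Returns a table sorted by AIC with a ``delta_aic`` column; failed fits
    are retained with NaN AIC and the error message, never dropped silently.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate structure")
    rows = []
    for label, spec in candidates.items():
        try:
            m = fit_ppmr_model(
                data, weight_scheme=weight_scheme,
                random_structure=tuple(spec), method=method,
            )
            rows.append(
                {
                    "structure": label,
                    "terms": "+".join(spec),
                    "aic": m.aic,
                    "loglik": m.reml_loglik,
                    "converged": m.result.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # recorded as non-comparable
            rows.append(
                {
                    "structure": label,
                    "terms": "+".join(spec),
                    "aic": np.nan,
                    "loglik": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        "aic", na_position="last", kind="mergesort"
    )
    # degenerate (noise-free) fits share AIC = -inf; their difference is 0
    a = table["aic"].to_numpy()
    mn = np.nanmin(a)
    with np.errstate(invalid="ignore"):
        table["delta_aic"] = np.where(a == mn, 0.0, a - mn)
    return table.reset_index(drop=True)


def predict_prey_mass(
    model: GuildPPMRModel,
    predator_mass_g,
    guild: str,
    mode: PredictionMode = PredictionMode.fixed_only,
    genus: str | None = None,
    individual: str | None = None,
    lognormal_correction: bool = False,
) -> np.ndarray:
    """Predict prey wet mass (g) for predators of given mass and guild.

    ``mode`` selects which random effects enter the linear predictor; the
    required identifiers must be known to the fitted model (no silent
    fall-back to zero).  The back-transform is naive ``10^yhat`` unless
    ``lognormal_correction`` adds half the residual variance (log10 scale).
    """
    mode = PredictionMode(mode)
    m = np.atleast_1d(np.asarray(predator_mass_g, dtype=float))
    if np.any(m <= 0):
        raise ValueError("predator mass must be positive")
    model._check_guild(guild)
    yhat = model.guild_intercept(guild) + model.total_slope(guild) * np.log10(m)
    if mode in (PredictionMode.full, PredictionMode.genus_only):
        if genus is None:
            raise ValueError(f"mode {mode.value!r} requires a genus")
        re_g = model.result.ranef.get("genus")
        if re_g is None or genus not in re_g.index:
            raise ValueError(f"genus {genus!r} unknown to the fitted model")
        yhat = yhat + float(re_g[genus])
    if mode is PredictionMode.full:
        if individual is None:
            raise ValueError("mode 'full' requires an individual id")
        re_i = model.result.ranef.get("individual")
        if re_i is None or individual not in re_i.index:
            raise ValueError(
                f"individual {individual!r} unknown to the fitted model"
            )
        yhat = yhat + float(re_i[individual])
    if lognormal_correction:
        yhat = yhat + 0.5 * np.log(10.0) * model.residual_variance
    out = 10.0**yhat
    return out if np.ndim(predator_mass_g) else float(out[0])


def compute_ppmr(
    model: GuildPPMRModel,
    predator_mass_g,
    guild: str,
    mode: PredictionMode = PredictionMode.fixed_only,
    genus: str | None = None,
    individual: str | None = None,
):
    """Predator-prey mass ratio: predator mass / predicted prey mass.

    Oriented so typical fish values are >> 1.  Strictly positive by
    construction (the prey-mass prediction is an exponential).
    """
    pred = predict_prey_mass(
        model, predator_mass_g, guild, mode=mode, genus=genus,
        individual=individual,
    )
    return np.asarray(predator_mass_g, dtype=float) / pred if np.ndim(
        predator_mass_g
    ) else float(predator_mass_g) / pred
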