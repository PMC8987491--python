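"""Parameter-recovery protocols.

Simulation studies that generate data with the field-reported estimates as truth
and refit the corresponding model: per-guild prey-mass slopes from the
biomass-weighted gut-content model, and the fixed effects of the
slope ~ log10 cPPMR x SST mixed model.  Used by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ppmr, prey, slopes, synthetic
from .synthetic import GutGenConfig, SurveyGenConfig

SLOPE_COEF_NAMES = ("intercept", "log10_cppmr", "sst_c", "log10_cppmr:sst_c")


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(2**31, size=n)


def guild_slope_recovery(
    n_replicates: int = 20, seed: int = 0, **config_kwargs
) -> pd.DataFrame:
    """Refit the guild model on synthetic gut data over seeded replicates.

    Each replicate generates gut contents with the generator's default guild
    slopes as truth, processes prey (conversion, filtering, weights) and
    refits the weighted mixed model.  Returns one row per replicate x guild
    with the total-slope estimate, its 95% CI and the truth.
    """
    rows = []
    for rep, s in enumerate(_replicate_seeds(seed, n_replicates)):
        cfg = GutGenConfig(seed=int(s), **config_kwargs)
        samples, truth = synthetic.gen_gut_dataset(cfg)
        gut = synthetic.gut_samples_to_frame(samples)
        allo = pd.DataFrame(truth["allometry"])
        processed, _ = prey.process_gut_frame(gut, allo)
        model = ppmr.fit_ppmr_model(processed)
        for guild in prey.GUILDS:
            est, lo, hi = model.total_slope_ci(guild)
            rows.append(
                {
                    "replicate": rep,
                    "guild": guild,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "truth": cfg.fixed_effects[guild][1],
                }
            )
    return pd.DataFrame(rows)


def slope_model_recovery(
    n_replicates: int = 20, seed: int = 0, **config_kwargs
) -> pd.DataFrame:
    """Refit the slope ~ cPPMR x SST model on synthetic transects.

    Each replicate generates transect slopes from the generator's default
    linear predictor (with site-within-year, year and residual noise) and
    refits by REML.  Returns one row per replicate x coefficient.
    """
    truths = None
    rows = []
    for rep, s in enumerate(_replicate_seeds(seed, n_replicates)):
        cfg = SurveyGenConfig(seed=int(s), **config_kwargs)
        truths = dict(zip(SLOPE_COEF_NAMES, cfg.coefficients))
        _, slope_df, _ = synthetic.gen_survey_dataset(cfg)
        fit = slopes.fit_slope_model(slope_df)
        for name in SLOPE_COEF_NAMES:
            rows.append(
                {
                    "replicate": rep,
                    "coefficient": name,
                    "estimate": fit.coefficients.loc[name, "estimate"],
                    "ci_low": fit.coefficients.loc[name, "ci_low"],
                    "ci_high": fit.coefficients.loc[name, "ci_high"],
                    "truth": truths[name],
                }
            )
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Mean estimate, bias and CI coverage per parameter."""
    def agg(g):
        return pd.Series(
            {
                "mean_estimate": g["estimate"].mean(),
                "truth": g["truth"].iloc[0],
                "bias": g["estimate"].mean() - g["truth"].iloc[0],
                "coverage": (
                    (g["ci_low"] <= g["truth"]) & (g["truth"] <= g["ci_high"])
                ).mean(),
            }
        )

    return table.groupby(by).apply(agg, include_groups=False)
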