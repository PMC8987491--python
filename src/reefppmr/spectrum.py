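"""Abundance size spectra and energetic-equivalence theory.

A community's abundance size spectrum is the log-log relationship between
body-mass class and the number of individuals in that class; its slope is
the abundance counterpart (b - 1) of the biomass spectrum slope b.  Under
energetic equivalence with trophic-transfer correction, the biomass slope is

    b = 0.25 + log(TE) / log(cPPMR),

where TE in (0, 1] is the trophic transfer efficiency, cPPMR > 1 the
community predator-prey mass ratio, and 0.25 the metabolic mass-scaling
exponent.  With the conventional TE ~ 0.1 and cPPMR ~ 10^4 this gives b = 0,
i.e. abundance declining with slope -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

METABOLIC_EXPONENT = 0.25


@dataclass
class TheoryParams:
    """Inputs of the energetic-equivalence slope prediction."""

    te: float
    cppmr: float
    metabolic_exponent: float = METABOLIC_EXPONENT

    def __post_init__(self):
        if not (0.0 < self.te <= 1.0):
            raise ValueError("TE must lie in (0, 1]")
        if self.cppmr <= 1.0:
            raise ValueError("cPPMR must exceed 1 (slope undefined at 1)")


@dataclass
class SpectrumFit:
    """Per-transect abundance size-spectrum fit (slope is b - 1)."""

    transect_id: str
    slope: float
    intercept: float
    n_bins_used: int
    r2: float
    bin_edges: np.ndarray

    @property
    def valid(self) -> bool:
        return self.n_bins_used >= 2 and np.isfinite(self.slope)


def bin_individuals(
    masses, abundances=None, min_mass_g: float | None = None
) -> pd.DataFrame:
    """Bin individuals into log2 doubling body-mass classes.

    Half-open bins [2^k, 2^(k+1)) g; each individual falls in exactly one
    bin and empty bins are omitted.  ``abundances`` gives counts per mass
    entry (default 1 each); ``min_mass_g`` optionally truncates the smallest
    classes.  Returns columns bin_low, bin_high, mid_mass_g (geometric
    midpoint) and abundance.
    """
    m = np.asarray(masses, dtype=float)
    if abundances is None:
        n = np.ones_like(m)
    else:
        n = np.asarray(abundances, dtype=float)
        if n.shape != m.shape:
            raise ValueError("masses and abundances must align")
    if min_mass_g is not None:
        keep = m >= min_mass_g
        m, n = m[keep], n[keep]
    keep = n > 0
    m, n = m[keep], n[keep]
    if m.size == 0 or np.any(m <= 0):
        raise ValueError("need positive masses with positive abundance")
    k = np.floor(np.log2(m)).astype(int)
    table = (
        pd.DataFrame({"k": k, "abundance": n})
        .groupby("k", sort=True)["abundance"]
        .sum()
        .reset_index()
    )
    table["bin_low"] = 2.0 ** table["k"]
    table["bin_high"] = 2.0 ** (table["k"] + 1)
    table["mid_mass_g"] = np.sqrt(table["bin_low"] * table["bin_high"])
    return table[["bin_low", "bin_high", "mid_mass_g", "abundance"]]


def fit_spectrum_slope(
    binned: pd.DataFrame, transect_id: str = ""
) -> SpectrumFit:
    """OLS of log10 abundance on log10 bin-midpoint mass.

    The fitted slope is the abundance spectrum slope (b - 1).  Fewer than
    two occupied bins gives an invalid (NaN) fit, flagged via ``valid``.
    """
    occ = binned[binned["abundance"] > 0]
    edges = np.concatenate(
        [occ["bin_low"].to_numpy(), occ["bin_high"].to_numpy()[-1:]]
    ) if len(occ) else np.array([])
    if len(occ) < 2:
        return SpectrumFit(
            transect_id=transect_id, slope=np.nan, intercept=np.nan,
            n_bins_used=len(occ), r2=np.nan, bin_edges=edges,
        )
    x = np.log10(occ["mid_mass_g"].to_numpy(float))
    y = np.log10(occ["abundance"].to_numpy(float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SpectrumFit(
        transect_id=transect_id,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_bins_used=len(occ),
        r2=float(res.rsquared) if len(occ) > 2 else 1.0,
        bin_edges=edges,
    )


def survey_spectrum_slopes(
    survey_with_mass: pd.DataFrame, min_mass_g: float | None = None
) -> pd.DataFrame:
    """Per-transect spectrum slopes from a survey table with body masses."""
    rows = []
    for tid, grp in survey_with_mass.groupby("transect_id", sort=True):
        binned = bin_individuals(
            grp["body_mass_g"].to_numpy(),
            grp["abundance"].to_numpy(),
            min_mass_g=min_mass_g,
        )
        fit = fit_spectrum_slope(binned, transect_id=str(tid))
        rows.append(
            {
                "transect_id": tid,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "n_bins_used": fit.n_bins_used,
                "r2": fit.r2,
                "valid": fit.valid,
            }
        )
    return pd.DataFrame(rows)


def theory_predict_b(params: TheoryParams) -> tuple[float, float]:
    """Energetic-equivalence slope prediction.

    Returns ``(b, b - 1)``: the biomass spectrum slope and the equivalent
    abundance spectrum slope.  The log ratio is base-independent.
    """
    b = params.metabolic_exponent + np.log(params.te) / np.log(params.cppmr)
    return float(b), float(b - 1.0)


def theory_invert(
    b: float,
    te: float | None = None,
    cppmr: float | None = None,
    metabolic_exponent: float = METABOLIC_EXPONENT,
) -> float:
    """Solve the slope relation for TE or cPPMR given the other.

    Exactly one of ``te`` / ``cppmr`` must be supplied; returns the other.
    Raises on parameter combinations whose solution leaves the valid domain
    (TE in (0, 1], cPPMR > 1).
    """
    if (te is None) == (cppmr is None):
        raise ValueError("supply exactly one of te or cppmr")
    d = b - metabolic_exponent
    if te is not None:
        if not (0.0 < te <= 1.0):
            raise ValueError("TE must lie in (0, 1]")
        if te == 1.0:
            raise ValueError("TE = 1 forces b = 0.25 for every cPPMR; "
                             "cPPMR is unidentifiable")
        if d >= 0:
            raise ValueError(
                f"b = {b} with TE = {te} < 1 would require cPPMR <= 1 "
                "(out of domain)"
            )
        return float(np.exp(np.log(te) / d))
    if cppmr <= 1.0:
        raise ValueError("cPPMR must exceed 1")
    te_out = float(np.exp(d * np.log(cppmr)))
    if not (0.0 < te_out <= 1.0):
        raise ValueError(
            f"b = {b} with cPPMR = {cppmr} implies TE = {te_out:.3g} "
            "outside (0, 1]"
        )
    return te_out
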