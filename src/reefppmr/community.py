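"""Community-level PPMR: guild consolidation, per-transect aggregation,
and sensitivity tools.

Survey fish arrive classified into nine fine trophic guilds; these are
consolidated into four (herbivore, invertivore, planktivore, piscivore).
Cleaner fish and non-fish predators (marine mammals, reptiles, birds) are
excluded with an explicit reason.  Each surveyed individual's PPMR is
predicted from its guild and body mass (fixed effects only), and the
community PPMR of a transect is the abundance-weighted arithmetic mean of
those individual PPMRs over guild x size-class groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ppmr import GuildPPMRModel, PredictionMode, compute_ppmr
from .prey import GUILDS

EXCLUDED = "excluded"

#: Fine-guild vocabulary -> consolidated guild (or excluded).  Keys are
#: normalized to lower case with single spaces.
GUILD_CONSOLIDATION = {
    "algal farmers": "herbivore",
    "browsing herbivores": "herbivore",
    "scraping herbivores": "herbivore",
    "excavators": "herbivore",
    "benthic invertivores": "invertivore",
    "omnivores": "invertivore",
    "corallivores": "invertivore",
    "higher carnivores": "piscivore",
    "planktivores": "planktivore",
    # exclusions
    "cleaner": EXCLUDED,
    "cleaners": EXCLUDED,
    "marine mammal": EXCLUDED,
    "marine mammals": EXCLUDED,
    "reptile": EXCLUDED,
    "reptiles": EXCLUDED,
    "bird": EXCLUDED,
    "birds": EXCLUDED,
}
# already-consolidated labels map to themselves
GUILD_CONSOLIDATION.update({g: g for g in GUILDS})


def consolidate_guild(raw_guild: str) -> str:
    """Map a fine trophic guild label to one of the four consolidated
    guilds, or ``"excluded"`` for cleaners and non-fish predators."""
    key = " ".join(str(raw_guild).strip().lower().replace("_", " ").split())
    try:
        return GUILD_CONSOLIDATION[key]
    except KeyError:
        raise ValueError(
            f"unknown guild label {raw_guild!r}; known labels: "
            f"{sorted(set(GUILD_CONSOLIDATION))}"
        ) from None


def size_class_to_mass(size_class_cm, lw_a, lw_b):
    """Wet body mass (g) from a length size class (cm, class midpoint) via
    the species' length-weight allometry mass = a * length^b."""
    length = np.asarray(size_class_cm, dtype=float)
    a = np.asarray(lw_a, dtype=float)
    b = np.asarray(lw_b, dtype=float)
    if np.any(length <= 0):
        raise ValueError("size class lengths must be positive")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)) or np.any(a <= 0):
        raise ValueError("length-weight coefficients missing or non-positive")
    out = a * length**b
    return out if np.ndim(size_class_cm) else float(out)


@dataclass
class CommunityPPMR:
    """Per-transect community PPMR summary."""

    transect_id: str
    cppmr: float
    log10_cppmr: float
    n_individuals: int
    guild_shares: dict


def prepare_survey(survey: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consolidate guilds and derive body masses for a survey table.

    Returns (records, audit): excluded rows land in ``audit`` with a reason,
    never silently dropped.
    """
    df = survey.copy()
    df["guild"] = [consolidate_guild(g) for g in df["guild"]]
    excluded = df[df["guild"] == EXCLUDED].copy()
    excluded["exclusion_reason"] = "cleaner_or_non_fish"
    df = df[df["guild"] != EXCLUDED].copy()
    df["body_mass_g"] = size_class_to_mass(
        df["size_class_cm"].to_numpy(),
        df["lw_a"].to_numpy(),
        df["lw_b"].to_numpy(),
    )
    return df, excluded


def transect_cppmr(
    records: pd.DataFrame, model: GuildPPMRModel, mean: str = "arithmetic"
) -> CommunityPPMR:
    """Community PPMR of one transect.

    cPPMR = sum over guild x size groups of PPMR(guild, mass) * N, divided by
    total N — the abundance-weighted arithmetic mean of individual PPMRs,
    with PPMR predicted from fixed effects only.  ``mean="geometric"``
    averages on the log scale instead (comparison option; the arithmetic
    mean is the definition used downstream).
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    tids = records["transect_id"].unique()
    if len(tids) != 1:
        raise ValueError("records must belong to a single transect")
    if "body_mass_g" not in records.columns:
        records = prepare_survey(records)[0]
    total_n = records["abundance"].sum()
    if total_n <= 0:
        raise ValueError(f"transect {tids[0]}: zero total abundance")
    ppmr = np.array(
        [
            compute_ppmr(model, m, g, mode=PredictionMode.fixed_only)
            for m, g in zip(records["body_mass_g"], records["guild"])
        ]
    )
    n = records["abundance"].to_numpy(float)
    if mean == "geometric":
        cppmr = float(10.0 ** (np.sum(np.log10(ppmr) * n) / np.sum(n)))
    else:
        cppmr = float(np.sum(ppmr * n) / np.sum(n))
    shares = (
        records.groupby("guild")["abundance"].sum() / total_n
    ).to_dict()
    return CommunityPPMR(
        transect_id=str(tids[0]),
        cppmr=cppmr,
        log10_cppmr=float(np.log10(cppmr)),
        n_individuals=int(total_n),
        guild_shares=shares,
    )


def survey_cppmr_table(
    survey: pd.DataFrame, model: GuildPPMRModel
) -> pd.DataFrame:
    """Per-transect cPPMR for a whole survey table."""
    records, _ = prepare_survey(survey)
    rows = []
    for tid, grp in records.groupby("transect_id", sort=True):
        c = transect_cppmr(grp, model)
        first = grp.iloc[0]
        rows.append(
            {
                "transect_id": tid,
                "site": first["site"],
                "year": first["year"],
                "sst_c": first["sst_c"],
                "cppmr": c.cppmr,
                "log10_cppmr": c.log10_cppmr,
                "n_individuals": c.n_individuals,
            }
        )
    return pd.DataFrame(rows)


def guild_exclusion_sensitivity(
    records: pd.DataFrame, model: GuildPPMRModel
) -> pd.DataFrame:
    """Recompute a transect's cPPMR with each guild dropped in turn.

    Returns one row per dropped guild plus the all-guilds baseline, with the
    relative change.  Dropping the only guild present yields an undefined
    (NaN) cPPMR, not zero.
    """
    if "body_mass_g" not in records.columns:
        records = prepare_survey(records)[0]
    present = sorted(records["guild"].unique())
    if len(present) < 2:
        raise ValueError("sensitivity needs >= 2 guilds on the transect")
    base = transect_cppmr(records, model)
    rows = [
        {
            "dropped_guild": "(none)",
            "cppmr": base.cppmr,
            "relative_change": 0.0,
        }
    ]
    for g in GUILDS:
        sub = records[records["guild"] != g]
        if sub["abundance"].sum() <= 0:
            rows.append(
                {"dropped_guild": g, "cppmr": np.nan,
                 "relative_change": np.nan}
            )
            continue
        c = transect_cppmr(sub, model)
        rows.append(
            {
                "dropped_guild": g,
                "cppmr": c.cppmr,
                "relative_change": (c.cppmr - base.cppmr) / base.cppmr,
            }
        )
    return pd.DataFrame(rows)


def trim_percentiles(
    communities: pd.DataFrame,
    lower: float = 0.01,
    upper: float = 0.99,
    column: str = "cppmr",
) -> tuple[pd.DataFrame, int]:
    """Drop communities with extreme cPPMR.

    Removes rows strictly below the ``lower`` and strictly above the
    ``upper`` empirical quantile (linear-interpolation definition) of
    ``column``.  Returns the retained rows and the count removed.
    """
    if len(communities) < 3:
        raise ValueError("need >= 3 communities to trim percentiles")
    x = communities[column].to_numpy(float)
    lo = np.quantile(x, lower)
    hi = np.quantile(x, upper)
    keep = (x >= lo) & (x <= hi)
    return communities[keep].copy(), int((~keep).sum())
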