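"""Synthetic data generators with known ground truth.

Every downstream stage (prey processing, the biomass-weighted guild model,
community aggregation, spectrum fitting, the slope ~ cPPMR x SST model) gets
a parameter-recovery test against data generated here.  The generators draw
from exactly the hierarchical structures the statistical models assume:

* gut contents: log10 prey mass linear in log10 predator mass per guild,
  with genus- and individual-level random intercepts and residual noise,
  lengths back-computed through an invertible toy allometry and censored at
  the guild's minimum measurable length;
* transect surveys: per-transect size-spectrum slopes formed from a linear
  predictor in log10 community PPMR and sea-surface temperature with
  year and site-within-year random intercepts, plus a guild x size-class
  abundance table consistent with each transect's slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prey import GUILDS, MIN_PREY_LENGTH_MM, PreyItem

# Per-guild truths for the prey-mass model (log10 scale).  Slopes are the
# field-estimated guild values; intercepts are free parameters chosen so that
# fixed-effect PPMRs at mid-range guild masses sit at the reported magnitudes
# (herbivores/planktivores ~1e4-1e5, piscivores lowest).
DEFAULT_FIXED_EFFECTS = {
    "herbivore": (-3.5, 0.11),
    "invertivore": (-3.2, 0.68),
    "planktivore": (-4.1, 0.47),
    "piscivore": (-6.0, 2.22),
}

DEFAULT_MASS_RANGES = {
    "herbivore": (10.0, 2000.0),
    "invertivore": (5.0, 3000.0),
    "planktivore": (1.97, 500.0),
    "piscivore": (20.0, 7878.0),
}

#: Guild composition of a typical invertivore-dominated reef community.
DEFAULT_GUILD_SHARES = {
    "herbivore": 0.20,
    "invertivore": 0.45,
    "planktivore": 0.25,
    "piscivore": 0.10,
}


@dataclass
class GutGenConfig:
    """Configuration for the gut-content generator."""

    n_predators_per_guild: int = 80
    mass_range_g: dict = field(
        default_factory=lambda: dict(DEFAULT_MASS_RANGES)
    )
    fixed_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    genus_sd: float = 0.3
    individual_sd: float = 0.3
    residual_sd: float = 0.5
    n_genera_per_guild: int = 8
    prey_mean: float = 10.0
    prey_dispersion: float = 5.0
    prey_max: int = 200
    min_prey_mm: dict = field(
        default_factory=lambda: dict(MIN_PREY_LENGTH_MM)
    )
    n_taxa: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_predators_per_guild <= 0:
            raise ValueError("n_predators_per_guild must be positive")
        if self.n_genera_per_guild <= 0:
            raise ValueError("n_genera_per_guild must be positive")
        if self.prey_mean <= 0 or self.prey_dispersion <= 0:
            raise ValueError("prey count parameters must be positive")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        for sd in (self.genus_sd, self.individual_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if set(self.fixed_effects) != set(GUILDS):
            raise ValueError(f"fixed_effects must cover exactly {GUILDS}")
        if set(self.mass_range_g) != set(GUILDS):
            raise ValueError(f"mass_range_g must cover exactly {GUILDS}")
        for lo, hi in self.mass_range_g.values():
            if lo <= 0 or hi <= lo:
                raise ValueError("mass ranges must be positive with hi > lo")


@dataclass
class SurveyGenConfig:
    """Configuration for the transect-survey generator."""

    n_sites: int = 200
    n_years: int = 5
    transects_per_site: int = 8
    n_transects: int | None = 1500
    sst_range_c: tuple = (14.0, 28.0)
    #: (intercept, log10 cPPMR, SST, interaction) of the slope predictor.
    coefficients: tuple = (1.67, -0.40, -0.13, 0.03)
    site_year_variance: float = 0.02
    year_variance: float = 0.00
    residual_variance: float = 0.03
    cppmr_log10_loc: float = 3.9
    cppmr_log10_scale: float = 0.4
    individuals_per_transect: float = 200.0
    seed: int = 0

    def __post_init__(self):
        n = self.n_transects
        if n is None:
            n = self.n_sites * self.transects_per_site
        if n <= 0 or self.n_sites <= 0 or self.n_years <= 0:
            raise ValueError("transect, site and year counts must be positive")
        for v in (
            self.site_year_variance,
            self.year_variance,
            self.residual_variance,
        ):
            if v < 0:
                raise ValueError("variances must be >= 0")
        lo, hi = self.sst_range_c
        if not (0.0 <= lo < hi <= 40.0):
            raise ValueError("SST range must lie within (0, 40) C")

    @property
    def total_transects(self) -> int:
        if self.n_transects is not None:
            return self.n_transects
        return self.n_sites * self.transects_per_site


@dataclass
class PredatorSample:
    """One dissected fish and its measured prey items."""

    predator_id: str
    species: str
    genus: str
    guild: str
    wet_mass_g: float
    prey: list = field(default_factory=list)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out to independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _zt_negbin(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Zero-truncated negative binomial counts (field prey counts are
    overdispersed and a sampled gut contains at least one prey)."""
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(dispersion, p, size=int(zero.sum()))
        zero = out == 0
    return out


def gen_length_weight_table(
    n_taxa: int, seed: int = 0, dry_fraction: float = 0.3
) -> pd.DataFrame:
    """Generate a per-taxon length-weight allometry table.

    Coefficients are for mass (g) from length (mm); roughly cubic scaling
    with realistic shape variation.  A fraction of taxa are dry-weight
    conversions carrying an explicit dry-to-wet factor (wet = factor * dry).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    a = 10.0 ** rng.uniform(-5.5, -4.5, size=n_taxa)
    b = rng.uniform(2.7, 3.3, size=n_taxa)
    dry = rng.random(n_taxa) < dry_fraction
    factor = np.where(dry, rng.uniform(3.0, 7.0, size=n_taxa), 1.0)
    return pd.DataFrame(
        {
            "taxon": [f"taxon_{i:02d}" for i in range(n_taxa)],
            "a": a,
            "b": b,
            "length_unit": "mm",
            "dry_flag": dry,
            "dry_to_wet_factor": factor,
        }
    )


def gen_gut_dataset(
    config: GutGenConfig, allometry: pd.DataFrame | None = None
) -> tuple[list[PredatorSample], dict]:
    """Generate gut-content samples with known ground truth.

    Prey log10 masses are drawn from the per-guild fixed-effect line plus
    genus, individual and residual noise.  Lengths are back-computed through
    the (invertible) allometry of a randomly assigned taxon, then censored:
    prey at or below the guild's minimum measurable length are dropped
    (truncation after drawing, mimicking the field measurement cutoff).

    Returns the predator samples and a truth record holding every drawn
    effect, the allometry used, and censoring counts.
    """
    rng_allo, rng_main = _child_rngs(config.seed, 2)
    if allometry is None:
        allometry = gen_length_weight_table(
            config.n_taxa, seed=int(rng_allo.integers(2**31))
        )
    allo = allometry.set_index("taxon")

    samples: list[PredatorSample] = []
    genus_effects: dict[str, float] = {}
    individual_effects: dict[str, float] = {}
    n_censored = 0

    taxa = allo.index.to_numpy()
    for guild in GUILDS:
        b0, b1 = config.fixed_effects[guild]
        lo, hi = config.mass_range_g[guild]
        genera = [f"{guild[:4].capitalize()}genus{i}" for i in range(
            config.n_genera_per_guild)]
        for g in genera:
            genus_effects[g] = float(rng_main.normal(0.0, config.genus_sd))
        n_prey = _zt_negbin(
            rng_main, config.prey_mean, config.prey_dispersion,
            config.n_predators_per_guild,
        )
        n_prey = np.minimum(n_prey, config.prey_max)
        min_mm = config.min_prey_mm[guild]
        for j in range(config.n_predators_per_guild):
            pid = f"{guild[:4]}_p{j:03d}"
            genus = genera[int(rng_main.integers(len(genera)))]
            mass = 10.0 ** rng_main.uniform(np.log10(lo), np.log10(hi))
            ind_eff = float(rng_main.normal(0.0, config.individual_sd))
            individual_effects[pid] = ind_eff
            sample = PredatorSample(
                predator_id=pid,
                species=f"{genus} sp{j % 3}",
                genus=genus,
                guild=guild,
                wet_mass_g=float(mass),
            )
            k = int(n_prey[j])
            y = (
                b0
                + b1 * np.log10(mass)
                + genus_effects[genus]
                + ind_eff
                + rng_main.normal(0.0, config.residual_sd, size=k)
            )
            prey_taxa = taxa[rng_main.integers(len(taxa), size=k)]
            for i in range(k):
                rule = allo.loc[prey_taxa[i]]
                wet = 10.0 ** y[i]
                eff_a = rule["a"] * (
                    rule["dry_to_wet_factor"] if rule["dry_flag"] else 1.0
                )
                length_mm = (wet / eff_a) ** (1.0 / rule["b"])
                if rule["length_unit"] == "cm":
                    length_mm *= 10.0
                if length_mm <= min_mm:  # measurement censoring
                    n_censored += 1
                    continue
                sample.prey.append(
                    PreyItem(
                        prey_id=f"{pid}_{i}",
                        predator_id=pid,
                        taxon=str(prey_taxa[i]),
                        length_mm=float(length_mm),
                        wet_mass_g=wet,
                        weight=wet,
                    )
                )
            samples.append(sample)

    truth = {
        "fixed_effects": {g: list(config.fixed_effects[g]) for g in GUILDS},
        "genus_sd": config.genus_sd,
        "individual_sd": config.individual_sd,
        "residual_sd": config.residual_sd,
        "genus_effects": genus_effects,
        "individual_effects": individual_effects,
        "n_censored": n_censored,
        "allometry": allometry.to_dict(orient="records"),
        "seed": config.seed,
    }
    return samples, truth


def gut_samples_to_frame(samples: list[PredatorSample]) -> pd.DataFrame:
    """Flatten predator samples to the gut-content table layout."""
    rows = []
    for s in samples:
        for it in s.prey:
            rows.append(
                {
                    "predator_id": s.predator_id,
                    "species": s.species,
                    "genus": s.genus,
                    "guild": s.guild,
                    "predator_mass_g": s.wet_mass_g,
                    "prey_taxon": it.taxon,
                    "prey_length_mm": it.length_mm,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "predator_id", "species", "genus", "guild", "predator_mass_g",
            "prey_taxon", "prey_length_mm",
        ],
    )


#: Survey size classes: lengths (cm) spaced so successive classes double in
#: body mass under the cubic length-weight rule used for survey fish.
SURVEY_LENGTH_CLASSES_CM = tuple(
    round(2.5 * 2.0 ** (k / 3.0), 2) for k in range(12)
)
SURVEY_LW_A = 0.01  # g per cm^3
SURVEY_LW_B = 3.0


def gen_survey_dataset(
    config: SurveyGenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a transect survey with known slope-model truth.

    Each transect draws a log10 community PPMR and inherits its site's SST;
    its abundance size-spectrum slope is the configured linear predictor plus
    year, site-within-year and residual noise.  A guild x size-class
    abundance table is emitted whose expected counts follow each transect's
    slope (for end-to-end pipeline runs).

    Returns ``(survey_table, slopes_table, truth)``.
    """
    n_total = config.total_transects
    rng_struct, rng_slope, rng_comm = _child_rngs(config.seed, 3)

    sites = [f"site{i:03d}" for i in range(config.n_sites)]
    years = [2015 + i for i in range(config.n_years)]
    sst_by_site = {
        s: float(rng_struct.uniform(*config.sst_range_c)) for s in sites
    }
    year_eff = {
        y: float(rng_struct.normal(0.0, np.sqrt(config.year_variance)))
        for y in years
    }

    if config.n_transects is not None:
        site_idx = rng_struct.integers(config.n_sites, size=n_total)
        year_idx = rng_struct.integers(config.n_years, size=n_total)
    else:
        site_idx = np.repeat(
            np.arange(config.n_sites), config.transects_per_site
        )
        year_idx = rng_struct.integers(config.n_years, size=n_total)

    b0, b1, b2, b3 = config.coefficients
    sy_eff: dict[tuple, float] = {}
    slope_rows = []
    survey_rows = []
    lengths = np.asarray(SURVEY_LENGTH_CLASSES_CM)
    masses = SURVEY_LW_A * lengths**SURVEY_LW_B

    for t in range(n_total):
        site = sites[int(site_idx[t])]
        year = years[int(year_idx[t])]
        sst = sst_by_site[site]
        key = (year, site)
        if key not in sy_eff:
            sy_eff[key] = float(
                rng_slope.normal(0.0, np.sqrt(config.site_year_variance))
            )
        lc = float(
            rng_slope.normal(config.cppmr_log10_loc, config.cppmr_log10_scale)
        )
        eps = float(rng_slope.normal(0.0, np.sqrt(config.residual_variance)))
        slope = (
            b0 + b1 * lc + b2 * sst + b3 * lc * sst
            + year_eff[year] + sy_eff[key] + eps
        )
        tid = f"tr{t:05d}"
        slope_rows.append(
            {
                "transect_id": tid,
                "site": site,
                "year": year,
                "sst_c": sst,
                "log10_cppmr": lc,
                "slope": slope,
            }
        )
        # community whose per-class expected abundance follows the slope
        wts = masses**slope
        wts = wts / wts.sum()
        for guild, share in DEFAULT_GUILD_SHARES.items():
            lam = config.individuals_per_transect * share * wts
            counts = rng_comm.poisson(lam)
            for cls_cm, n_ind in zip(lengths, counts):
                if n_ind == 0:
                    continue
                survey_rows.append(
                    {
                        "transect_id": tid,
                        "site": site,
                        "year": year,
                        "sst_c": sst,
                        "species": f"sp_{guild}",
                        "guild": guild,
                        "size_class_cm": float(cls_cm),
                        "abundance": int(n_ind),
                        "lw_a": SURVEY_LW_A,
                        "lw_b": SURVEY_LW_B,
                    }
                )

    survey = pd.DataFrame(
        survey_rows,
        columns=[
            "transect_id", "site", "year", "sst_c", "species", "guild",
            "size_class_cm", "abundance", "lw_a", "lw_b",
        ],
    )
    slopes = pd.DataFrame(slope_rows)
    truth = {
        "coefficients": {
            "intercept": b0, "log10_cppmr": b1, "sst": b2, "interaction": b3,
        },
        "site_year_variance": config.site_year_variance,
        "year_variance": config.year_variance,
        "residual_variance": config.residual_variance,
        "year_effects": {str(k): v for k, v in year_eff.items()},
        "site_year_effects": {f"{y}:{s}": v for (y, s), v in sy_eff.items()},
        "n_transects": n_total,
        "seed": config.seed,
    }
    return survey, slopes, truth
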