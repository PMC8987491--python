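import numpy as np
import pandas as pd
import pytest

import reefppmr as rp

GUILD_TRUTHS = {
    "piscivore": 2.22,
    "invertivore": 0.68,
    "planktivore": 0.47,
    "herbivore": 0.11,
}


def make_lmm_fixture(seed: int = 7) -> pd.DataFrame:
    """Small two-level hierarchical dataset with per-row weights, used for
    cross-checks against external mixed-model fitters."""
    rng = np.random.default_rng(seed)
    n_g, n_per, n_obs = 6, 5, 8
    rows = []
    for g in range(n_g):
        ug = rng.normal(0, 0.5)
        for i in range(n_per):
            ui = rng.normal(0, 0.3)
            x = rng.uniform(0, 3, n_obs)
            y = 1.0 + 0.8 * x + ug + ui + rng.normal(0, 0.4, n_obs)
            for xx, yy in zip(x, y):
                rows.append(
                    dict(g=f"g{g}", ind=f"g{g}i{i}", x=xx, y=yy,
                         w=float(rng.uniform(0.5, 2.0)))
                )
    return pd.DataFrame(rows)


def gen_processed_gut(seed: int = 0, scheme: str = "normalized", **kwargs):
    """Generate and fully process a synthetic gut dataset."""
    cfg = rp.GutGenConfig(seed=seed, **kwargs)
    samples, truth = rp.gen_gut_dataset(cfg)
    gut = rp.synthetic.gut_samples_to_frame(samples)
    allo = pd.DataFrame(truth["allometry"])
    processed, _ = rp.prey.process_gut_frame(gut, allo, scheme=scheme)
    return processed, truth


def noise_free_gut(fixed_effects=None, seed: int = 0):
    """Gut dataset lying exactly on the configured fixed-effect planes."""
    fixed = fixed_effects or {
        "herbivore": (-3.0, 0.2),
        "invertivore": (-3.0, 0.7),
        "planktivore": (-4.0, 0.5),
        "piscivore": (-5.0, 2.0),
    }
    cfg = rp.GutGenConfig(
        n_predators_per_guild=25,
        fixed_effects=fixed,
        genus_sd=0.0,
        individual_sd=0.0,
        residual_sd=0.0,
        seed=seed,
    )
    samples, truth = rp.gen_gut_dataset(cfg)
    gut = rp.synthetic.gut_samples_to_frame(samples)
    allo = pd.DataFrame(truth["allometry"])
    processed, _ = rp.prey.process_gut_frame(gut, allo)
    return processed, fixed


@pytest.fixture(scope="session")
def lmm_fixture():
    return make_lmm_fixture()


@pytest.fixture(scope="session")
def small_gut():
    processed, truth = gen_processed_gut(seed=11, n_predators_per_guild=30)
    return processed, truth


@pytest.fixture(scope="session")
def small_gut_model(small_gut):
    processed, _ = small_gut
    return rp.fit_ppmr_model(processed)


@pytest.fixture(scope="session")
def unit_slope_model():
    """Guild model with total slope 1 everywhere and known intercepts, so
    PPMR is mass-independent per guild: herb 1e2, inv 1e3, plank 1e4,
    pisc 1e5."""
    fixed = {
        "herbivore": (-2.0, 1.0),
        "invertivore": (-3.0, 1.0),
        "planktivore": (-4.0, 1.0),
        "piscivore": (-5.0, 1.0),
    }
    processed, _ = noise_free_gut(fixed_effects=fixed, seed=5)
    return rp.fit_ppmr_model(processed)


@pytest.fixture(scope="session")
def small_survey():
    cfg = rp.SurveyGenConfig(
        n_sites=40, n_years=3, n_transects=120, seed=21,
        individuals_per_transect=150.0,
    )
    return rp.gen_survey_dataset(cfg)
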