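"""Guild consolidation, body-mass derivation, transect cPPMR aggregation,
sensitivity and trimming."""

import numpy as np
import pandas as pd
import pytest

import reefppmr as rp
from reefppmr.community import (
    consolidate_guild,
    guild_exclusion_sensitivity,
    size_class_to_mass,
    transect_cppmr,
    trim_percentiles,
)


def _transect(rows, tid="t1"):
    """Build a transect record table; rows = (guild, size_cm, abundance)."""
    return pd.DataFrame(
        [
            {
                "transect_id": tid,
                "site": "s1",
                "year": 2020,
                "sst_c": 20.0,
                "species": "sp",
                "guild": g,
                "size_class_cm": sc,
                "abundance": n,
                "lw_a": 0.01,
                "lw_b": 3.0,
            }
            for g, sc, n in rows
        ]
    )


class TestConsolidation:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Browsing Herbivores", "herbivore"),
            ("Algal Farmers", "herbivore"),
            ("Scraping Herbivores", "herbivore"),
            ("Excavators", "herbivore"),
            ("Benthic Invertivores", "invertivore"),
            ("Omnivores", "invertivore"),
            ("Corallivores", "invertivore"),
            ("Higher Carnivores", "piscivore"),
            ("Planktivores", "planktivore"),
            ("herbivore", "herbivore"),
        ],
    )
    def test_mapping(self, raw, expected):
        assert consolidate_guild(raw) == expected

    @pytest.mark.parametrize(
        "raw", ["cleaner", "Cleaners", "marine mammals", "reptiles", "birds"]
    )
    def test_cleaners_and_non_fish_excluded(self, raw):
        assert consolidate_guild(raw) == "excluded"

    def test_unknown_label_lists_vocabulary(self):
        with pytest.raises(ValueError, match="known labels"):
            consolidate_guild("kelp grazers")


class TestSizeClassMass:
    def test_cubic_example(self):
        assert size_class_to_mass(10.0, 0.01, 3.0) == pytest.approx(10.0)

    def test_monotone(self):
        lengths = np.linspace(2, 60, 30)
        masses = size_class_to_mass(lengths, 0.015, 3.1)
        assert np.all(np.diff(masses) > 0)

    def test_batch_equals_rowwise(self):
        rng = np.random.default_rng(0)
        l = rng.uniform(2, 50, 40)
        a = rng.uniform(0.005, 0.03, 40)
        b = rng.uniform(2.8, 3.2, 40)
        batch = size_class_to_mass(l, a, b)
        for i in range(40):
            assert batch[i] == pytest.approx(a[i] * l[i] ** b[i])

    def test_missing_coefficients_rejected(self):
        with pytest.raises(ValueError):
            size_class_to_mass(10.0, np.nan, 3.0)


class TestTransectCPPMR:
    def test_single_group_equals_its_ppmr(self, unit_slope_model):
        rec = _transect([("planktivore", 10.0, 7)])
        c = transect_cppmr(rec, unit_slope_model)
        assert c.cppmr == pytest.approx(1e4, rel=1e-6)

    def test_hand_computed_weighted_mean(self, unit_slope_model):
        # herbivore PPMR 100 (N=3), invertivore PPMR 1000 (N=1) -> 325
        rec = _transect([("herbivore", 10.0, 3), ("invertivore", 10.0, 1)])
        c = transect_cppmr(rec, unit_slope_model)
        assert c.cppmr == pytest.approx(325.0, rel=1e-9)
        assert c.n_individuals == 4

    def test_grouped_equals_exploded_individual_mean(
        self, unit_slope_model, small_survey
    ):
        """The grouped formula equals the mean over a per-individual list
        (exact: PPMR depends only on guild and mass)."""
        survey, _, _ = small_survey
        records, _ = rp.community.prepare_survey(survey)
        for tid, grp in list(records.groupby("transect_id"))[:10]:
            c = transect_cppmr(grp, unit_slope_model)
            exploded = []
            for r in grp.itertuples(index=False):
                p = rp.compute_ppmr(unit_slope_model, r.body_mass_g, r.guild)
                exploded.extend([p] * int(r.abundance))
            assert c.cppmr == pytest.approx(np.mean(exploded), rel=1e-12)

    def test_bounded_by_min_max_individual_ppmr(
        self, small_gut_model, small_survey
    ):
        survey, _, _ = small_survey
        records, _ = rp.community.prepare_survey(survey)
        for tid, grp in list(records.groupby("transect_id"))[:10]:
            c = transect_cppmr(grp, small_gut_model)
            pp = np.array(
                [
                    rp.compute_ppmr(small_gut_model, r.body_mass_g, r.guild)
                    for r in grp.itertuples(index=False)
                ]
            )
            assert pp.min() - 1e-9 <= c.cppmr <= pp.max() + 1e-9
            assert np.isfinite(c.log10_cppmr)

    def test_geometric_mean_option(self, unit_slope_model):
        # equal abundances of PPMR 100 and 1000: geometric mean
        # sqrt(100*1000), below the arithmetic 550
        rec = _transect([("herbivore", 10.0, 2), ("invertivore", 10.0, 2)])
        geo = transect_cppmr(rec, unit_slope_model, mean="geometric")
        art = transect_cppmr(rec, unit_slope_model)
        assert geo.cppmr == pytest.approx(np.sqrt(1e5), rel=1e-9)
        assert art.cppmr == pytest.approx(550.0, rel=1e-9)
        with pytest.raises(ValueError):
            transect_cppmr(rec, unit_slope_model, mean="harmonic")

    def test_zero_abundance_rejected(self, unit_slope_model):
        rec = _transect([("herbivore", 10.0, 0)])
        with pytest.raises(ValueError, match="zero total abundance"):
            transect_cppmr(rec, unit_slope_model)

    def test_multiple_transects_rejected(self, unit_slope_model):
        rec = pd.concat(
            [_transect([("herbivore", 10.0, 1)], tid="a"),
             _transect([("herbivore", 10.0, 1)], tid="b")]
        )
        with pytest.raises(ValueError, match="single transect"):
            transect_cppmr(rec, unit_slope_model)


class TestSensitivity:
    def test_drop_one_of_two_equal_groups(self, unit_slope_model):
        rec = _transect([("herbivore", 10.0, 2), ("invertivore", 10.0, 2)])
        table = guild_exclusion_sensitivity(rec, unit_slope_model)
        dropped = table.set_index("dropped_guild")
        assert dropped.loc["herbivore", "cppmr"] == pytest.approx(1000.0)
        assert dropped.loc["invertivore", "cppmr"] == pytest.approx(100.0)

    def test_absent_guild_leaves_cppmr_unchanged(self, unit_slope_model):
        rec = _transect([("herbivore", 10.0, 2), ("invertivore", 10.0, 2)])
        table = guild_exclusion_sensitivity(rec, unit_slope_model)
        base = table.iloc[0]["cppmr"]
        pisc = table.set_index("dropped_guild").loc["piscivore"]
        assert np.isnan(pisc["cppmr"]) or pisc["cppmr"] == pytest.approx(base)

    def test_dominant_guild_has_largest_impact(self, unit_slope_model):
        """On an invertivore-dominated transect, dropping invertivores
        changes cPPMR the most."""
        rec = _transect(
            [
                ("herbivore", 10.0, 5),
                ("invertivore", 10.0, 60),
                ("planktivore", 5.0, 10),
                ("piscivore", 30.0, 3),
            ]
        )
        table = guild_exclusion_sensitivity(rec, unit_slope_model)
        changes = (
            table[table["dropped_guild"] != "(none)"]
            .set_index("dropped_guild")["relative_change"]
            .abs()
        )
        assert changes.idxmax() == "invertivore"

    def test_single_guild_rejected(self, unit_slope_model):
        rec = _transect([("herbivore", 10.0, 2)])
        with pytest.raises(ValueError):
            guild_exclusion_sensitivity(rec, unit_slope_model)


class TestTrim:
    def test_hundred_distinct_removes_two(self):
        df = pd.DataFrame({"cppmr": np.arange(1.0, 101.0)})
        kept, removed = trim_percentiles(df)
        assert removed == 2
        assert len(kept) == 98

    def test_identical_values_remove_none(self):
        df = pd.DataFrame({"cppmr": np.full(50, 7.0)})
        kept, removed = trim_percentiles(df)
        assert removed == 0

    def test_removal_fraction_about_two_percent(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"cppmr": 10 ** rng.normal(3.9, 0.4, 2000)})
        _, removed = trim_percentiles(df)
        assert 0.015 <= removed / len(df) <= 0.025

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            trim_percentiles(pd.DataFrame({"cppmr": [1.0, 2.0]}))
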