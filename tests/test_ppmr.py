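"""Guild prey-mass mixed model: recovery, weighting equivalences,
prediction modes, PPMR derivation, model comparison."""

import numpy as np
import pytest

import reefppmr as rp
from reefppmr.ppmr import PredictionMode

from conftest import gen_processed_gut, noise_free_gut


class TestFit:
    def test_noise_free_recovers_truth_exactly(self):
        processed, fixed = noise_free_gut(seed=1)
        m = rp.fit_ppmr_model(processed)
        for g, (b0, b1) in fixed.items():
            assert m.total_slope(g) == pytest.approx(b1, abs=1e-6)
            assert m.guild_intercept(g) == pytest.approx(b0, abs=1e-6)

    def test_equal_weights_match_unweighted(self):
        processed, _ = gen_processed_gut(seed=4, n_predators_per_guild=20)
        data = processed.copy()
        data["weight"] = 2.5
        weighted = rp.fit_ppmr_model(data, weight_scheme="raw")
        unweighted = rp.fit_ppmr_model(data, weight_scheme="none")
        np.testing.assert_allclose(
            weighted.result.params, unweighted.result.params, rtol=1e-8
        )

    def test_missing_guild_contrast_rejected(self):
        processed, _ = gen_processed_gut(seed=4, n_predators_per_guild=10)
        one = processed[processed["guild"] == "piscivore"]
        with pytest.raises(ValueError):
            rp.fit_ppmr_model(one)

    def test_r2_bounds(self, small_gut_model):
        m = small_gut_model
        assert 0.0 <= m.marginal_r2 <= m.conditional_r2 <= 1.0

    def test_variances_nonnegative(self, small_gut_model):
        assert all(v >= 0 for v in small_gut_model.vc.values())
        assert small_gut_model.residual_variance >= 0

    def test_model_json_serializes(self, small_gut_model):
        import json

        payload = json.loads(small_gut_model.to_json())
        assert set(payload["total_slopes"]) == set(rp.prey.GUILDS)


class TestPrediction:
    def test_fixed_only_closed_form(self, unit_slope_model):
        # planktivore: intercept -4, slope 1 -> 100 g predator eats 0.01 g
        pred = rp.predict_prey_mass(
            unit_slope_model, 100.0, "planktivore",
            mode=PredictionMode.fixed_only,
        )
        assert pred == pytest.approx(0.01, rel=1e-6)

    def test_full_mode_with_zero_random_effects_equals_fixed(
        self, unit_slope_model
    ):
        m = unit_slope_model
        genus = m.result.ranef["genus"].index[0]
        ind = m.result.ranef["individual"].index[0]
        a = rp.predict_prey_mass(m, 50.0, "herbivore", mode="full",
                                 genus=genus, individual=ind)
        b = rp.predict_prey_mass(m, 50.0, "herbivore", mode="fixed_only")
        assert a == pytest.approx(b, rel=1e-8)

    def test_predictions_match_hand_built_linear_predictor(
        self, small_gut_model, small_gut
    ):
        """Row-wise brute force: intercept + slope*log10(m) + BLUPs."""
        m = small_gut_model
        processed, _ = small_gut
        rows = processed.sample(50, random_state=7)
        for r in rows.itertuples(index=False):
            yhat = (
                m.guild_intercept(r.guild)
                + m.total_slope(r.guild) * np.log10(r.predator_mass_g)
                + float(m.result.ranef["genus"][r.genus])
                + float(m.result.ranef["individual"][r.predator_id])
            )
            got = rp.predict_prey_mass(
                m, r.predator_mass_g, r.guild, mode="full",
                genus=r.genus, individual=r.predator_id,
            )
            assert got == pytest.approx(10.0**yhat, rel=1e-10)

    def test_unknown_genus_errors(self, unit_slope_model):
        with pytest.raises(ValueError, match="unknown"):
            rp.predict_prey_mass(
                unit_slope_model, 10.0, "piscivore", mode="genus_only",
                genus="Nosuchgenus",
            )

    def test_mode_requires_identifiers(self, unit_slope_model):
        with pytest.raises(ValueError):
            rp.predict_prey_mass(
                unit_slope_model, 10.0, "piscivore", mode="full"
            )


class TestPPMR:
    def test_ratio_orientation(self, unit_slope_model):
        # planktivore PPMR is 1e4 at any mass (total slope 1, intercept -4)
        assert rp.compute_ppmr(
            unit_slope_model, 100.0, "planktivore"
        ) == pytest.approx(1e4, rel=1e-6)

    def test_log_ppmr_linear_with_slope_one_minus_total(self):
        processed, fixed = noise_free_gut(seed=2)
        m = rp.fit_ppmr_model(processed)
        for g, (_, b1) in fixed.items():
            p1 = rp.compute_ppmr(m, 10.0, g)
            p2 = rp.compute_ppmr(m, 1000.0, g)
            implied = (np.log10(p2) - np.log10(p1)) / 2.0
            assert implied == pytest.approx(1.0 - b1, abs=1e-6)

    def test_herbivore_ppmr_increases_when_slope_below_one(self):
        """Guilds whose prey mass grows slower than predator mass show
        increasing PPMR with body size."""
        processed, fixed = noise_free_gut(seed=3)
        m = rp.fit_ppmr_model(processed)
        assert fixed["herbivore"][1] < 1.0
        assert rp.compute_ppmr(m, 1000.0, "herbivore") > rp.compute_ppmr(
            m, 10.0, "herbivore"
        )

    def test_ppmr_positive(self, small_gut_model):
        masses = np.logspace(0.5, 3.5, 20)
        for g in rp.prey.GUILDS:
            assert np.all(
                np.asarray(rp.compute_ppmr(small_gut_model, masses, g)) > 0
            )


class TestStructureComparison:
    def test_single_candidate_delta_zero(self, small_gut):
        processed, _ = small_gut
        table = rp.compare_random_structures(
            processed, {"genus_only": ("genus",)}
        )
        assert table["delta_aic"].iloc[0] == 0.0

    def test_strong_individual_effects_favor_nested_structure(self):
        processed, _ = gen_processed_gut(
            seed=9, n_predators_per_guild=40,
            genus_sd=0.05, individual_sd=0.8, residual_sd=0.3,
        )
        table = rp.compare_random_structures(
            processed,
            {"genus_only": ("genus",), "genus_id": ("genus", "individual")},
        )
        assert table.iloc[0]["structure"] == "genus_id"
        assert table[table["structure"] == "genus_only"]["delta_aic"].iloc[0] > 4

    def test_noise_free_structures_indistinguishable(self):
        processed, _ = noise_free_gut(seed=6)
        table = rp.compare_random_structures(
            processed,
            {"genus_only": ("genus",), "genus_id": ("genus", "individual")},
        )
        assert (table["delta_aic"] < 4).all()

    def test_failed_fit_recorded_not_dropped(self, small_gut):
        processed, _ = small_gut
        table = rp.compare_random_structures(
            processed,
            {"ok": ("genus",), "broken": ("no_such_column",)},
        )
        bad = table[table["structure"] == "broken"]
        assert len(bad) == 1 and bad["error"].iloc[0] != ""
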