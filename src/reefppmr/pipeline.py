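"""End-to-end pipeline: gut contents -> guild model -> community PPMR ->
spectrum slopes -> slope ~ cPPMR x SST fit, with a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import community, io, ppmr, prey, slopes, spectrum

log = logging.getLogger("reefppmr")


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    gut_csv: str
    survey_csv: str
    allometry_csv: str
    out_dir: str
    weight_scheme: str = "normalized"
    prediction_mode: str = "fixed_only"
    trim: bool = True
    trim_lower: float = 0.01
    trim_upper: float = 0.99
    min_mass_g: float | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run conversion -> guild model -> cPPMR -> spectra -> slope model.

    Writes all intermediate CSVs, the model JSON and a manifest (config
    hash, seed, per-stage row counts) to ``config.out_dir``; returns the
    manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
    }

    gut = _stage("read_inputs")(io.read_gut_csv)(config.gut_csv)
    allometry = io.read_allometry_csv(config.allometry_csv)
    survey = io.read_survey_csv(config.survey_csv)

    processed, audit = _stage("prey_processing")(prey.process_gut_frame)(
        gut, allometry, scheme=config.weight_scheme
    )
    log.info("prey_processing: %d rows kept, %d audited", len(processed),
             len(audit))
    manifest["stages"]["prey_processing"] = {
        "rows_in": len(gut), "rows_kept": len(processed),
        "rows_audited": len(audit),
    }
    manifest["outputs"]["prey_audit"] = str(
        io.write_csv(audit, out / "prey_audit.csv")
    )

    model = _stage("ppmr_model")(ppmr.fit_ppmr_model)(
        processed, weight_scheme=config.weight_scheme
    )
    (out / "ppmr_model.json").write_text(model.to_json())
    manifest["outputs"]["ppmr_model"] = str(out / "ppmr_model.json")
    manifest["outputs"]["ppmr_coefficients"] = str(
        io.write_csv(model.coef_table().reset_index(names="term"),
                     out / "ppmr_coefficients.csv")
    )
    manifest["stages"]["ppmr_model"] = {
        "n_obs": model.n_obs, "n_predators": model.n_predators,
        "n_genera": model.n_genera,
    }

    cpp = _stage("community_ppmr")(community.survey_cppmr_table)(
        survey, model
    )
    manifest["outputs"]["cppmr"] = str(
        io.write_csv(cpp, out / "transect_cppmr.csv")
    )
    manifest["stages"]["community_ppmr"] = {"n_transects": len(cpp)}

    records, _ = community.prepare_survey(survey)
    spec = _stage("size_spectrum")(spectrum.survey_spectrum_slopes)(
        records, min_mass_g=config.min_mass_g
    )
    manifest["outputs"]["spectrum_slopes"] = str(
        io.write_csv(spec, out / "spectrum_slopes.csv")
    )
    manifest["stages"]["size_spectrum"] = {
        "n_valid": int(spec["valid"].sum()), "n_total": len(spec),
    }

    joined = cpp.merge(
        spec.loc[spec["valid"], ["transect_id", "slope"]], on="transect_id"
    )
    removed = 0
    if config.trim and len(joined) >= 3:
        joined, removed = community.trim_percentiles(
            joined, config.trim_lower, config.trim_upper
        )
    slope_fit = _stage("slope_analysis")(slopes.fit_slope_model)(joined)
    manifest["outputs"]["slope_model_summary"] = str(
        out / "slope_model_summary.txt"
    )
    (out / "slope_model_summary.txt").write_text(slopes.summary_text(slope_fit))
    manifest["outputs"]["slope_model_coefficients"] = str(
        io.write_csv(
            slope_fit.coefficients.reset_index(names="term"),
            out / "slope_model_coefficients.csv",
        )
    )
    manifest["stages"]["slope_analysis"] = {
        "n_obs": slope_fit.n_obs,
        "trimmed": removed,
        "singular": slope_fit.singular,
    }

    trend = slopes.predict_trendlines(
        slope_fit,
        sst_fitted_range=(
            float(joined["sst_c"].min()), float(joined["sst_c"].max())
        ),
    )
    manifest["outputs"]["trendlines"] = str(
        io.write_csv(trend, out / "trendlines.csv")
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def simulate_to_dir(
    out_dir,
    gut_config=None,
    survey_config=None,
) -> dict:
    """Write synthetic gut, survey and allometry CSVs plus truth sidecars."""
    from . import synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gut_config = gut_config or synthetic.GutGenConfig()
    survey_config = survey_config or synthetic.SurveyGenConfig()

    samples, gut_truth = synthetic.gen_gut_dataset(gut_config)
    gut = synthetic.gut_samples_to_frame(samples)
    allometry = pd.DataFrame(gut_truth["allometry"])
    survey, slopes_df, survey_truth = synthetic.gen_survey_dataset(
        survey_config
    )

    paths = {
        "gut": str(io.write_csv(gut, out / "gut.csv")),
        "allometry": str(io.write_csv(allometry, out / "allometry.csv")),
        "survey": str(io.write_csv(survey, out / "survey.csv")),
        "slopes": str(io.write_csv(slopes_df, out / "slopes.csv")),
        "truth": str(
            io.write_truth_json(
                {"gut": {k: v for k, v in gut_truth.items()
                         if k != "allometry"},
                 "survey": survey_truth},
                out / "truth.json",
            )
        ),
    }
    return paths
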