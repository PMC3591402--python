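"""End-to-end reproducible pipeline: simulate → fit → tables → predict.

A single declarative config (YAML or JSON, versioned schema) drives the
run; all seeds and sizes live in the config, never in code.  Every run
writes a manifest with the config snapshot, seeds, input digests and
fitted-parameter digests — two runs from the same manifest produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import synthetic
from .amh import RegressionModel, amh_percentile_curves, fit_amh_regression
from .menopause import (
    BMI_CATEGORIES,
    CovariateProfile,
    ThresholdModel,
    all_profiles,
    fit_threshold_model,
    menopause_percentiles,
)
from .predict import predict_menopause_interval, prediction_report
from .skewt import SkewTParams

__all__ = [
    "SCHEMA_VERSION",
    "DEFAULT_CONFIG",
    "run_pipeline",
    "regression_to_dict",
    "regression_from_dict",
    "threshold_to_dict",
    "threshold_from_dict",
]

SCHEMA_VERSION = 1
_VERSION = "0.1.0"

logger = logging.getLogger("menopredict")

DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "simulate": {"n_amh": 375, "n_meno": 2635},
    "fit": {"terms": ["age", "age2"], "n_starts": 5},
    "percentiles": {"probs": [0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95]},
    "predictions": [],
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def regression_to_dict(rm: RegressionModel) -> dict:
    return {
        "terms": list(rm.terms),
        "coef": dict(rm.coef),
        "residual": dataclasses.asdict(rm.residual),
        "loglik": rm.loglik,
        "n": rm.n,
        "n_params": rm.n_params,
        "converged": rm.converged,
        "message": rm.message,
        "age_range": list(rm.age_range),
    }


def regression_from_dict(d: dict) -> RegressionModel:
    return RegressionModel(
        terms=tuple(d["terms"]),
        coef=dict(d["coef"]),
        residual=SkewTParams(**d["residual"]),
        loglik=d["loglik"],
        n=d["n"],
        n_params=d["n_params"],
        converged=d.get("converged", True),
        message=d.get("message", ""),
        age_range=tuple(d.get("age_range", (19.0, 44.0))),
    )


def threshold_to_dict(tm: ThresholdModel) -> dict:
    return {
        "alpha": tm.alpha,
        "beta_bmi": dict(tm.beta_bmi),
        "gamma_smoke": tm.gamma_smoke,
        "kappa": tm.kappa,
        "stage2_residual": dataclasses.asdict(tm.stage2_residual),
        "loglik": tm.loglik,
        "n": tm.n,
        "converged": tm.converged,
        "unidentifiable": list(tm.unidentifiable),
    }


def threshold_from_dict(d: dict) -> ThresholdModel:
    return ThresholdModel(
        alpha=d["alpha"],
        beta_bmi=dict(d["beta_bmi"]),
        gamma_smoke=d["gamma_smoke"],
        kappa=d["kappa"],
        stage2_residual=SkewTParams(**d["stage2_residual"]),
        loglik=d["loglik"],
        n=d["n"],
        converged=d.get("converged", True),
        unidentifiable=tuple(d.get("unidentifiable", ())),
    )


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    version = cfg.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _threshold_table(tm: ThresholdModel) -> pd.DataFrame:
    """Thresholds (ng/mL) as BMI-category rows × smoking columns."""
    rows = {
        cat: {
            "nonsmoker": tm.threshold(CovariateProfile(cat, False)),
            "smoker": tm.threshold(CovariateProfile(cat, True)),
        }
        for cat in BMI_CATEGORIES
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("bmi_category")


def _percentile_table(tm: ThresholdModel, rm: RegressionModel, probs) -> pd.DataFrame:
    """Menopausal-age percentiles, profile rows × probability columns."""
    rows = {}
    for p in all_profiles():
        rows[p.label()] = dict(
            zip(
                [f"p{int(round(q * 100)):02d}" for q in probs],
                menopause_percentiles(tm, rm, p, probs),
            )
        )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("profile")


def run_pipeline(config, out_dir) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    ``config`` is a path to a YAML/JSON file or an already-loaded mapping.
    Stages: simulate (or read input CSVs) → stage-1 fit → stage-2 fit →
    percentile tables (covariate-specific and no-covariate) → individual
    predictions.  A failing stage leaves a ``FAILED_<stage>`` marker.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge_default(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "tool_version": _VERSION,
        "config": cfg,
        "seed": cfg["seed"],
        "inputs": {},
        "digests": {},
        "stages": {},
    }
    stage = "simulate"
    try:
        seed = int(cfg["seed"])
        inputs = cfg.get("inputs") or {}
        if inputs:
            amh_df = mio.read_cohort_csv(inputs["amh_csv"], "amh")
            meno_df = mio.read_cohort_csv(inputs["menopause_csv"], "menopause")
            manifest["inputs"] = {
                "amh_csv": _sha256(Path(inputs["amh_csv"])),
                "menopause_csv": _sha256(Path(inputs["menopause_csv"])),
            }
        else:
            gen = synthetic.default_generating_params(seed=seed)
            gen = gen.replace(
                n_amh=int(cfg["simulate"]["n_amh"]), n_meno=int(cfg["simulate"]["n_meno"])
            )
            amh_df = synthetic.generate_amh_cohort(gen)
            meno_df = synthetic.generate_menopause_cohort(gen)
            mio.write_cohort_csv(amh_df, out / "amh_cohort.csv")
            mio.write_cohort_csv(meno_df, out / "menopause_cohort.csv")
            _write_json(
                {
                    "seed": seed,
                    "regression": regression_to_dict(gen.regression),
                    "thresholds": {f"{c}_{int(s)}": v for (c, s), v in gen.thresholds.items()},
                    "kappa": gen.kappa,
                },
                out / "generating_params.json",
            )
            logger.info("simulate: seed=%d n_amh=%d n_meno=%d", seed, gen.n_amh, gen.n_meno)
        manifest["stages"]["simulate"] = {"seed": seed, "n_amh": len(amh_df), "n_meno": len(meno_df)}

        stage = "fit-amh"
        rm = fit_amh_regression(
            amh_df,
            terms=tuple(cfg["fit"]["terms"]),
            n_starts=int(cfg["fit"]["n_starts"]),
        )
        _write_json(regression_to_dict(rm), out / "amh_fit.json")
        logger.info("fit-amh: loglik=%.6f converged=%s peak_age=%.2f", rm.loglik, rm.converged, rm.peak_age)
        manifest["stages"]["fit-amh"] = {"loglik": rm.loglik, "converged": rm.converged}

        stage = "fit-threshold"
        tm = fit_threshold_model(meno_df, rm)
        tm_nocov = fit_threshold_model(meno_df, rm, include_covariates=False)
        _write_json(threshold_to_dict(tm), out / "threshold_fit.json")
        _write_json(threshold_to_dict(tm_nocov), out / "threshold_fit_nocovariates.json")
        logger.info("fit-threshold: loglik=%.6f kappa=%.4f", tm.loglik, tm.kappa)
        manifest["stages"]["fit-threshold"] = {
            "loglik": tm.loglik,
            "kappa": tm.kappa,
            "converged": tm.converged,
        }

        stage = "percentiles"
        probs = [float(p) for p in cfg["percentiles"]["probs"]]
        curves = amh_percentile_curves(rm, probs=probs)
        mio.write_percentile_table(curves, out / "amh_percentiles.csv")
        mio.write_threshold_table(_threshold_table(tm), out / "thresholds.csv")
        mio.write_threshold_table(
            _percentile_table(tm, rm, probs), out / "menopause_percentiles.csv"
        )
        nocov = pd.DataFrame.from_dict(
            {
                "all": dict(
                    zip(
                        [f"p{int(round(q * 100)):02d}" for q in probs],
                        menopause_percentiles(
                            tm_nocov, rm, CovariateProfile("normal", False), probs
                        ),
                    )
                )
            },
            orient="index",
        ).rename_axis("profile")
        mio.write_threshold_table(nocov, out / "menopause_percentiles_nocovariates.csv")

        stage = "predict"
        lines = []
        for row in cfg.get("predictions", []):
            profile = (
                CovariateProfile(row["bmi_category"], bool(row["smoker"]))
                if "bmi_category" in row
                else CovariateProfile.from_bmi(float(row["bmi"]), bool(row["smoker"]))
            )
            pred = predict_menopause_interval(
                float(row["age_years"]), float(row["amh_ng_ml"]), profile, rm, tm
            )
            lines.append(json.dumps(prediction_report(pred, rm, tm), sort_keys=True))
        (out / "predictions.jsonl").write_text("\n".join(lines) + ("\n" if lines else ""))

        manifest["digests"] = {
            f.name: _sha256(f)
            for f in sorted(out.iterdir())
            if f.suffix in (".csv", ".json", ".jsonl") and f.name != "manifest.json"
        }
        manifest["models"] = {
            "regression_signature": rm.param_signature(),
            "threshold_signature": tm.param_signature(),
        }
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception:
        (out / f"FAILED_{stage}").write_text("stage failed; see traceback\n")
        logger.exception("pipeline failed in stage %s", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _merge_default(cfg: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged
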