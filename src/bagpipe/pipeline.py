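"""Orchestration: configuration, logging and the end-to-end run
(simulate → train → cross-validate → predict → bias-correct → compare →
report).

Every stage reads and writes plain-text artifacts under the output
directory, so stages can be run separately (see :mod:`bagpipe.cli`) and
compose to the same result as a single ``run_pipeline`` call.  A run log
(``run.log``) captures the config echo, seeds and every default in
force; report tables are regenerated deterministically from config +
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_bag, brainage, inference, synthetic_cohort, tables_io

__all__ = ["RunConfig", "run_pipeline", "load_config", "setup_logging"]

log = logging.getLogger("bagpipe")

MODALITY_KEYS = ("T1", "DTI")


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when an output directory is given, run.log."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log", mode="a"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML/JSON on disk)."""

    seed: int
    out_dir: str = "bagpipe_out"
    synthetic: bool = True
    # used when synthetic is False:
    train_cohort: str | None = None
    train_features: dict[str, str] = field(default_factory=dict)
    patient_cohort: str | None = None
    patient_features: dict[str, str] = field(default_factory=dict)
    # synthetic generator overrides (field name -> value)
    synthetic_overrides: dict = field(default_factory=dict)
    hyperparameters: brainage.Hyperparameters = field(
        default_factory=brainage.Hyperparameters
    )
    grid: dict | None = None
    cv_k: int = 5
    cv_reps: int = 100
    nested: bool = False
    bias_fit: str = "out-of-fold"  # or "in-sample"
    analyses: list[str] = field(default_factory=lambda: ["bag"])
    q: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must specify a seed")
        self.seed = int(self.seed)
        if self.cv_reps < 1:
            raise ValueError("cv_reps must be >= 1")
        if self.bias_fit not in ("out-of-fold", "in-sample"):
            raise ValueError("bias_fit must be 'out-of-fold' or 'in-sample'")
        unknown = set(self.analyses) - set(inference.COVARIATE_SCHEMES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if not self.synthetic:
            for path in filter(
                None,
                [self.train_cohort, self.patient_cohort]
                + list(self.train_features.values())
                + list(self.patient_features.values()),
            ):
                if not Path(path).exists():
                    raise FileNotFoundError(f"configured input does not exist: {path}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "seed" not in raw:
        raise ValueError("config must specify a seed")
    if "hyperparameters" in raw and isinstance(raw["hyperparameters"], dict):
        raw["hyperparameters"] = brainage.Hyperparameters(**raw["hyperparameters"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _synthetic_config(config: RunConfig) -> synthetic_cohort.SyntheticConfig:
    return synthetic_cohort.SyntheticConfig(
        seed=config.seed, **config.synthetic_overrides
    )


# ---------------------------------------------------------------- stages


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate synthetic training and patient cohorts into out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = _synthetic_config(config)
    paths: dict[str, Path] = {}
    for role in ("training", "patient"):
        cohort, t1, dti, gt = synthetic_cohort.generate_cohort(sc, role)
        tag = "train" if role == "training" else "patient"
        p = out / f"cohort_{tag}.csv"
        tables_io.write_cohort_table(cohort, p)
        paths[f"cohort_{tag}"] = p
        for ft in (t1, dti):
            p = out / f"features_{ft.modality.lower()}_{tag}.csv"
            tables_io.write_feature_table(ft, p)
            paths[f"features_{ft.modality}_{tag}"] = p
        synthetic_cohort.export_ground_truth(gt, out / f"ground_truth_{tag}")
    log.info("simulated cohorts with %s", sc)
    return paths


def _load_inputs(config: RunConfig, role: str):
    out = Path(config.out_dir)
    tag = "train" if role == "training" else "patient"
    if config.synthetic:
        cohort_path = out / f"cohort_{tag}.csv"
        feat_paths = {
            m: out / f"features_{m.lower()}_{tag}.csv" for m in MODALITY_KEYS
        }
    else:
        cohort_path = Path(
            config.train_cohort if role == "training" else config.patient_cohort
        )
        src = config.train_features if role == "training" else config.patient_features
        feat_paths = {m: Path(p) for m, p in src.items()}
    if not cohort_path.exists():
        raise FileNotFoundError(
            f"expected {role} cohort at {cohort_path}; run the simulate stage first"
        )
    cohort = tables_io.read_cohort_table(cohort_path)
    features = []
    for modality, p in feat_paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"expected {role} {modality} features at {p}")
        features.append(tables_io.read_feature_table(p, modality))
    return tables_io.assemble_dataset(cohort, *features)


def stage_train(config: RunConfig) -> dict[str, brainage.AgeModel]:
    """Fit one age model per modality on the training cohort; also fit
    and persist the bias correction (out-of-fold by default)."""
    ds = _load_inputs(config, "training")
    ages = ds.cohort.data["age"].to_numpy()
    out = Path(config.out_dir)
    models = {}
    bias: dict[str, dict] = {}
    for modality, ft in ds.features.items():
        model = brainage.fit_age_model(ft, ages, config.hyperparameters, seed=config.seed)
        brainage.save_model(model, out / f"model_{modality.lower()}")
        models[modality] = model
        if config.bias_fit == "out-of-fold":
            preds = brainage.out_of_fold_predictions(
                ft, ages, k=config.cv_k, hyper=config.hyperparameters, seed=config.seed
            )
        else:
            preds = brainage.predict_age(model, ft)
        bc = bias_bag.fit_bias(preds, ages, source=config.bias_fit)
        bias[modality] = {"alpha": bc.alpha, "beta": bc.beta, "source": bc.source}
        log.info(
            "%s model trained (n=%d); bias fit (%s): alpha=%.4f beta=%.3f",
            modality, ft.n_subjects, config.bias_fit, bc.alpha, bc.beta,
        )
    (out / "bias_correction.json").write_text(json.dumps(bias, indent=2))
    return models


def stage_cv(config: RunConfig, reps: int | None = None) -> pd.DataFrame:
    """Repeated-CV (and optional nested-CV) metrics on the training
    cohort, one row per modality; writes cv_report.tsv."""
    ds = _load_inputs(config, "training")
    ages = ds.cohort.data["age"].to_numpy()
    reps = config.cv_reps if reps is None else reps
    rows = []
    for modality, ft in ds.features.items():
        cv = brainage.cross_validate(
            ft, ages, k=config.cv_k, reps=reps,
            hyper=config.hyperparameters, seed=config.seed,
        )
        agg = cv.aggregate()
        row = {"modality": modality, "n": ft.n_subjects, "k": config.cv_k, "reps": reps}
        for metric, (mean, sd) in agg.items():
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
        if config.nested:
            best, outer = brainage.nested_grid_search(
                ft, ages, grid=config.grid,
                outer_k=config.cv_k, inner_k=config.cv_k, seed=config.seed,
            )
            for metric, (mean, sd) in outer.aggregate().items():
                row[f"{metric}_nested_mean"] = mean
                row[f"{metric}_nested_sd"] = sd
            row["nested_best"] = json.dumps(best.to_dict())
        rows.append(row)
        log.info(
            "CV %s: %s", modality,
            {k: (round(m, 4), round(s, 4)) for k, (m, s) in agg.items()},
        )
    report = pd.DataFrame(rows)
    report.to_csv(Path(config.out_dir) / "cv_report.tsv", sep="\t", index=False)
    return report


def stage_predict_bag(config: RunConfig) -> pd.DataFrame:
    """Predict patient ages with the trained models, apply the stored
    bias correction, and write the per-subject BAG table plus test-set
    metrics before/after correction (test_metrics.tsv)."""
    ds = _load_inputs(config, "patient")
    ages = ds.cohort.data["age"].to_numpy()
    out = Path(config.out_dir)
    bias_path = out / "bias_correction.json"
    if not bias_path.exists():
        raise FileNotFoundError(f"expected bias correction at {bias_path}; run train first")
    bias = json.loads(bias_path.read_text())
    bag_frames = []
    metric_rows = []
    for modality, ft in ds.features.items():
        model_dir = out / f"model_{modality.lower()}"
        model = brainage.load_model(model_dir)
        preds = brainage.predict_age(model, ft)
        bc = bias_bag.BiasCorrection(**bias[modality])
        table = bias_bag.bag_table(ft.subject_ids, ages, preds, bc, modality)
        bag_frames.append(table)
        raw = brainage.regression_metrics(preds, ages)
        corr = brainage.regression_metrics(
            table["corrected_predicted_age"].to_numpy(), ages
        )
        rcor = brainage.pearson_ci(table["corrected_predicted_age"].to_numpy(), ages)
        metric_rows.append(
            {
                "modality": modality,
                "n": ft.n_subjects,
                "r2_raw": raw[0], "rmse_raw": raw[1], "mae_raw": raw[2],
                "r2_corrected": corr[0], "rmse_corrected": corr[1],
                "mae_corrected": corr[2],
                "pearson_r": rcor.r, "r_ci_low": rcor.ci_low, "r_ci_high": rcor.ci_high,
            }
        )
    bag = pd.concat(bag_frames, ignore_index=True)
    bag.to_csv(out / "bag.tsv", sep="\t", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "test_metrics.tsv", sep="\t", index=False)
    return bag


def stage_compare(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Group comparisons (carriers vs non-carriers) for each configured
    analysis; writes one regression TSV per analysis."""
    ds = _load_inputs(config, "patient")
    ds.cohort.require_apoe()
    out = Path(config.out_dir)
    bag_path = out / "bag.tsv"
    data = ds.cohort.data.set_index("subject_id")
    if bag_path.exists():
        bag = pd.read_csv(bag_path, sep="\t")
        for modality in bag["modality"].unique():
            sub = bag[bag["modality"] == modality].set_index("subject_id")
            data[f"bag_{modality.lower()}"] = sub["bag"]
    reports = {}
    for analysis in config.analyses:
        if analysis == "bag":
            outcomes = sorted(c for c in data.columns if c.startswith("bag_"))
            if not outcomes:
                raise FileNotFoundError(
                    f"bag analysis requires {bag_path}; run the bag stage first"
                )
            frame = data
        else:
            modality = "DTI" if analysis == "dti" else "T1"
            ft = ds.features[modality]
            outcomes = ft.feature_names
            frame = data.join(
                ft.to_frame().set_index("subject_id"), how="inner"
            )
        table, fdr = inference.compare_groups(
            frame.reset_index(), outcomes, analysis=analysis, q=config.q
        )
        name = "bag_regression.tsv" if analysis == "bag" else f"roi_regression_{analysis}.tsv"
        table.to_csv(out / name, sep="\t", index=False)
        n_sig = sum(fdr.significant)
        log.info("%s analysis: %d outcomes, %d FDR-significant at Q=%.2g",
                 analysis, fdr.m, n_sig, config.q)
        reports[analysis] = table
    return reports


def stage_descriptives(config: RunConfig) -> pd.DataFrame:
    """Carrier vs non-carrier descriptive table (t-tests on continuous
    fields, chi-square on sex/head coil); writes descriptives.tsv."""
    ds = _load_inputs(config, "patient")
    ds.cohort.require_apoe()
    df = ds.cohort.data
    carrier = df["apoe_e4"] == 1
    rows = []
    numeric = ["age"] + [
        c for c in ds.cohort.clinical_fields
        if pd.api.types.is_numeric_dtype(df[c])
    ]
    for col in numeric:
        g1, g2 = df.loc[~carrier, col].dropna(), df.loc[carrier, col].dropna()
        res = inference.two_sample_t_summary(
            g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
        )
        rows.append(
            {
                "variable": col, "test": res.method,
                "noncarrier_mean": g1.mean(), "noncarrier_sd": g1.std(ddof=1),
                "carrier_mean": g2.mean(), "carrier_sd": g2.std(ddof=1),
                "statistic": res.statistic, "df": res.df, "p": res.p,
            }
        )
    for col in ("sex", "head_coil"):
        if col in df.columns:
            counts = pd.crosstab(df[col], carrier).to_numpy()
            res = inference.chi_square_test(counts)
            rows.append(
                {"variable": col, "test": res.method,
                 "statistic": res.statistic, "df": res.df, "p": res.p}
            )
    report = pd.DataFrame(rows)
    report.to_csv(Path(config.out_dir) / "descriptives.tsv", sep="\t", index=False)
    return report


def run_pipeline(config: RunConfig, cv_reps: int | None = None) -> Path:
    """Full run: simulate (if synthetic), train, CV, predict+BAG,
    descriptives, group comparisons.  Returns the report directory."""
    out = Path(config.out_dir)
    setup_logging(out)
    log.info("run config: %s", config)
    (out / "config_echo.json").write_text(
        json.dumps(dataclasses.asdict(config), default=str, indent=2)
    )
    stages: list[tuple[str, object]] = []
    if config.synthetic:
        stages.append(("simulate", lambda: stage_simulate(config)))
    stages += [
        ("train", lambda: stage_train(config)),
        ("cv", lambda: stage_cv(config, reps=cv_reps)),
        ("predict+bag", lambda: stage_predict_bag(config)),
        ("descriptives", lambda: stage_descriptives(config)),
        ("compare", lambda: stage_compare(config)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("pipeline complete; reports in %s", out)
    return out
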