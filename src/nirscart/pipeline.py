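"""End-to-end pipeline wiring: cohort -> preprocessing -> outlier rejection
-> fold-wise ensemble training -> location-averaged evaluation and reports.

Every stage persists its outputs into a run directory so stages can be
re-run independently; all randomness flows from the single pipeline seed
plus the fixed member seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NirscartError
from .cohort import (
    CohortConfig,
    CohortDataset,
    SpectralForwardParams,
    generate_cohort,
    save_cohort,
)
from .preprocess import PreprocessConfig, preprocess_matrix
from .profiles import TARGET_NAMES
from .outliers import (
    Ellipsoid,
    OutlierReport,
    PCAModel,
    fit_mvee,
    fit_pca,
    project,
    radius_sweep,
)
from .ensemble import (
    REDUCED_TRAIN_CONFIG,
    FoldPlan,
    TrainConfig,
    make_folds,
    train_ensemble,
    save_ensemble,
)
from . import evaluate as ev

log = logging.getLogger(__name__)


class ParseError(NirscartError, ValueError):
    pass


class StageError(NirscartError, RuntimeError):
    pass


DEFAULT_SWEEP_RADII = (75.0, 90.0, 100.0, 105.0, 125.0, 150.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of every stage plus the global seed.

    The training profile defaults to the epoch-reduced schedule so a full
    ten-pony run stays desk-scale; pass ``train=TrainConfig()`` for the full
    500-epoch protocol.
    """

    cohort: CohortConfig = CohortConfig()
    forward: SpectralForwardParams = SpectralForwardParams()
    preprocess: PreprocessConfig = PreprocessConfig()
    radius_pct: float = 105.0
    sweep_radii: tuple[float, ...] = DEFAULT_SWEEP_RADII
    mvee_tolerance: float = 1e-6
    train: TrainConfig = REDUCED_TRAIN_CONFIG
    seed: int = 42
    persist_spectra: bool = False
    persist_models: bool = False

    def __post_init__(self) -> None:
        if self.radius_pct <= 0:
            raise NirscartError("radius_pct must be positive")
        if not self.sweep_radii:
            raise NirscartError("sweep radii must be non-empty")

    def with_seed(self) -> "PipelineConfig":
        """Propagate the global seed into the cohort configuration."""
        return replace(self, cohort=replace(self.cohort, seed=self.seed))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class PipelineResult:
    """Everything a run computes, plus where it was written."""

    config: PipelineConfig
    run_dir: Path | None
    cohort: CohortDataset
    wavelengths: np.ndarray
    pca: PCAModel
    ellipsoid: Ellipsoid
    outlier_report: OutlierReport
    outlier_stats: dict
    fold_plans: dict[str, FoldPlan]
    references: pd.DataFrame
    predictions: pd.DataFrame          # location-level, all sets
    repeat_predictions: pd.DataFrame   # in-vivo per-repeat, for the sweep
    mahalanobis_sq: np.ndarray         # per in-vivo repeat
    report: pd.DataFrame
    sweep: pd.DataFrame
    group_stats: pd.DataFrame
    histories: pd.DataFrame


def _location_ids(meta: pd.DataFrame, latent: pd.DataFrame) -> np.ndarray:
    """Map repeat-level metadata rows to latent-table row indices."""
    key = CohortDataset.KEY_COLS
    idx = latent.reset_index().rename(columns={"index": "location_id"})
    merged = meta.merge(idx[key + ["location_id"]], on=key, how="left", sort=False)
    if merged["location_id"].isna().any():
        raise ParseError("metadata rows reference unknown locations")
    return merged["location_id"].to_numpy(dtype=int)


def references_table(latent: pd.DataFrame) -> pd.DataFrame:
    """Long-format reference table (target, location_id, reference)."""
    return latent.melt(
        id_vars=[], value_vars=list(TARGET_NAMES),
        var_name="target", value_name="reference", ignore_index=False,
    ).reset_index(names="location_id")


def plan_folds(latent: pd.DataFrame) -> dict[str, FoldPlan]:
    """Per-target rank-paired fold plans from pony-level target means."""
    plans = {}
    for target in TARGET_NAMES:
        pony_means = latent.groupby("pony_id")[target].mean().to_dict()
        plans[target] = make_folds(pony_means, target)
    return plans


def train_and_predict(
    latent: pd.DataFrame,
    meta_vitro: pd.DataFrame,
    x_vitro: np.ndarray,
    meta_vivo: pd.DataFrame,
    x_vivo: np.ndarray,
    inlier: np.ndarray,
    train_config: TrainConfig,
    fold_plans: dict[str, FoldPlan] | None = None,
    models_dir: Path | None = None,
) -> tuple[dict[str, FoldPlan], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Train every (target, fold) ensemble and collect all predictions.

    Returns (fold_plans, location-level predictions, in-vivo per-repeat
    predictions, training histories).  Calibration predictions are in-sample
    and pooled across folds; validation/test predictions come from the fold
    holding the pony out.  In-vivo location predictions average non-outlier
    repeats only.
    """
    if fold_plans is None:
        fold_plans = plan_folds(latent)
    loc_vitro = _location_ids(meta_vitro, latent)
    loc_vivo = _location_ids(meta_vivo, latent)
    pred_rows, repeat_rows, hist_rows = [], [], []
    t0 = time.perf_counter()
    for target in TARGET_NAMES:
        plan = fold_plans[target]
        y_by_loc = latent[target].to_numpy()
        for fold_id in range(plan.n_folds):
            cal_ponies = set(plan.calibration[fold_id])
            val_ponies = set(plan.validation[fold_id])
            cal_mask = meta_vitro["pony_id"].isin(cal_ponies).to_numpy()
            val_mask = meta_vitro["pony_id"].isin(val_ponies).to_numpy()
            model = train_ensemble(
                x_vitro[cal_mask], y_by_loc[loc_vitro[cal_mask]],
                x_vitro[val_mask], y_by_loc[loc_vitro[val_mask]],
                target=target, fold_id=fold_id, config=train_config,
            )
            for m in model.members:
                hist_rows.append(dict(
                    target=target, fold=fold_id, architecture=m.architecture,
                    seed=m.seed, epochs=len(m.history.val_rmse),
                    best_epoch=m.history.best_epoch,
                    best_val_rmse=float(np.min(m.history.val_rmse)),
                ))
            if models_dir is not None:
                save_ensemble(model, models_dir / f"{target}_fold{fold_id}")
            for mask, set_name in ((cal_mask, "calibration"),
                                   (val_mask, "validation")):
                p = model.predict(x_vitro[mask])
                df = pd.DataFrame({"location_id": loc_vitro[mask], "prediction": p})
                agg = df.groupby("location_id")["prediction"].mean()
                pred_rows.append(pd.DataFrame(dict(
                    target=target, set=set_name, fold=fold_id,
                    location_id=agg.index, prediction=agg.to_numpy())))
            test_mask = meta_vivo["pony_id"].isin(val_ponies).to_numpy()
            p_vivo = model.predict(x_vivo[test_mask])
            rep = pd.DataFrame(dict(
                target=target, fold=fold_id,
                location_id=loc_vivo[test_mask],
                repeat_row=np.flatnonzero(test_mask),
                prediction=p_vivo))
            repeat_rows.append(rep)
            keep = np.asarray(inlier, dtype=bool)[test_mask]
            agg = (rep.loc[keep].groupby("location_id")["prediction"].mean()
                   .reindex(np.unique(rep["location_id"])))
            pred_rows.append(pd.DataFrame(dict(
                target=target, set="test", fold=fold_id,
                location_id=agg.index, prediction=agg.to_numpy())))
        log.info("train: finished target %s (%.1fs cumulative)",
                 target, time.perf_counter() - t0)
    return (fold_plans, pd.concat(pred_rows, ignore_index=True),
            pd.concat(repeat_rows, ignore_index=True), pd.DataFrame(hist_rows))


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 run_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline; any stage failure names the stage."""
    config = config.with_seed()
    out = Path(run_dir) if run_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())

    stage = "generate"
    try:
        t0 = time.perf_counter()
        ds = generate_cohort(config.cohort, config.forward)
        log.info("generate: %d locations, %d in-vitro and %d in-vivo spectra (%.1fs)",
                 len(ds.latent), len(ds.in_vitro_meta), len(ds.in_vivo_meta),
                 time.perf_counter() - t0)
        if out is not None and config.persist_spectra:
            save_cohort(ds, out / "cohort")
        if out is not None:
            ds.latent.to_csv(out / "latent.csv", index=False)

        stage = "preprocess"
        t0 = time.perf_counter()
        wavelengths, x_vitro = preprocess_matrix(ds.in_vitro, ds.grids, config.preprocess)
        _, x_vivo = preprocess_matrix(ds.in_vivo, ds.grids, config.preprocess)
        log.info("preprocess: %d analysis wavelengths (%.1fs)",
                 wavelengths.size, time.perf_counter() - t0)
        if out is not None and config.persist_spectra:
            save_spectra(wavelengths, x_vitro, ds.in_vitro_meta, out / "in_vitro_pp.csv")
            save_spectra(wavelengths, x_vivo, ds.in_vivo_meta, out / "in_vivo_pp.csv")

        stage = "outliers"
        t0 = time.perf_counter()
        pca = fit_pca(x_vitro)
        scores_vivo = project(pca, x_vivo)
        ell = fit_mvee(project(pca, x_vitro), tolerance=config.mvee_tolerance)
        m2 = ell.mahalanobis_sq(scores_vivo)
        o_report = radius_sweep(ell, scores_vivo, config.sweep_radii, config.radius_pct)
        truth = ds.in_vivo_meta["artifact"].to_numpy(dtype=bool)
        flagged = ~o_report.inlier
        outlier_stats = {
            "n_in_vivo": int(truth.size),
            "n_true_artifacts": int(truth.sum()),
            "contamination_fraction": float(truth.mean()),
            "n_flagged": int(flagged.sum()),
            "sensitivity": float(flagged[truth].mean()) if truth.any() else float("nan"),
            "specificity": float((~flagged[~truth]).mean()),
            "radius_pct": config.radius_pct,
        }
        log.info("outliers: flagged %d/%d at radius %.0f%% (%.1fs)",
                 outlier_stats["n_flagged"], truth.size, config.radius_pct,
                 time.perf_counter() - t0)
        if out is not None:
            ell.to_json(out / "ellipsoid.json", tolerance=config.mvee_tolerance,
                        radius_pct=config.radius_pct)
            pd.DataFrame({"mahalanobis_sq": m2, "inlier": o_report.inlier,
                          "artifact_truth": truth}).to_csv(
                out / "outlier_flags.csv", index=False)
            o_report.to_frame().to_csv(out / "outlier_counts.csv", index=False)

        stage = "references"
        references = references_table(ds.latent)

        stage = "folds"
        fold_plans = plan_folds(ds.latent)
        if out is not None:
            (out / "folds.json").write_text(json.dumps(
                {t: {"validation": fp.validation, "calibration": fp.calibration}
                 for t, fp in fold_plans.items()}, indent=2, default=list))

        stage = "train"
        fold_plans, predictions, repeat_predictions, histories = train_and_predict(
            ds.latent, ds.in_vitro_meta, x_vitro, ds.in_vivo_meta, x_vivo,
            o_report.inlier, config.train, fold_plans,
            models_dir=(out / "models") if (out is not None and config.persist_models)
            else None,
        )
        if out is not None:
            predictions.to_csv(out / "predictions.csv", index=False)
            repeat_predictions.to_csv(out / "repeat_predictions.csv", index=False)
            histories.to_csv(out / "histories.csv", index=False)

        stage = "evaluate"
        report, sweep, group_stats = evaluate_run(
            ds.latent, predictions, repeat_predictions, m2, config.sweep_radii
        )
        if out is not None:
            report.to_csv(out / "report.csv", index=False)
            sweep.to_csv(out / "sweep.csv", index=False)
            group_stats.to_csv(out / "group_stats.csv", index=False)
            (out / "stats.json").write_text(json.dumps(outlier_stats, indent=2))
        return PipelineResult(
            config=config, run_dir=out, cohort=ds, wavelengths=wavelengths,
            pca=pca, ellipsoid=ell, outlier_report=o_report,
            outlier_stats=outlier_stats, fold_plans=fold_plans,
            references=references, predictions=predictions,
            repeat_predictions=repeat_predictions, mahalanobis_sq=m2,
            report=report, sweep=sweep, group_stats=group_stats,
            histories=histories,
        )
    except NirscartError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc


def evaluate_run(
    latent: pd.DataFrame,
    predictions: pd.DataFrame,
    repeat_predictions: pd.DataFrame,
    mahalanobis_sq: np.ndarray,
    sweep_radii=DEFAULT_SWEEP_RADII,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Metrics report, radius-sweep curves and group contrasts for a run."""
    references = references_table(latent)
    report = ev.evaluate_sets(predictions, references)
    target_ranges = {
        t: (float(g["reference"].min()), float(g["reference"].max()))
        for t, g in references.groupby("target")
    }
    sweep = ev.sweep_performance(
        sweep_radii, mahalanobis_sq, repeat_predictions, references, target_ranges
    )
    return report, sweep, _group_comparisons(latent)


def _group_comparisons(latent: pd.DataFrame) -> pd.DataFrame:
    """Experimental-vs-control Mann-Whitney tests of the measured targets,
    per location index (pooled over legs and site lines)."""
    rows = []
    for target in TARGET_NAMES:
        for location, grp in latent.groupby("location"):
            exp = grp.loc[grp["group"] == "experimental", target]
            ctrl = grp.loc[grp["group"] == "control", target]
            if exp.empty or ctrl.empty:
                continue
            rows.append(dict(
                target=target, location=int(location),
                p_value=ev.compare_groups(exp, ctrl),
                mean_experimental=float(exp.mean()),
                mean_control=float(ctrl.mean()),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectra persistence with schema validation

_META_PREFIX = ("pony_id", "group", "leg", "site", "location", "repeat", "artifact")


def save_spectra(wavelengths: np.ndarray, values: np.ndarray,
                 meta: pd.DataFrame, path: str | Path) -> Path:
    """Preprocessed spectra as CSV: metadata columns then one column per
    wavelength (um, 6 decimals)."""
    path = Path(path)
    wl_cols = [f"w_{w:.6f}" for w in wavelengths]
    df = pd.concat(
        [meta.reset_index(drop=True),
         pd.DataFrame(np.asarray(values), columns=wl_cols)], axis=1
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_spectra(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Load spectra saved by :func:`save_spectra`; validates the schema and
    reports malformed rows by line number."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    wl_cols = [c for c in df.columns if c.startswith("w_")]
    if not wl_cols:
        raise ParseError(f"{path}: no wavelength columns (header 'w_<um>')")
    values = df[wl_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    if bad.size:
        # +2: header line and 1-based numbering
        raise ParseError(f"{path}: non-numeric or missing intensity at line {bad[0] + 2}")
    wavelengths = np.array([float(c[2:]) for c in wl_cols])
    meta = df[[c for c in df.columns if not c.startswith("w_")]]
    return meta, wavelengths, values
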