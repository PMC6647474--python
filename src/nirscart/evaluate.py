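"""Location-averaged evaluation: correlations, errors, group comparisons.

Predictions are aggregated per measurement location (mean over in-vitro
repeats, or over non-outlier in-vivo repeats) and compared to the reference
values with Spearman's rank correlation, RMSE, and NRMSE (RMSE as a percent
of the reference value range).  Group contrasts use the two-sided
Mann-Whitney U test (exact enumeration for small samples), paired
measured-vs-predicted contrasts the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import NirscartError

log = logging.getLogger(__name__)

SETS = ("calibration", "validation", "test")


class UndefinedCorrelationError(NirscartError, ValueError):
    pass


class DegenerateNormalizationError(NirscartError, ValueError):
    pass


class ProvenanceError(NirscartError, ValueError):
    pass


def aggregate_by_location(
    repeat_predictions: np.ndarray, inlier_flags: np.ndarray | None = None
) -> float:
    """Mean prediction over the inlier repeats of one location.

    Returns NaN (with a warning) when every repeat is flagged as an outlier;
    such locations are excluded from metrics downstream.
    """
    p = np.asarray(repeat_predictions, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one repeat prediction")
    if inlier_flags is None:
        return float(p.mean())
    keep = np.asarray(inlier_flags, dtype=bool)
    if not keep.any():
        log.warning("all repeats of a location are outliers; prediction is missing")
        return float("nan")
    return float(p[keep].mean())


def spearman(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedCorrelationError("need >= 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def rmse(pred, ref) -> float:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    keep = np.isfinite(pred) & np.isfinite(ref)
    return float(np.sqrt(np.mean((pred[keep] - ref[keep]) ** 2)))


def nrmse(rmse_value: float, ref_min: float, ref_max: float) -> float:
    """RMSE normalized by the reference value range, in percent."""
    if ref_max <= ref_min:
        raise DegenerateNormalizationError("reference range must be positive")
    return 100.0 * rmse_value / (ref_max - ref_min)


@dataclass(frozen=True)
class MetricSet:
    spearman_rho: float
    rmse: float
    nrmse: float  # percent

    def __post_init__(self) -> None:
        if np.isfinite(self.spearman_rho) and not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("rho out of range")


def metric_set(pred, ref, ref_min: float, ref_max: float) -> MetricSet:
    e = rmse(pred, ref)
    return MetricSet(spearman(pred, ref), e, nrmse(e, ref_min, ref_max))


def evaluate_sets(predictions: pd.DataFrame, references: pd.DataFrame) -> pd.DataFrame:
    """Table of per-target, per-set metrics from location-level predictions.

    ``predictions`` needs columns (target, set, location_id, fold, prediction);
    ``references`` columns (target, location_id, reference).  Validation and
    test rows must cover each location exactly once (the fold holding out the
    location's pony); calibration rows are in-sample and pooled across folds.
    NRMSE is normalized by each target's overall reference range.
    """
    for s in ("validation", "test"):
        sub = predictions[predictions["set"] == s]
        dup = sub.groupby(["target", "location_id"]).size()
        if (dup > 1).any():
            raise ProvenanceError(
                f"{s} pooling predicts some locations more than once"
            )
    merged = predictions.merge(references, on=["target", "location_id"], how="left")
    rows = []
    for (target, set_name), grp in merged.groupby(["target", "set"], sort=False):
        t_ref = references.loc[references["target"] == target, "reference"]
        m = metric_set(
            grp["prediction"].to_numpy(),
            grp["reference"].to_numpy(),
            float(t_ref.min()),
            float(t_ref.max()),
        )
        rows.append(
            dict(
                target=target,
                set=set_name,
                n=int(grp["prediction"].notna().sum()),
                spearman_rho=m.spearman_rho,
                rmse=m.rmse,
                nrmse=m.nrmse,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric group comparisons

_EXACT_MW_LIMIT = 20


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Handles ties through mid-ranks; p is the fraction of assignments whose U
    statistic lies at least as far from its mean as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    idx = range(pooled.size)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * y.size / 2.0
    hits = total = 0
    for comb in combinations(idx, n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def compare_groups(values_exp, values_ctrl) -> float:
    """Two-sided Mann-Whitney U p-value for an experimental/control contrast.

    Exact enumeration when the combined sample is small (n <= 20), the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(values_exp, dtype=float)
    y = np.asarray(values_ctrl, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= _EXACT_MW_LIMIT:
        return float(_mannwhitney_exact(x, y))
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def compare_paired(measured, predicted) -> float:
    """Two-sided Wilcoxon signed-rank p-value for measured vs predicted.

    Zero differences are dropped (signed-rank convention); if every pair is
    tied the test is degenerate and p = 1 is returned with a warning.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    keep = np.isfinite(m) & np.isfinite(p)
    d = m[keep] - p[keep]
    if d.size == 0:
        raise ValueError("no finite pairs")
    if np.all(d == 0):
        log.warning("all paired differences are zero; Wilcoxon test degenerate, p=1")
        return 1.0
    nz = d[d != 0]
    method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method=method).pvalue
        )


def sweep_performance(
    radii_pct,
    mahalanobis_sq: np.ndarray,
    repeat_predictions: pd.DataFrame,
    references: pd.DataFrame,
    target_ranges: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Test-set metrics as a function of the relative ellipsoid radius.

    ``mahalanobis_sq`` holds the squared ellipsoid distance of each in-vivo
    repeat (aligned with ``repeat_predictions`` rows, which need columns
    target, location_id, repeat_row, prediction).  Per radius, repeats inside
    the scaled ellipsoid are averaged per location and metrics recomputed;
    the summary averages RMSE on range-scaled values and Spearman's rho
    across targets, and counts excluded repeats.

    Two variants of each metric are reported.  The plain columns use every
    location that retains at least one inlier repeat at that radius, so the
    evaluated location set changes with the radius; the ``*_common`` columns
    restrict every radius to the locations that survive at the tightest
    swept radius, the fixed-support comparison that isolates how rejection
    affects prediction quality from which locations happen to survive
    (shrinking radii preferentially drop locations at the edge of the
    calibration range, which are also the hardest to predict).
    """
    rows = []
    m2 = np.asarray(mahalanobis_sq, dtype=float)
    ref_by_target = {
        t: g.set_index("location_id")["reference"] for t, g in references.groupby("target")
    }
    tightest = min(radii_pct)
    common_inlier = m2 <= (tightest / 100.0) ** 2
    common_locs = {
        target: set(
            grp.loc[common_inlier[grp["repeat_row"].to_numpy()], "location_id"]
        )
        for target, grp in repeat_predictions.groupby("target")
    }
    for r in radii_pct:
        inlier = m2 <= (r / 100.0) ** 2
        scaled_rmses, rhos = [], []
        scaled_rmses_common, rhos_common = [], []
        for target, grp in repeat_predictions.groupby("target"):
            keep = inlier[grp["repeat_row"].to_numpy()]
            agg = grp.loc[keep].groupby("location_id")["prediction"].mean()
            ref = ref_by_target[target].reindex(agg.index)
            lo, hi = target_ranges[target]
            scaled_rmses.append(rmse(agg.to_numpy(), ref.to_numpy()) / (hi - lo))
            rhos.append(spearman(agg.to_numpy(), ref.to_numpy()))
            agg_c = agg[agg.index.isin(common_locs[target])]
            ref_c = ref_by_target[target].reindex(agg_c.index)
            scaled_rmses_common.append(
                rmse(agg_c.to_numpy(), ref_c.to_numpy()) / (hi - lo))
            rhos_common.append(spearman(agg_c.to_numpy(), ref_c.to_numpy()))
        rows.append(
            dict(
                radius_pct=float(r),
                avg_scaled_rmse=float(np.mean(scaled_rmses)),
                avg_spearman_rho=float(np.mean(rhos)),
                avg_scaled_rmse_common=float(np.mean(scaled_rmses_common)),
                avg_spearman_rho_common=float(np.mean(rhos_common)),
                n_outliers=int((~inlier).sum()),
            )
        )
    return pd.DataFrame(rows)
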