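"""Statistical linkage between model quantities and communicativeness ratings.

Effect sizes are reported as Pearson correlations with 95% percentile
bootstrap confidence intervals (resampling paths, the unit of analysis).
Model scores are put on the rating scale by ordinary least squares
("calibration"), disagreement is summarized per movement class as the mean
signed residual, and the gain in correlation from excluding a chosen path
subset is tested against a Monte-Carlo null of equally sized random
exclusions.  All resampling is seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "CalibrationFit",
    "PermutationResult",
    "pearson_bootstrap",
    "calibrate_linear",
    "slope_bootstrap",
    "crossed_slope_bootstrap",
    "correlation_increase_permutation",
    "class_discrepancy",
    "repetition_trend",
    "path_mean_ratings",
]


def path_mean_ratings(judgments: pd.DataFrame, condition: Optional[str] = None) -> pd.Series:
    """Per-path mean rating from a participant x path judgment table."""
    df = judgments
    if condition is not None:
        df = df[df["condition"] == condition]
    return df.groupby("path_id")["rating"].mean()


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paths")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return x, y


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for paired (B, n) resample matrices."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self):
        assert -1.0 <= self.ci_low <= self.r + 1e-12
        assert self.r - 1e-12 <= self.ci_high <= 1.0


def pearson_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation with a 95% percentile bootstrap CI over paths.

    Pairs (x_i, y_i) are resampled with replacement; degenerate resamples
    (constant x or y) are dropped from the percentile computation.
    """
    x, y = _validate_pair(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = _pearson_rows(x[idx], y[idx])
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    # percentile CIs can exclude the point estimate in tiny samples; clamp
    # so the interval always brackets r
    return CorrelationResult(
        r=r, ci_low=float(min(lo, r)), ci_high=float(max(hi, r)), n_boot=n_boot, seed=seed
    )


@dataclass(frozen=True)
class CalibrationFit:
    """OLS of mean ratings on model scores (rating units per score unit)."""

    slope: float
    intercept: float
    fitted: np.ndarray

    def predict(self, scores) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(scores, dtype=float)


def calibrate_linear(scores: Sequence[float], ratings: Sequence[float]) -> CalibrationFit:
    """Linear transform putting model scores on the Likert rating scale."""
    x, y = _validate_pair(scores, ratings)
    fit = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fitted=fit.intercept + fit.slope * x,
    )


def slope_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """OLS slope of y on x with a 95% percentile bootstrap CI over pairs."""
    x, y = _validate_pair(x, y)
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.sum(xc * ys, axis=1) / np.sum(xc**2, axis=1)
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return float(fit.slope), float(lo), float(hi)


def crossed_slope_bootstrap(
    judgments: pd.DataFrame,
    predictor: Mapping,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Slope of path-mean ratings on a standardized per-path predictor, with
    a 95% CI from a crossed (participants x paths) percentile bootstrap.

    In a fully crossed design both factors are sampled — participants from a
    population of raters, paths from a large path space — so both variance
    components belong in the interval; resampling either factor alone
    under-covers.  ``predictor`` maps path_id to its predictor value.

    Returns (slope, ci_low, ci_high) in rating units per predictor SD.
    """
    wide = judgments.pivot_table(index="participant", columns="path_id", values="rating")
    paths = list(wide.columns)
    x = np.array([predictor[p] for p in paths], dtype=float)
    if x.std() == 0:
        raise ValueError("constant predictor")
    z = (x - x.mean()) / x.std()
    ratings = wide.to_numpy()  # (n_participants, n_paths)
    n_sub, n_path = ratings.shape
    means = ratings.mean(axis=0)
    zc = z - z.mean()
    slope = float(np.sum(zc * means) / np.sum(zc * zc))
    rng = np.random.default_rng(seed)
    pi = rng.integers(0, n_path, size=(n_boot, n_path))
    qi = rng.integers(0, n_sub, size=(n_boot, n_sub))
    res = ratings[qi]  # (B, n_sub, n_path)
    res = np.take_along_axis(res, pi[:, None, :], axis=2).mean(axis=1)  # (B, n_path)
    zb = z[pi]
    zbc = zb - zb.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.sum(zbc * res, axis=1) / np.sum(zbc * zbc, axis=1)
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return slope, float(lo), float(hi)


@dataclass(frozen=True)
class PermutationResult:
    delta_r_observed: float
    p_value: float
    n_perm: int
    seed: int
    excluded: tuple
    exhaustive: bool = False

    def __post_init__(self):
        assert 1.0 / (self.n_perm + 1) - 1e-12 <= self.p_value <= 1.0


def correlation_increase_permutation(
    scores: Sequence[float],
    ratings: Sequence[float],
    excluded_ids: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
    path_ids: Optional[Sequence] = None,
) -> PermutationResult:
    """Test whether excluding a chosen path subset increases the correlation
    more than excluding random subsets of the same size.

    The observed statistic is Delta r = r(without excluded) - r(all).  The
    null resamples equally sized exclusion subsets uniformly (exhaustively
    when there are at most ``n_perm`` such subsets) and the p-value uses the
    add-one estimator p = (1 + #{Delta_null >= Delta_obs}) / (n_perm + 1).
    """
    x, y = _validate_pair(scores, ratings)
    n = x.size
    if path_ids is None:
        path_ids = np.arange(n)
    path_ids = np.asarray(path_ids, dtype=object)
    id_to_pos = {pid: i for i, pid in enumerate(path_ids)}
    try:
        excl = np.array([id_to_pos[e] for e in excluded_ids], dtype=int)
    except KeyError as e:
        raise ValueError(f"excluded id {e} not among path ids") from None
    k = excl.size
    if k == 0 or n - k < 3:
        raise ValueError("exclusion must leave at least 3 paths")
    r_all = float(stats.pearsonr(x, y).statistic)

    def _delta(mask_out: np.ndarray) -> float:
        keep = np.setdiff1d(np.arange(n), mask_out)
        return float(stats.pearsonr(x[keep], y[keep]).statistic) - r_all

    delta_obs = _delta(excl)
    n_subsets = math.comb(n, k)
    if n_subsets <= n_perm:
        drop = np.array(list(combinations(range(n), k)))
        n_eff = n_subsets
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        drop = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        n_eff = drop.shape[0]
        exhaustive = False
    keep_masks = np.ones((drop.shape[0], n), dtype=bool)
    np.put_along_axis(keep_masks, drop, False, axis=1)
    kept = np.argsort(~keep_masks, axis=1, kind="stable")[:, : n - k]
    deltas = _pearson_rows(x[kept], y[kept]) - r_all
    p = (1.0 + np.sum(deltas >= delta_obs - 1e-12)) / (n_eff + 1.0)
    return PermutationResult(
        delta_r_observed=delta_obs,
        p_value=float(p),
        n_perm=n_eff,
        seed=seed,
        excluded=tuple(excluded_ids),
        exhaustive=exhaustive,
    )


def class_discrepancy(
    calibration: CalibrationFit,
    ratings: Sequence[float],
    classes: Sequence[str],
) -> dict[str, float]:
    """Mean signed residual (fitted - mean rating) per movement class.

    Positive values mean the model saw the class as more communicative than
    participants did; negative values the reverse.  Classes with no paths
    are omitted with a warning.
    """
    y = np.asarray(ratings, dtype=float)
    fitted = np.asarray(calibration.fitted, dtype=float)
    classes = np.asarray(classes, dtype=object)
    if not (y.shape == fitted.shape == classes.shape):
        raise ValueError("ratings, fitted values and classes must align")
    out: dict[str, float] = {}
    for label in pd.unique(classes):
        m = classes == label
        out[str(label)] = float(np.mean(fitted[m] - y[m]))
    return out


def repetition_trend(ratings_by_repetition: Mapping[int, object]) -> float:
    """OLS slope of path-mean rating on repetition count (rating units per
    repetition) — the simple-trend analogue of the repetition effect.

    Values may be scalars (one mean per level) or sequences of path means.
    """
    if len(ratings_by_repetition) < 2:
        raise ValueError("need at least two repetition levels")
    k, m = [], []
    for rep, vals in sorted(ratings_by_repetition.items()):
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        k.extend([float(rep)] * vals.size)
        m.extend(vals.tolist())
    return float(stats.linregress(np.array(k), np.array(m)).slope)
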