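"""Accuracy metrics, cross-validation protocol, and error-predictability fits.

Reconstruction accuracy is the position-displacement RMSE: the root mean
square of each ground-truth point's distance to its nearest neighbor in the
reconstructed shape (one-sided, ground truth -> reconstruction).  Because
reconstruction error falls off with how much of the scalp was swept, the
RMSE-vs-trajectory-length relationship is summarized with regression models
(exponential decay ``a*exp(b*x) + c`` or polynomials of degree 3-7) whose
goodness of fit is scored with Pearson's chi-squared statistic over 200 mm
length bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .mesh_core import PointCloud, nearest_neighbors

__all__ = [
    "ErrorModelFit",
    "BinnedErrors",
    "ErrorModelRegressor",
    "position_rmse",
    "segment_cross_validation",
    "fit_error_model",
    "pearson_chi_squared",
    "binned_confidence_intervals",
    "BIN_WIDTH_MM",
]

BIN_WIDTH_MM = 200.0


@dataclass
class ErrorModelFit:
    family: str                      # "exp_decay" | "polynomial"
    degree: Optional[int]
    coefficients: np.ndarray         # (a, b, c) or (a_0 ... a_m)
    chi_squared: float
    n_points: int
    # polynomials are fit on a rescaled abscissa for conditioning; the
    # coefficients above refer to x mapped from `domain` onto [-1, 1]
    domain: Optional[np.ndarray] = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.family == "exp_decay":
            a, b, c = self.coefficients
            return a * np.exp(b * x) + c
        poly = np.polynomial.Polynomial(
            self.coefficients,
            domain=self.domain if self.domain is not None else [-1, 1],
        )
        return poly(x)


@dataclass
class BinnedErrors:
    bin_centers: np.ndarray
    means: np.ndarray
    ci95: np.ndarray                 # half-widths, 1.96 * SEM
    counts: np.ndarray
    single_point_bins: np.ndarray    # flags: half-width 0 by convention


def position_rmse(ground_truth: PointCloud, reconstructed: PointCloud) -> float:
    """RMSE over per-ground-truth-point nearest-neighbor distances (mm)."""
    _, d = nearest_neighbors(ground_truth, reconstructed)
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# segment cross-validation (the lab protocol)


def _segment_points(trajectories, n_segments: int):
    """Cut the pooled ordered samples into contiguous equal-count segments,
    tagged with hemisphere (lateral sign) and arc-position strata."""
    pts = np.concatenate([t.points for t in trajectories])
    if len(pts) < n_segments:
        raise ValueError("not enough points for the requested segments")
    bounds = np.linspace(0, len(pts), n_segments + 1).astype(int)
    segments = [pts[bounds[i] : bounds[i + 1]] for i in range(n_segments)]
    center = pts.mean(axis=0)
    hemis = np.array([int(np.median(s[:, 0] - center[0]) >= 0) for s in segments])
    backfront = np.array([float(np.median(s[:, 1] - center[1])) for s in segments])
    strata = np.digitize(backfront, np.quantile(backfront, [0.25, 0.5, 0.75]))
    return segments, hemis, strata


def segment_cross_validation(
    trajectories: Sequence,
    fit_fn: Callable[[np.ndarray], PointCloud],
    n_segments: int = 20,
    train_fraction: float = 0.75,
    n_repeats: int = 10,
    seed: int = 0,
):
    """Per-repeat held-out RMSE of reconstructions fit on partial trajectories.

    The pooled samples are cut into ``n_segments`` contiguous equal-count
    segments; each repeat holds out ``1 - train_fraction`` of them (selection
    stratified so the held-out set spans both hemispheres and several head
    regions, falling back to an unstratified draw when infeasible), fits on
    the training points via ``fit_fn`` and scores the held-out points against
    the returned reconstruction.

    Returns a dict with per-repeat ``rmse`` values, their mean/SD, the splits
    used, and a ``stratified`` flag per repeat.
    """
    segments, hemis, strata = _segment_points(trajectories, n_segments)
    n_test = max(1, int(round(n_segments * (1 - train_fraction))))
    rng = np.random.default_rng(seed)
    rmses, splits, strat_flags = [], [], []
    for _ in range(n_repeats):
        chosen = None
        stratified = False
        for _attempt in range(100):
            cand = rng.choice(n_segments, size=n_test, replace=False)
            if len(set(hemis[cand])) == min(2, len(set(hemis))) and len(
                set(strata[cand])
            ) >= min(3, len(set(strata))):
                chosen = np.sort(cand)
                stratified = True
                break
        if chosen is None:
            chosen = np.sort(rng.choice(n_segments, size=n_test, replace=False))
        test_mask = np.zeros(n_segments, dtype=bool)
        test_mask[chosen] = True
        train = np.concatenate([s for i, s in enumerate(segments) if not test_mask[i]])
        test = np.concatenate([s for i, s in enumerate(segments) if test_mask[i]])
        recon = fit_fn(train)
        rmses.append(position_rmse(PointCloud(test), recon))
        splits.append(chosen)
        strat_flags.append(stratified)
    rmses = np.asarray(rmses)
    return {
        "rmse": rmses,
        "mean": float(rmses.mean()),
        "sd": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
        "splits": splits,
        "stratified": np.asarray(strat_flags),
    }


# ---------------------------------------------------------------------------
# error-vs-length regression


class ErrorModelRegressor(BaseEstimator, RegressorMixin):
    """RMSE-vs-trajectory-length regression.

    Parameters
    ----------
    family : "exp_decay" or "polynomial"
    degree : polynomial degree (3-7 in the study protocol)
    n_starts : multi-start count for the nonlinear exponential fit

    Attributes after ``fit``: ``coefficients_``, ``chi_squared_`` (Pearson
    statistic over 200 mm binned means), ``fit_``.
    """

    def __init__(self, family: str = "exp_decay", degree: int = 3, n_starts: int = 8):
        self.family = family
        self.degree = degree
        self.n_starts = n_starts

    def fit(self, X, y):
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if self.family == "polynomial":
            n_coef = self.degree + 1
        elif self.family == "exp_decay":
            n_coef = 3
        else:
            raise ValueError("family must be 'exp_decay' or 'polynomial'")
        if len(x) <= n_coef:
            raise ValueError("need more points than coefficients")

        domain = None
        if self.family == "polynomial":
            poly = np.polynomial.Polynomial.fit(x, y, self.degree)
            coef = poly.coef
            domain = np.asarray(poly.domain)
        else:
            coef = self._fit_exp(x, y)
        self.coefficients_ = coef
        model = ErrorModelFit(self.family,
                              self.degree if self.family == "polynomial" else None,
                              coef, np.nan, len(x), domain)
        # goodness of fit: binned mean RMSE vs the model at each bin's mean
        # observed length (partially filled edge bins would otherwise force
        # the model to extrapolate outside the data's support)
        idx = np.floor(x / BIN_WIDTH_MM).astype(int)
        observed, abscissa = [], []
        for b in np.unique(idx):
            sel = idx == b
            observed.append(y[sel].mean())
            abscissa.append(x[sel].mean())
        expected = model.predict(np.asarray(abscissa))
        if np.all(expected > 0):
            model.chi_squared = pearson_chi_squared(np.asarray(observed), expected)
        self.chi_squared_ = model.chi_squared
        self.fit_ = model
        return self

    def _fit_exp(self, x, y):
        span = max(x.max() - x.min(), 1e-9)
        amp = y.max() - y.min()
        starts = [
            (amp if amp > 0 else 1.0, -rate / span, y.min())
            for rate in (1.0, 3.0, 10.0, 30.0)
        ]
        starts += [(y.max(), -1.0 / span, 0.0), (1.0, -1e-3, float(np.mean(y)))]
        starts = starts[: max(self.n_starts, 1)]
        best = None
        errors = []
        for p0 in starts:
            try:
                popt, _ = curve_fit(
                    lambda t, a, b, c: a * np.exp(b * t) + c,
                    x, y, p0=p0, maxfev=20000,
                )
                r = float(np.sum((y - (popt[0] * np.exp(popt[1] * x) + popt[2])) ** 2))
                if np.all(np.isfinite(popt)) and (best is None or r < best[0]):
                    best = (r, popt)
            except RuntimeError as err:  # no convergence from this start
                errors.append(str(err))
        if best is None:
            raise RuntimeError(
                "exponential-decay fit failed from every start: " + "; ".join(errors)
            )
        return np.asarray(best[1])

    def predict(self, X):
        return self.fit_.predict(np.asarray(X, dtype=np.float64).reshape(-1))


def fit_error_model(
    lengths, rmses, family: str = "exp_decay", degree: int = 3
) -> ErrorModelFit:
    """Functional wrapper around :class:`ErrorModelRegressor`."""
    return ErrorModelRegressor(family=family, degree=degree).fit(lengths, rmses).fit_


def pearson_chi_squared(observed, expected) -> float:
    """``sum (O_i - E_i)^2 / E_i``; expected values must be positive."""
    o = np.asarray(observed, dtype=np.float64).reshape(-1)
    e = np.asarray(expected, dtype=np.float64).reshape(-1)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(e <= 0):
        raise ValueError("expected values must be positive")
    return float(np.sum((o - e) ** 2 / e))


def binned_confidence_intervals(
    lengths, rmses, bin_width: float = BIN_WIDTH_MM
) -> BinnedErrors:
    """Per-bin mean RMSE with normal-approximation 95% CIs (1.96 * SEM).

    Bins are ``bin_width`` wide starting at bin_width/2 below the first
    populated multiple of ``bin_width`` (i.e. centered on 300, 500, ... for
    the default width).  Empty bins are dropped; single-point bins get a
    zero half-width and are flagged.
    """
    x = np.asarray(lengths, dtype=np.float64).reshape(-1)
    y = np.asarray(rmses, dtype=np.float64).reshape(-1)
    if x.shape != y.shape or len(x) == 0:
        raise ValueError("lengths and rmses must be equal-length and non-empty")
    idx = np.floor(x / bin_width).astype(int)
    centers, means, ci, counts, singles = [], [], [], [], []
    for b in np.unique(idx):
        sel = idx == b
        vals = y[sel]
        centers.append((b + 0.5) * bin_width)
        means.append(vals.mean())
        counts.append(sel.sum())
        if len(vals) > 1:
            ci.append(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
            singles.append(False)
        else:
            ci.append(0.0)
            singles.append(True)
    return BinnedErrors(
        np.asarray(centers), np.asarray(means), np.asarray(ci),
        np.asarray(counts), np.asarray(singles),
    )
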