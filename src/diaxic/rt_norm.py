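"""Retention-time calibration between library scale and run scale.

A random sample of endogenous (target) library precursors is scanned across
the whole gradient with the representation model; the cycle with maximal
dds is the anchor for that precursor. A robust regression then maps library
normalized RT to run seconds: RANSAC for the linear model, LOWESS with a
MAD-based outlier pass for the nonlinear one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression, RANSACRegressor
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from . import deep_rep, rsm as _rsm
from .raw_io import RunData

__all__ = ["RTAnchor", "RTModel", "select_anchors", "fit_rt_model", "predict_rt"]

MIN_ANCHORS_LINEAR = 10
MIN_ANCHORS_LOWESS = 30
DEFAULT_N_SAMPLE = 500
DEFAULT_DDS_MIN = 0.5


@dataclass
class RTAnchor:
    normalized_rt: float
    best_cycle: int
    best_rt_s: float
    dds: float


@dataclass
class RTModel:
    """Fitted library-RT -> run-RT map with its inlier bookkeeping."""

    kind: str                        # "linear" | "lowess"
    slope: float | None
    intercept: float | None
    curve_x: np.ndarray | None       # lowess support points (library RT)
    curve_y: np.ndarray | None       # lowess fitted seconds
    inlier_mask: np.ndarray
    residual_scale: float            # MAD of inlier residuals, seconds

    def predict_seconds(self, normalized_rt) -> np.ndarray:
        x = np.atleast_1d(np.asarray(normalized_rt, dtype=np.float64))
        if self.kind == "linear":
            return self.slope * x + self.intercept
        # lowess: linear interpolation, clamped at the anchor range
        return np.interp(x, self.curve_x, self.curve_y)


def select_anchors(
    run: RunData,
    library,
    model: deep_rep.RepresentationModel,
    n_sample: int = DEFAULT_N_SAMPLE,
    seed: int = 0,
    params: _rsm.RSMParams | None = None,
    dds_min: float = DEFAULT_DDS_MIN,
) -> list[RTAnchor]:
    """Best-dds cycle per sampled target precursor, across the gradient.

    Decoys are never sampled. Anchors below ``dds_min`` are dropped so the
    regression does not fit noise.
    """
    params = params or _rsm.RSMParams()
    targets = [e for e in library if not e.is_decoy]
    rng = np.random.default_rng(seed)
    if n_sample > len(targets):
        warnings.warn(
            f"n_sample={n_sample} exceeds the {len(targets)} library targets; "
            "using all of them"
        )
        n_sample = len(targets)
    picked = [targets[i] for i in sorted(
        rng.choice(len(targets), size=n_sample, replace=False)
    )]

    centers = np.arange(run.n_cycles)
    traces = _rsm.extract_traces_for_entries(run, picked, params)
    anchors = []
    for entry, tr in zip(picked, traces):
        aw = _rsm.assemble_windows(tr, centers, params)
        _, dds = deep_rep.embed_batch(
            model, _rsm.normalize_matrices(aw.matrices)
        )
        if dds.max() < dds_min:
            continue
        # dds plateaus over windows that still contain the peak; localize the
        # apex within the near-maximal plateau by the library-block intensity
        # at the window's center column (maximal exactly at the elution apex)
        plateau = np.flatnonzero(dds >= dds.max() - 0.02)
        center_signal = aw.lib_block[:, :, params.center_offset].sum(axis=1)
        best = int(plateau[np.argmax(center_signal[plateau])])
        anchors.append(RTAnchor(
            normalized_rt=entry.normalized_rt,
            best_cycle=best,
            best_rt_s=float(run.rt_per_cycle[best]),
            dds=float(dds[best]),
        ))
    return anchors


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def fit_rt_model(anchors, kind: str = "linear", seed: int = 0) -> RTModel:
    """Fit the robust calibration model on (normalized_rt, run-seconds) anchors."""
    x = np.array([a.normalized_rt for a in anchors])
    y = np.array([a.best_rt_s for a in anchors])
    if kind == "linear":
        if len(anchors) < MIN_ANCHORS_LINEAR:
            raise ValueError(
                f"linear RT fit needs >= {MIN_ANCHORS_LINEAR} anchors, "
                f"got {len(anchors)}"
            )
        # residual threshold from a preliminary ordinary least-squares fit
        pre = LinearRegression().fit(x[:, None], y)
        resid = y - pre.predict(x[:, None])
        thr = max(2.5 * _mad(resid), 1e-9)
        ransac = RANSACRegressor(
            estimator=LinearRegression(),
            residual_threshold=thr,
            max_trials=100,
            random_state=seed,
        ).fit(x[:, None], y)
        inliers = ransac.inlier_mask_
        est = ransac.estimator_
        final_resid = (y - est.predict(x[:, None]))[inliers]
        return RTModel(
            kind="linear",
            slope=float(est.coef_[0]),
            intercept=float(est.intercept_),
            curve_x=None, curve_y=None,
            inlier_mask=inliers,
            residual_scale=_mad(final_resid),
        )
    if kind == "lowess":
        if len(anchors) < MIN_ANCHORS_LOWESS:
            raise ValueError(
                f"lowess RT fit needs >= {MIN_ANCHORS_LOWESS} anchors, "
                f"got {len(anchors)}"
            )
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        fit0 = _lowess(ys, xs, frac=0.3, it=2, return_sorted=False)
        resid = ys - fit0
        keep = np.abs(resid - np.median(resid)) <= max(3.0 * _mad(resid), 1e-9)
        fit1 = _lowess(ys[keep], xs[keep], frac=0.3, it=2, return_sorted=False)
        inliers = np.zeros(len(anchors), dtype=bool)
        inliers[order[keep]] = True
        return RTModel(
            kind="lowess",
            slope=None, intercept=None,
            curve_x=xs[keep], curve_y=fit1,
            inlier_mask=inliers,
            residual_scale=_mad(ys[keep] - fit1),
        )
    raise ValueError(f"kind must be 'linear' or 'lowess', got {kind!r}")


def predict_rt(model: RTModel, normalized_rt: float, run: RunData) -> int:
    """Predicted run RT for a library precursor, as the nearest cycle index."""
    sec = float(model.predict_seconds(normalized_rt)[0])
    return int(np.abs(run.rt_per_cycle - sec).argmin())
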