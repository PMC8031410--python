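"""Occupancy model with false positives (certain/uncertain detections).

Observations take three codes: 0 (no detection), 1 (uncertain
detection — an eDNA positive with no corroborating dip-net catch) and
2 (certain detection — an eDNA positive at an event where the dip-net
caught the species).  Certain detections can only arise at occupied
sites, which is what separates the true-positive rate p11 from the
false-positive rate p10:

    occupied site:    f1(0) = 1 - p11,  f1(1) = p11 (1 - b),  f1(2) = p11 b
    unoccupied site:  f0(0) = 1 - p10,  f0(1) = p10,          f0(2) = 0

    L_i = psi_i * prod_j f1(y_ij) + (1 - psi_i) * prod_j f0(y_ij)

where b is the probability that a detection at an occupied site is
recorded as certain.  p10 is a single scalar — a contaminant or assay
artefact has no reason to track pool area or filtration method — while
p11 may carry logit-linked covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .datatypes import DetectionHistory
from .occupancy import (
    OccupancyModelSpec,
    _BOUNDARY_FLAG,
    _design_matrices,
    _multi_start_minimize,
)

__all__ = ["FPParams", "FPOccupancyModel", "negloglik_fp", "fit_fp"]


@dataclass(frozen=True)
class FPParams:
    """Probability-scale parameter set of the false-positive model."""

    psi: float
    p11: float
    p10: float
    b: float
    beta: np.ndarray | None = None   # covariate coefficients on logit p11


def _nll_fp_core(
    params: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    b_fixed: float | None,
) -> float:
    """Packed params: (alpha | beta | logit p10 [| logit b])."""
    ko, kd = W.shape[1], X.shape[2]
    alpha = params[:ko]
    beta = params[ko:ko + kd]
    p10 = expit(params[ko + kd])
    b = b_fixed if b_fixed is not None else expit(params[ko + kd + 1])
    psi = expit(W @ alpha)
    p11 = expit(X @ beta)

    y0 = (Y == 0.0) & mask
    y1 = (Y == 1.0) & mask
    y2 = (Y == 2.0) & mask
    with np.errstate(divide="ignore"):
        lf1 = np.where(y0, np.log1p(-p11), 0.0)
        lf1 = lf1 + np.where(y1, np.log(p11 * (1.0 - b)), 0.0)
        lf1 = lf1 + np.where(y2, np.log(p11 * b), 0.0)
        lf1 = lf1.sum(axis=1)
        lf0 = np.where(y0, np.log1p(-p10), 0.0).sum(axis=1) \
            + np.where(y1, np.log(p10), 0.0).sum(axis=1)
    has_certain = y2.any(axis=1)            # f0(2) = 0 kills the unoccupied branch
    occ = np.log(psi) + lf1
    unocc = np.where(has_certain, -np.inf, np.log1p(-psi) + lf0)
    ll = np.logaddexp(occ, unocc)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-np.sum(ll))


def negloglik_fp(
    params: FPParams | Sequence[float],
    history: DetectionHistory,
    spec: OccupancyModelSpec | None = None,
) -> float:
    """Negative log likelihood of a {0,1,2}-coded detection history.

    ``params`` is either an :class:`FPParams` (probability scale, no
    covariates) or a packed logit-scale vector
    (alpha | beta | logit p10 | logit b).
    """
    spec = spec or OccupancyModelSpec()
    spec.validate(history)
    Y = history.observations
    mask = ~np.isnan(Y)
    W, X = _design_matrices(history, spec)
    if isinstance(params, FPParams):
        if spec.detection_covariates or spec.occupancy_covariates:
            raise ValueError("probability-scale FPParams only supports the no-covariate model")
        # probability-scale evaluation handles exact 0/1 values directly
        return _nll_fp_exact(params, Y, mask)
    packed = np.asarray(params, dtype=float)
    k_expected = W.shape[1] + X.shape[2] + 2
    if packed.shape != (k_expected,):
        raise ValueError(f"expected {k_expected} packed parameters, got {packed.shape}")
    return _nll_fp_core(packed, W, X, Y, mask, None)


def _nll_fp_exact(params: FPParams, Y: np.ndarray, mask: np.ndarray) -> float:
    """Probability-scale evaluation without logit clipping (handles
    exact 0/1 parameter values)."""
    psi, p11, p10, b = params.psi, params.p11, params.p10, params.b
    total = 0.0
    for i in range(Y.shape[0]):
        occ, unocc = 1.0, 1.0
        for j in range(Y.shape[1]):
            if not mask[i, j]:
                continue
            y = Y[i, j]
            if y == 0.0:
                occ *= 1.0 - p11
                unocc *= 1.0 - p10
            elif y == 1.0:
                occ *= p11 * (1.0 - b)
                unocc *= p10
            else:
                occ *= p11 * b
                unocc *= 0.0
        L = psi * occ + (1.0 - psi) * unocc
        if L <= 0.0:
            return np.inf
        total -= np.log(L)
    return total


class FPOccupancyModel(BaseEstimator):
    """False-positive occupancy estimator on {0,1,2}-coded histories.

    Parameters
    ----------
    detection_covariates : sequence of str
        Covariates on logit p11 (p10 never carries covariates).
    estimate_b : bool
        Estimate the certainty probability b (default); otherwise fix it
        at ``b_fixed``.
    n_starts, seed, standardize : as in :class:`~vernal.occupancy.OccupancyModel`.

    Fitted attributes: ``psi_``, ``p11_``, ``p10_``, ``b_``, ``beta_``
    (standardized scale), ``beta_raw_``, ``vcov_`` (packed logit scale),
    ``loglik_``, ``aic_``, ``converged_``, ``boundary_``.
    """

    def __init__(self, detection_covariates=(), occupancy_covariates=(),
                 estimate_b=True, b_fixed=0.5, n_starts=5, seed=0, standardize=True):
        self.detection_covariates = tuple(detection_covariates)
        self.occupancy_covariates = tuple(occupancy_covariates)
        self.estimate_b = estimate_b
        self.b_fixed = b_fixed
        self.n_starts = n_starts
        self.seed = seed
        self.standardize = standardize

    def fit(self, history: DetectionHistory, y=None, warm_start_params=None):
        spec = OccupancyModelSpec(self.detection_covariates, self.occupancy_covariates)
        spec.validate(history)
        from .occupancy import OccupancyModel  # reuse the z-scoring helper
        hist_std, stats = OccupancyModel(
            standardize=self.standardize
        )._standardized(history)
        Y = hist_std.observations
        mask = ~np.isnan(Y)
        if not ((Y == 1.0) | (Y == 2.0))[mask].any():
            raise ValueError("no detections in the history; nothing identifies p11/p10")
        if self.estimate_b and not (Y[mask] == 2.0).any():
            warnings.warn("b requested but no certain detections present; "
                          "b is unidentifiable and will sit at a boundary")
        W, X = _design_matrices(hist_std, spec)
        ko, kd = W.shape[1], X.shape[2]
        b_fixed = None if self.estimate_b else float(self.b_fixed)
        n_extra = 2 if self.estimate_b else 1

        def fun(params):
            # with b fixed the trailing logit-b slot is simply absent
            return _nll_fp_core(params, W, X, Y, mask, b_fixed)

        rng = np.random.default_rng(self.seed)
        det_frac = float(np.sum((Y >= 1.0) & mask) / max(mask.sum(), 1))
        base = np.zeros(ko + kd + n_extra)
        base[0] = logit(np.clip(float(np.mean(((Y >= 1.0) & mask).any(axis=1))), 0.05, 0.95))
        base[ko] = logit(np.clip(det_frac if det_frac > 0 else 0.2, 0.05, 0.95))
        base[ko + kd] = logit(0.05)          # p10 starts small
        if self.estimate_b:
            certain_frac = float(
                np.sum(Y[mask] == 2.0) / max(np.sum(Y[mask] >= 1.0), 1)
            )
            base[ko + kd + 1] = logit(np.clip(certain_frac, 0.05, 0.95))
        if warm_start_params is not None:
            base = np.asarray(warm_start_params, dtype=float)
        starts = [base] + [base + rng.normal(0, 1, base.size)
                           for _ in range(max(self.n_starts, 1) - 1)]
        res = _multi_start_minimize(fun, base.size, starts)
        theta = res.x
        converged = bool(res.success) and np.isfinite(res.fun)
        boundary = bool(np.any(np.abs(theta) > _BOUNDARY_FLAG))
        vcov = np.full((theta.size, theta.size), np.nan)
        if converged and not boundary:
            try:
                H = approx_hess(theta, fun)
                vcov = np.linalg.pinv(H)
                vcov = 0.5 * (vcov + vcov.T)
            except Exception:
                pass

        alpha = theta[:ko]
        beta = theta[ko:ko + kd]
        self.spec_ = spec
        self.alpha_ = alpha
        self.beta_ = beta
        self.beta_raw_ = OccupancyModel._destandardize(
            beta, self.detection_covariates, stats
        )
        self.psi_ = float(np.mean(expit(W @ alpha)))
        self.p11_ = float(np.mean(expit(X @ beta)))
        self.p10_ = float(expit(theta[ko + kd]))
        self.b_ = float(expit(theta[ko + kd + 1])) if self.estimate_b else float(self.b_fixed)
        self.theta_ = theta
        self.vcov_ = vcov
        self.loglik_ = -float(res.fun)
        self.aic_ = 2.0 * theta.size - self.loglik_ * 2.0
        self.converged_ = converged
        self.boundary_ = boundary
        self.n_sites_ = Y.shape[0]
        self.n_params_ = theta.size
        self.standardization_ = stats
        self.history_ = history
        if boundary:
            warnings.warn("boundary estimate (|logit| > 10) in false-positive model")
        return self

    def params(self) -> FPParams:
        return FPParams(psi=self.psi_, p11=self.p11_, p10=self.p10_, b=self.b_,
                        beta=self.beta_.copy() if self.beta_.size > 1 else None)


def fit_fp(
    history: DetectionHistory,
    spec: OccupancyModelSpec | None = None,
    estimate_b: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> FPOccupancyModel:
    """Fit the false-positive occupancy model (thin estimator wrapper)."""
    spec = spec or OccupancyModelSpec()
    return FPOccupancyModel(
        detection_covariates=spec.detection_covariates,
        occupancy_covariates=spec.occupancy_covariates,
        estimate_b=estimate_b, n_starts=n_starts, seed=seed,
    ).fit(history)
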