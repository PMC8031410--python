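"""qPCR standard-curve calibration: efficiency, Low95, LOD and LOQ.

A dilution series of synthetic double-stranded standards (typically five
concentrations spanning 1–100 copies/reaction, eight replicate wells
each, plus eight no-template controls) calibrates each assay.  The
quantification cycle of an amplifying well follows the log-linear model

    Cq = m * log10(copies) + c

so the amplification efficiency is ``10^(-1/m) - 1`` (m = -3.32 is a
perfectly doubling reaction).  Sensitivity is summarised three ways:

* **Low95** — the lowest *tested* concentration at which >= 95% of
  replicate wells amplified;
* **LOD** — the lowest concentration reliably distinguished from blank
  at 95% confidence, either discretely (= Low95) or by fitting a
  logistic dose-response to the per-concentration detection fractions
  and solving for 95% detection;
* **LOQ** — the lowest concentration quantified with acceptable
  precision: back-calculate copies for every amplifying well through
  the fitted line and require the coefficient of variation to fall at
  or below a threshold (default 0.35).

All three report single-replicate values; running r replicates improves
effective detection to ``1 - (1 - d)^r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "ABOVE_MAX_TESTED",
    "StandardPanel",
    "CurveFit",
    "StandardCurve",
    "fit_curve",
    "low95",
    "estimate_lod",
    "estimate_loq",
    "quantify",
    "replicate_adjusted_lod",
]

#: Sentinel returned when no tested concentration meets a sensitivity rule.
ABOVE_MAX_TESTED = np.inf


@dataclass
class StandardPanel:
    """A standard-curve panel: known copies/reaction vs observed Cq.

    ``copies`` and ``cq`` are parallel per-well arrays; a NaN Cq marks a
    non-amplifying well.  Non-amplifying wells are excluded from the
    regression but counted in detection fractions.
    """

    copies: np.ndarray
    cq: np.ndarray
    ntc_cqs: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        self.ntc_cqs = np.asarray(self.ntc_cqs, dtype=float)
        if self.copies.shape != self.cq.shape:
            raise ValueError("copies and cq must be parallel arrays")
        if np.any(self.copies <= 0):
            raise ValueError("standard concentrations must be positive copies/reaction")
        if len(np.unique(self.copies)) < 2:
            raise ValueError("need at least two distinct standard concentrations")

    @classmethod
    def from_points(
        cls,
        points: Sequence[tuple[float, float | None]],
        ntc_cqs: Sequence[float] = (),
    ) -> "StandardPanel":
        copies = np.array([c for c, _ in points], dtype=float)
        cq = np.array([np.nan if q is None else q for _, q in points], dtype=float)
        return cls(copies=copies, cq=cq, ntc_cqs=np.asarray(ntc_cqs, dtype=float))

    def concentrations(self) -> np.ndarray:
        return np.unique(self.copies)

    def detection_fractions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(concentrations ascending, n amplified, n wells) per level."""
        concs = self.concentrations()
        amp = np.array([np.sum(~np.isnan(self.cq[self.copies == c])) for c in concs])
        tot = np.array([np.sum(self.copies == c) for c in concs])
        return concs, amp, tot


@dataclass(frozen=True)
class CurveFit:
    """Standard-curve regression outputs plus the sensitivity metrics."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    low95: float | None = None
    lod: float | None = None
    loq: float | None = None
    n_wells: int = 0

    def quantify(self, cq: float | np.ndarray) -> float | np.ndarray:
        return quantify(cq, self)


def fit_curve(panel: StandardPanel) -> CurveFit:
    """Ordinary least squares of Cq on log10(copies) over amplifying wells."""
    amp = ~np.isnan(panel.cq)
    if not amp.any():
        raise ValueError("no amplifying wells: cannot fit a standard curve")
    x = np.log10(panel.copies[amp])
    y = panel.cq[amp]
    if len(np.unique(x)) < 2:
        raise ValueError("need amplifying wells at >= 2 concentrations")
    X = np.column_stack([x, np.ones_like(x)])
    (m, c), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (m * x + c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if m >= 0:
        warnings.warn(f"standard-curve slope is non-negative ({m:.3f}); assay suspect")
        eff = np.nan
    else:
        eff = 10.0 ** (-1.0 / m) - 1.0
    return CurveFit(slope=float(m), intercept=float(c), r_squared=r2,
                    efficiency=float(eff), n_wells=int(amp.sum()))


def low95(panel: StandardPanel) -> float:
    """Lowest tested concentration with >= 95% of replicates amplifying.

    Returns the ``ABOVE_MAX_TESTED`` sentinel when no level reaches 95%.
    """
    concs, amp, tot = panel.detection_fractions()
    ok = concs[(amp / tot) >= 0.95]
    return float(ok.min()) if len(ok) else ABOVE_MAX_TESTED


def _fit_detection_logistic(concs, amp, tot) -> tuple[float, float]:
    """Binomial ML fit of detect-probability = expit(a + b*log10(conc))."""
    x = np.log10(concs)

    def nll(params):
        a, b = params
        p = np.clip(expit(a + b * x), 1e-12, 1 - 1e-12)
        return -np.sum(amp * np.log(p) + (tot - amp) * np.log1p(-p))

    best = None
    for a0, b0 in ((0.0, 1.0), (2.0, 3.0), (-2.0, 5.0)):
        res = minimize(nll, np.array([a0, b0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


def estimate_lod(panel: StandardPanel, method: str = "curvefit") -> float:
    """Limit of detection at 95% confidence for a single replicate.

    ``discrete`` applies the Low95 rule directly.  ``curvefit`` fits a
    two-parameter logistic dose-response of detection probability
    against log10(copies) and solves for the 95%-detection crossing,
    clamped to no less than the smallest tested concentration; if the
    detection pattern admits no rising logistic, it falls back to the
    discrete rule with a warning.
    """
    if method == "discrete":
        return low95(panel)
    if method != "curvefit":
        raise ValueError(f"unknown LOD method {method!r}")
    concs, amp, tot = panel.detection_fractions()
    frac = amp / tot
    if frac.min() >= 0.95:
        return float(concs.min())
    a, b = _fit_detection_logistic(concs, amp, tot)
    if b <= 0:
        warnings.warn("detection pattern not increasing in concentration; "
                      "falling back to discrete LOD")
        return low95(panel)
    x95 = (logit(0.95) - a) / b
    return float(max(10.0**x95, concs.min()))


def _back_calculated_cv(panel: StandardPanel, fit: CurveFit):
    """Per-concentration CV of back-calculated copy numbers (>=3 wells)."""
    concs = panel.concentrations()
    out_c, out_cv = [], []
    for c in concs:
        cqs = panel.cq[(panel.copies == c) & ~np.isnan(panel.cq)]
        if len(cqs) < 3:
            continue
        est = quantify(cqs, fit)
        mean = est.mean()
        if mean <= 0:
            continue
        out_c.append(float(c))
        out_cv.append(float(est.std(ddof=1) / mean))
    return np.array(out_c), np.array(out_cv)


def estimate_loq(
    panel: StandardPanel,
    cv_threshold: float = 0.35,
    method: str = "discrete",
    fit: CurveFit | None = None,
) -> float:
    """Limit of quantitation: lowest concentration whose back-calculated
    copy numbers have coefficient of variation <= ``cv_threshold``.

    ``curvefit`` instead fits a monotone decreasing model of CV against
    log10(copies) (log-linear decay) and solves the threshold crossing.
    Returns the ``ABOVE_MAX_TESTED`` sentinel when nothing qualifies.
    """
    fit = fit or fit_curve(panel)
    concs, cvs = _back_calculated_cv(panel, fit)
    if len(concs) == 0:
        raise ValueError("no concentration has >= 3 amplifying wells; LOQ undefined")
    if method == "discrete":
        ok = concs[cvs <= cv_threshold]
        return float(ok.min()) if len(ok) else ABOVE_MAX_TESTED
    if method != "curvefit":
        raise ValueError(f"unknown LOQ method {method!r}")
    if len(concs) < 2 or np.all(cvs <= 0):
        return estimate_loq(panel, cv_threshold, "discrete", fit)
    x = np.log10(concs)
    pos = cvs > 0
    if pos.sum() < 2:
        return float(concs.min())
    coef = np.polyfit(x[pos], np.log(cvs[pos]), 1)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope >= 0:
        warnings.warn("CV not decreasing with concentration; using discrete LOQ")
        return estimate_loq(panel, cv_threshold, "discrete", fit)

    def f(lx):
        return slope * lx + intercept - np.log(cv_threshold)

    lo, hi = x.min(), x.max()
    if f(lo) <= 0:       # already precise at the lowest tested level
        return float(concs.min())
    if f(hi) > 0:        # never reaches the threshold within the panel
        return ABOVE_MAX_TESTED
    return float(10.0 ** brentq(f, lo, hi))


def quantify(cq: float | np.ndarray, fit: CurveFit) -> float | np.ndarray:
    """Invert the calibration line: copies = 10^((Cq - intercept)/slope)."""
    if not fit.slope < 0:
        raise ValueError("quantification requires a negative calibration slope")
    out = 10.0 ** ((np.asarray(cq, dtype=float) - fit.intercept) / fit.slope)
    return float(out) if np.isscalar(cq) else out


def replicate_adjusted_lod(single_replicate_detection: float, n_replicates: int,
                           target: float = 0.95) -> bool:
    """Whether ``n_replicates`` wells at a per-replicate detection rate
    reach the target via 1 - (1 - d)^r >= target."""
    return 1.0 - (1.0 - single_replicate_detection) ** n_replicates >= target


class StandardCurve(BaseEstimator):
    """Estimator wrapper over the calibration workflow.

    Parameters
    ----------
    cv_threshold : float
        CV ceiling for the limit of quantitation.
    lod_method, loq_method : str
        "discrete" or "curvefit".

    After ``fit(panel)`` the instance exposes ``slope_``, ``intercept_``,
    ``r_squared_``, ``efficiency_``, ``low95_``, ``lod_``, ``loq_`` and
    ``result_`` (the full :class:`CurveFit`); ``predict(cq)`` maps Cq
    values to copy-number estimates.
    """

    def __init__(self, cv_threshold: float = 0.35,
                 lod_method: str = "curvefit", loq_method: str = "discrete"):
        self.cv_threshold = cv_threshold
        self.lod_method = lod_method
        self.loq_method = loq_method

    def fit(self, panel: StandardPanel, y=None) -> "StandardCurve":
        base = fit_curve(panel)
        self.result_ = CurveFit(
            slope=base.slope,
            intercept=base.intercept,
            r_squared=base.r_squared,
            efficiency=base.efficiency,
            low95=low95(panel),
            lod=estimate_lod(panel, self.lod_method),
            loq=estimate_loq(panel, self.cv_threshold, self.loq_method, base),
            n_wells=base.n_wells,
        )
        self.slope_ = self.result_.slope
        self.intercept_ = self.result_.intercept
        self.r_squared_ = self.result_.r_squared
        self.efficiency_ = self.result_.efficiency
        self.low95_ = self.result_.low95
        self.lod_ = self.result_.lod
        self.loq_ = self.result_.loq
        return self

    def predict(self, cq) -> np.ndarray:
        return np.asarray(quantify(np.asarray(cq, dtype=float), self.result_))
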