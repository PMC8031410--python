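"""Synthetic study generator.

Produces complete artificial field studies — pool covariates, latent
occupancy, replicate-level eDNA detections with false positives,
dip-net outcomes, well-level qPCR tables and standard-curve panels —
with the same shapes and CSV schemas the readers consume, so every
pipeline stage can be exercised end to end with known truth.

The default configuration mirrors the study design this package
models: 89 sampling events, three replicate water samples each, a
single-replicate detection probability of about 0.76 at occupied
pools, no false positives, and a five-concentration (1–100
copies/reaction) standard panel with eight replicate wells per level
plus eight no-template controls.  Water volume per replicate is
clog-limited: a site-level turbidity latent depresses both a
replicate's volume and (through the configurable volume coefficient)
its detection probability, which is what makes *average volume
filtered* a meaningful site covariate.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .calibration import StandardPanel
from .datatypes import SamplingEvent, WaterReplicate

__all__ = ["SimConfig", "SimStudy", "simulate_study", "simulate_fp_history",
           "simulate_standard_panel"]


@dataclass
class SimConfig:
    """Truth parameters and generators for one synthetic study.

    Detection at occupied sites follows
    ``logit(p11) = intercept + sum_k coef_k * z_k`` where the z_k are
    the standardized covariates (volume per replicate in units of
    100 mL, log10 pool area, protocol as 0/1); unoccupied sites detect
    with constant probability ``p10``.
    """

    n_sites: int = 89
    replicates_per_site: int = 3
    psi: float = 0.5
    detect_intercept: float = float(logit(0.7564))
    coef_volume: float = 0.0        # per 100 mL of replicate volume
    coef_avg_volume: float = 0.0    # per 100 mL of site-average volume
    coef_pool_area: float = 0.0     # per log10 m^2
    coef_protocol: float = 0.0      # lab (1) vs field (0)
    p10: float = 0.0
    dipnet_sensitivity: float = 0.8
    species: str = "BRLY"
    # covariate generators
    pool_area_log10_mean: float = 2.7    # median pool ~ 500 m^2
    pool_area_log10_sd: float = 0.5
    max_volume_ml: float = 1000.0
    prob_lab_protocol: float = 0.5
    # qPCR well-level generation
    curve_slope: float = -3.609
    curve_intercept: float = 38.664
    cq_sd: float = 0.35
    mean_log10_copies: float = 1.3       # ~20 copies/reaction in positives
    single_amp_rate: float = 0.05        # non-detections that show 1-of-4 wells
    contamination_rate: float = 0.0      # field/equipment negatives that amplify
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psi", "p10", "dipnet_sensitivity", "prob_lab_protocol",
                     "single_amp_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SimStudy:
    """One simulated study plus its latent truth."""

    events: list[SamplingEvent]
    qpcr: pd.DataFrame
    dipnet: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _site_covariates(cfg: SimConfig, rng: np.random.Generator):
    n, J = cfg.n_sites, cfg.replicates_per_site
    area = 10.0 ** rng.normal(cfg.pool_area_log10_mean, cfg.pool_area_log10_sd, n)
    turbidity = rng.normal(0.0, 1.0, n)
    # clogging: turbid pools filter less water before the filter blocks
    frac = expit(1.5 - 1.2 * turbidity[:, None] + rng.normal(0.0, 0.5, (n, J)))
    volume = np.clip(cfg.max_volume_ml * frac, 25.0, cfg.max_volume_ml)
    protocol = (rng.random(n) < cfg.prob_lab_protocol).astype(float)  # event-level
    return area, volume, protocol


def _detection_probability(cfg: SimConfig, area, volume, protocol):
    avg_vol = volume.mean(axis=1, keepdims=True)
    eta = (
        cfg.detect_intercept
        + cfg.coef_volume * volume / 100.0
        + cfg.coef_avg_volume * avg_vol / 100.0
        + cfg.coef_pool_area * np.log10(area)[:, None]
        + cfg.coef_protocol * protocol[:, None]
    )
    return expit(eta)


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate a complete synthetic side-by-side eDNA/dip-net study.

    Occupancy is Bernoulli(psi) per site; replicate detections are
    Bernoulli(p11(x)) at occupied sites and Bernoulli(p10) elsewhere;
    the dip-net detects occupied sites with the configured sensitivity.
    Detected replicates expand to quadruplicate wells with at least two
    amplifications; non-detected replicates occasionally show a single
    amplifying well followed by an all-negative re-run, exercising the
    re-run rule.  Fixed seeds give byte-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, J = cfg.n_sites, cfg.replicates_per_site
    area, volume, protocol = _site_covariates(cfg, rng)
    p11 = _detection_probability(cfg, area, volume, protocol)
    z = (rng.random(n) < cfg.psi).astype(int)
    p_det = np.where(z[:, None] == 1, p11, cfg.p10)
    detected = rng.random((n, J)) < p_det
    dipnet_detected = (rng.random(n) < cfg.dipnet_sensitivity) & (z == 1)

    events: list[SamplingEvent] = []
    qpcr_rows: list[dict] = []
    dipnet_rows: list[dict] = []
    date0 = _dt.date(2017, 3, 1)
    m, c = cfg.curve_slope, cfg.curve_intercept
    for i in range(n):
        pool = f"P{i:03d}"
        date = date0 + _dt.timedelta(days=int(i))
        event_id = f"{pool}:{date.isoformat()}"
        proto = "lab" if protocol[i] == 1.0 else "field"
        reps = []
        plate = f"plate-{cfg.species}-{i:03d}"
        well_no = 1
        for j in range(J):
            sid = f"{pool}-{date.isoformat()}-r{j + 1}"
            reps.append(
                WaterReplicate(
                    replicate_id=sid,
                    volume_ml=float(volume[i, j]),
                    protocol=proto,
                    calls={cfg.species: "positive" if detected[i, j] else "negative"},
                )
            )
            if detected[i, j]:
                n_amp = 2 + int(rng.integers(0, 3))    # 2..4 amplifying wells
                log10_copies = rng.normal(cfg.mean_log10_copies, 0.4)
                cqs = m * log10_copies + c + rng.normal(0.0, cfg.cq_sd, 4)
                flags = np.zeros(4, dtype=bool)
                flags[rng.permutation(4)[:n_amp]] = True
                for w in range(4):
                    qpcr_rows.append(_well(plate, well_no + w, cfg.species, sid,
                                           "sample", float(np.clip(cqs[w], 10, 50)) if flags[w] else None, 1))
            else:
                one_amp = rng.random() < cfg.single_amp_rate
                for w in range(4):
                    cq = float(rng.uniform(38, 45)) if (one_amp and w == 0) else None
                    qpcr_rows.append(_well(plate, well_no + w, cfg.species, sid, "sample", cq, 1))
                if one_amp:                     # all-negative re-run -> negative
                    for w in range(4):
                        qpcr_rows.append(_well(plate, 100 + w, cfg.species, sid, "sample", None, 2))
            well_no += 4
        # plate controls: duplicate quadruplicate positives, one NTC quad,
        # and the paired field/equipment negative for the event
        for w in range(8):
            qpcr_rows.append(_well(plate, well_no + w, cfg.species, f"{plate}-pos",
                                   "positive_control",
                                   float(m * np.log10(10.0) + c + rng.normal(0, cfg.cq_sd)), 1))
        well_no += 8
        for w in range(4):
            qpcr_rows.append(_well(plate, well_no + w, cfg.species, f"{plate}-ntc", "ntc", None, 1))
        well_no += 4
        contaminated = rng.random() < cfg.contamination_rate
        for w in range(4):
            cq = float(rng.uniform(35, 45)) if (contaminated and w < 2) else None
            qpcr_rows.append(_well(plate, well_no + w, cfg.species, f"{event_id}-fneg",
                                   "field_negative", cq, 1))
        events.append(
            SamplingEvent(
                event_id=event_id,
                pool_id=pool,
                property_name="synthetic-preserve",
                date=date,
                pool_area_m2=float(area[i]),
                replicates=reps,
                dipnet={cfg.species: bool(dipnet_detected[i])},
            )
        )
        dipnet_rows.append({"event_id": event_id, "species": cfg.species,
                            "detected": bool(dipnet_detected[i]),
                            "voucher_confirmed": bool(dipnet_detected[i])})
    truth = {
        "z": z,
        "detected": detected,
        "p11": p11,
        "dipnet_detected": dipnet_detected,
        "psi": cfg.psi,
        "p10": cfg.p10,
        "config": cfg,
    }
    return SimStudy(
        events=events,
        qpcr=pd.DataFrame(qpcr_rows),
        dipnet=pd.DataFrame(dipnet_rows),
        truth=truth,
    )


def _well(plate, well, assay, sample_id, role, cq, run) -> dict:
    return {"plate_id": plate, "well": f"W{well:03d}", "assay": assay,
            "sample_id": sample_id, "role": role,
            "cq": np.nan if cq is None else cq, "run": run}


def simulate_fp_history(
    n_sites: int,
    replicates_per_site: int = 3,
    psi: float = 0.5,
    p11: float = 0.8,
    p10: float = 0.05,
    b: float = 0.7,
    seed: int = 0,
):
    """Draw a {0,1,2}-coded detection history directly from the
    false-positive observation model.

    Certainty is assigned per replicate: each detection at an occupied
    site is independently recorded as certain with probability b.  This
    is the generating process the false-positive likelihood assumes,
    so it is the right input for checking that estimator.  (In a real
    study certainty instead comes from the event-level dip-net result,
    which ties the certainty codes of an event's replicates together;
    see :func:`simulate_study` and the methods note.)
    """
    from .datatypes import DetectionHistory

    rng = np.random.default_rng(seed)
    n, J = n_sites, replicates_per_site
    z = (rng.random(n) < psi).astype(float)
    det = rng.random((n, J)) < np.where(z[:, None] == 1.0, p11, p10)
    certain = (rng.random((n, J)) < b) & det & (z[:, None] == 1.0)
    obs = det.astype(float) + certain.astype(float)
    known = certain.any(axis=1)
    truth = {"z": z, "psi": psi, "p11": p11, "p10": p10, "b": b}
    hist = DetectionHistory(
        site_ids=[f"S{i:04d}" for i in range(n)],
        observations=obs,
        known_occupied=known,
    )
    return hist, truth


def simulate_standard_panel(
    slope: float = -3.609,
    intercept: float = 38.664,
    cq_sd: float = 0.35,
    concentrations: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 100.0),
    replicates: int = 8,
    n_ntc: int = 8,
    detect50: float = 0.3,
    detect_slope: float = 4.0,
    seed: int = 0,
) -> StandardPanel:
    """Simulate a dilution-series standard panel.

    Per-well amplification is Bernoulli with probability
    ``expit(detect_slope * (log10(conc) - log10(detect50)))`` — a
    logistic dropout curve crossing 50% detection at ``detect50``
    copies/reaction — and amplifying wells draw
    ``Cq ~ Normal(slope * log10(conc) + intercept, cq_sd)``.  The
    default geometry is five concentrations spanning 1–100
    copies/reaction, eight replicates each, eight no-template controls.
    """
    rng = np.random.default_rng(seed)
    copies, cq = [], []
    for conc in concentrations:
        p_amp = expit(detect_slope * (np.log10(conc) - np.log10(detect50)))
        for _ in range(replicates):
            copies.append(float(conc))
            if rng.random() < p_amp:
                cq.append(slope * np.log10(conc) + intercept + rng.normal(0.0, cq_sd))
            else:
                cq.append(np.nan)
    return StandardPanel(
        copies=np.array(copies),
        cq=np.array(cq),
        ntc_cqs=np.full(n_ntc, np.nan),
    )
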