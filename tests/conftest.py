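"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized likelihood
code paths: they enumerate the latent occupancy state (and, for the
design calculus, every replicate outcome vector) with plain Python
loops, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math

import numpy as np
import pytest

from vernal import DetectionHistory, SamplingEvent, WaterReplicate


# ---------------------------------------------------------------------------
# brute-force oracles


def nll_oracle(psi_sites, p_sites, Y, known):
    """Occupancy negative log likelihood by two-branch enumeration.

    psi_sites: per-site occupancy probability; p_sites: per-site,
    per-replicate detection probability; Y binary with NaN missing.
    """
    total = 0.0
    for i in range(Y.shape[0]):
        occ = 1.0
        all_zero = True
        for j in range(Y.shape[1]):
            y = Y[i, j]
            if math.isnan(y):
                continue
            p = p_sites[i][j]
            occ *= p if y == 1.0 else (1.0 - p)
            if y == 1.0:
                all_zero = False
        lik = psi_sites[i] * occ
        if not known[i] and all_zero:
            lik += 1.0 - psi_sites[i]
        total -= math.log(lik)
    return total


def nll_fp_oracle(psi, p11, p10, b, Y):
    """False-positive model negative log likelihood by enumeration."""
    total = 0.0
    for i in range(Y.shape[0]):
        occ, unocc = 1.0, 1.0
        for j in range(Y.shape[1]):
            y = Y[i, j]
            if math.isnan(y):
                continue
            if y == 0.0:
                occ *= 1.0 - p11
                unocc *= 1.0 - p10
            elif y == 1.0:
                occ *= p11 * (1.0 - b)
                unocc *= p10
            else:
                occ *= p11 * b
                unocc *= 0.0
        total -= math.log(psi * occ + (1.0 - psi) * unocc)
    return total


def binomial_tail_oracle(p, n, k):
    """P(at least k successes of n) by summing over all 2^n outcomes."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        if sum(outcome) >= k:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1.0 - p)
            total += prob
    return total


# ---------------------------------------------------------------------------
# fixture builders


def make_history(obs, known=None, covariates=None):
    obs = np.asarray(obs, dtype=float)
    return DetectionHistory(
        site_ids=[f"S{i}" for i in range(obs.shape[0])],
        observations=obs,
        covariates=covariates or {},
        known_occupied=known,
    )


def make_event(event_id, calls, dipnet_positive, species="BRLY", volumes=None,
               protocol="field", pool_area=500.0, date=dt.date(2017, 3, 15)):
    """One sampling event with per-replicate eDNA call states."""
    volumes = volumes or [500.0] * len(calls)
    reps = [
        WaterReplicate(
            replicate_id=f"{event_id}-r{j + 1}",
            volume_ml=volumes[j],
            protocol=protocol,
            calls={species: call},
        )
        for j, call in enumerate(calls)
    ]
    return SamplingEvent(
        event_id=event_id,
        pool_id=event_id.split(":")[0],
        property_name="test-preserve",
        date=date,
        pool_area_m2=pool_area,
        replicates=reps,
        dipnet={species: dipnet_positive},
    )


def events_for_counts(epp, epn, enp, enn, species="BRLY"):
    """A set of sampling events that reduces to the given 2x2 counts."""
    events = []
    i = 0
    for count, (edna, dip) in (
        (epp, (True, True)), (epn, (True, False)),
        (enp, (False, True)), (enn, (False, False)),
    ):
        for _ in range(count):
            calls = ["positive", "negative", "negative"] if edna else ["negative"] * 3
            events.append(make_event(f"E{i:03d}:2017-03-15", calls, dip, species=species))
            i += 1
    return events


@pytest.fixture
def toy_history():
    """Six sites, three replicates, mixed histories, one known-occupied."""
    return make_history(
        [[1, 0, 0], [0, 0, 0], [1, 1, 0], [0, 0, 0], [1, 1, 1], [0, 1, 0]],
        known=[False, False, True, False, True, False],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170315)
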