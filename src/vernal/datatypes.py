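"""Core domain types shared across the pipeline.

The survey design this package models is a side-by-side comparison of
eDNA sampling and dip-net surveys of vernal pools: at each *sampling
event* (one visit to one pool) several replicate water samples are
filtered and assayed by species-specific TaqMan qPCR, and the pool is
dip-netted immediately afterwards.  These types carry that structure
from the raw sample sheets through to the occupancy-model input (the
detection-history matrix).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IUPAC_DNA",
    "Assay",
    "BUILTIN_ASSAYS",
    "WaterReplicate",
    "SamplingEvent",
    "DetectionHistory",
    "DETECTION_COVARIATES",
]

#: IUPAC nucleotide codes accepted in primer/probe sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Detection covariates the occupancy models know how to resolve.
DETECTION_COVARIATES = ("volume_per_replicate", "avg_volume", "pool_area", "protocol")


@dataclass(frozen=True)
class Assay:
    """One species-specific TaqMan qPCR assay.

    ``positive_call_max_cycle`` is the tissue-identification cutoff: on
    high-concentration tissue-derived DNA the target amplifies within
    this many cycles.  ``offtarget_floor_cycle`` is the earliest cycle
    at which any off-target species has been observed to amplify; a
    specimen with no amplification before it is called non-target.
    """

    species_code: str
    gene: str
    primer_f: str
    primer_r: str
    probe: str
    anneal_temp_c: float
    positive_call_max_cycle: int
    offtarget_floor_cycle: int

    def __post_init__(self) -> None:
        for name in ("primer_f", "primer_r", "probe"):
            seq = getattr(self, name)
            if not seq:
                raise ValueError(f"{name} must be a nonempty sequence")
            bad = set(seq.upper()) - IUPAC_DNA
            if bad:
                raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
        if not self.positive_call_max_cycle < self.offtarget_floor_cycle <= 50:
            raise ValueError(
                "require positive_call_max_cycle < offtarget_floor_cycle <= 50, "
                f"got {self.positive_call_max_cycle} / {self.offtarget_floor_cycle}"
            )


#: The four published branchiopod assays.  Primer and probe sequences are the
#: amplification-relevant oligo sequences (probe given without the
#: fluorophore/quencher chemistry labels).
BUILTIN_ASSAYS: Mapping[str, Assay] = {
    "BRCO": Assay(
        species_code="BRCO",
        gene="COI",
        primer_f="TGCAGAAAGGGGAGGATARACC",
        primer_r="TGCCTCCTGCCTTRACCTTRC",
        probe="YCACCCAGTCCCAGCTCCACT",
        anneal_temp_c=56.2,
        positive_call_max_cycle=20,
        offtarget_floor_cycle=30,
    ),
    "BRLY": Assay(
        species_code="BRLY",
        gene="12S",
        primer_f="GGATTTGGCGGTTCTTAAACTT",
        primer_r="TTTTCCTAGAAAAATGCATCCGT",
        probe="TYAACAGCTTATATACCGTCGTTTAGAGGA",
        anneal_temp_c=58.2,
        positive_call_max_cycle=30,
        offtarget_floor_cycle=42,
    ),
    "BRME": Assay(
        species_code="BRME",
        gene="12S",
        primer_f="CCGTCGCTTAGAGGATTACATT",
        primer_r="ATGAGCTACGCCTTGATCTG",
        probe="TTTAAATTCTTTTATTGGGAGTTCC",
        anneal_temp_c=59.0,
        positive_call_max_cycle=20,
        offtarget_floor_cycle=30,
    ),
    "LEPA": Assay(
        species_code="LEPA",
        gene="16S",
        primer_f="CCGTGCGAAGGTAGCATAAT",
        primer_r="AGGGTCTTATCGTCCCTCAA",
        probe="TGAAGGCTGGTATGAATGGCTGGA",
        anneal_temp_c=57.0,
        positive_call_max_cycle=20,
        offtarget_floor_cycle=30,
    ),
}

#: Per-species eDNA call states for a water replicate.
CALL_STATES = ("positive", "negative", "discarded", "missing")


@dataclass
class WaterReplicate:
    """One replicate water sample within a sampling event.

    ``calls`` maps species code to the sample-level qPCR outcome.  A
    replicate is ``discarded`` when the paired field/equipment negative
    control amplified for that species.
    """

    replicate_id: str
    volume_ml: float
    protocol: str  # "field" or "lab"
    filter_type: str = "CN 0.22um"
    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.volume_ml) or self.volume_ml < 0:
            raise ValueError(f"volume_ml must be finite and >= 0, got {self.volume_ml}")
        if self.volume_ml > 1000:
            raise ValueError(f"volume_ml exceeds the 1000 mL protocol maximum: {self.volume_ml}")
        if self.protocol not in ("field", "lab"):
            raise ValueError(f"protocol must be 'field' or 'lab', got {self.protocol!r}")
        for sp, call in self.calls.items():
            if call not in CALL_STATES:
                raise ValueError(f"bad call state {call!r} for {sp}")


@dataclass
class SamplingEvent:
    """One visit to one vernal pool: replicate water samples + dip-net.

    Each sampling event is treated as an independent site in the
    occupancy models even when the same pool is visited repeatedly;
    ``pool_id`` is retained for reporting only.
    """

    event_id: str
    pool_id: str
    property_name: str
    date: _dt.date
    pool_area_m2: float
    replicates: list[WaterReplicate] = field(default_factory=list)
    dipnet: dict[str, bool] = field(default_factory=dict)
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pool_area_m2) and self.pool_area_m2 > 0):
            raise ValueError(f"pool_area_m2 must be finite and positive, got {self.pool_area_m2}")
        if len(self.replicates) < 1:
            raise ValueError("a sampling event needs at least one water replicate")

    @property
    def avg_volume_ml(self) -> float:
        return float(np.mean([r.volume_ml for r in self.replicates]))

    def edna_positive(self, species: str) -> bool | None:
        """Site-level eDNA call: positive if any non-discarded replicate is.

        Returns None when every replicate is discarded/missing.
        """
        calls = [r.calls.get(species, "missing") for r in self.replicates]
        usable = [c for c in calls if c in ("positive", "negative")]
        if not usable:
            return None
        return "positive" in usable


@dataclass
class DetectionHistory:
    """Sites x replicates observation matrix for the occupancy models.

    ``observations`` uses float codes 0 (no detection), 1 (uncertain
    detection), 2 (certain, dip-net-confirmed detection) and NaN for
    missing/discarded replicates.  ``covariates`` holds named arrays:
    site-level covariates with shape ``(n_sites,)`` and replicate-level
    covariates with shape ``(n_sites, n_replicates)``.
    """

    site_ids: list[str]
    observations: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    known_occupied: np.ndarray | None = None
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.ndim != 2:
            raise ValueError("observations must be a 2-D sites x replicates matrix")
        if len(self.site_ids) != self.observations.shape[0]:
            raise ValueError("site_ids length must match the observation rows")
        obs = self.observations
        valid = np.isnan(obs) | np.isin(obs, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("observation codes must be 0, 1, 2 or NaN")
        if self.known_occupied is None:
            self.known_occupied = np.zeros(obs.shape[0], dtype=bool)
        self.known_occupied = np.asarray(self.known_occupied, dtype=bool)
        certain_rows = np.nansum(obs == 2.0, axis=1) > 0
        if np.any(certain_rows & ~self.known_occupied):
            raise ValueError("certain (code 2) detections require known_occupied sites")
        for name, arr in self.covariates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape not in (obs.shape, (obs.shape[0],)):
                raise ValueError(
                    f"covariate {name!r} must be per-site {(obs.shape[0],)} "
                    f"or per-replicate {obs.shape}, got {arr.shape}"
                )
            self.covariates[name] = arr

    @property
    def n_sites(self) -> int:
        return self.observations.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.observations.shape[1]

    def binary(self) -> "DetectionHistory":
        """Collapse certain/uncertain codes {1, 2} to 1 (binary history)."""
        obs = self.observations.copy()
        obs[obs == 2.0] = 1.0
        return dataclasses.replace(self, observations=obs)

    def replicate_covariate(self, name: str) -> np.ndarray:
        """Return a covariate broadcast to sites x replicates shape."""
        arr = self.covariates[name]
        if arr.ndim == 1:
            return np.broadcast_to(arr[:, None], self.observations.shape)
        return arr

    def subset(self, idx: Sequence[int]) -> "DetectionHistory":
        idx = np.asarray(idx, dtype=int)
        return DetectionHistory(
            site_ids=[self.site_ids[i] for i in idx],
            observations=self.observations[idx],
            covariates={k: v[idx] for k, v in self.covariates.items()},
            known_occupied=self.known_occupied[idx],
            n_discarded=self.n_discarded,
        )
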