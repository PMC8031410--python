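"""Well-level and sample-level qPCR call rules, plate QC, specimen typing.

Every eDNA sample (one water replicate's extract) is run in
quadruplicate on a single-assay plate alongside two low-concentration
synthetic positive controls and a no-template control.  The calling
rule is: two or more amplified wells of four -> positive; zero ->
negative; exactly one -> re-run, and positive if the re-run yields at
least one amplified well, otherwise negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Assay

__all__ = [
    "QpcrPlate",
    "SampleCall",
    "call_well",
    "call_sample",
    "qc_plate",
    "classify_specimen",
    "call_table",
]


@dataclass
class QpcrPlate:
    """One single-assay qPCR plate: wells are (well_id, role, sample_id, cq)."""

    plate_id: str
    assay: str
    wells: list[tuple[str, str, str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for well_id, role, sample_id, cq in self.wells:
            if cq is not None and not 0.0 < cq <= 50.0:
                raise ValueError(f"well {well_id}: Cq must lie in (0, 50], got {cq}")


@dataclass(frozen=True)
class SampleCall:
    """Sample-level call after applying the 2-of-4 / re-run rule."""

    sample_id: str
    n_amplified_of_4: int
    status: str  # positive | negative | rerun_needed
    rerun_applied: bool = False


def call_well(cq: float | None, max_cycle: float = 50.0) -> bool:
    """Whether a single well amplified: a Cq was reported at or before
    ``max_cycle``.  For eDNA samples the default counts any Cq within
    the 50-cycle protocol."""
    if max_cycle > 50:
        raise ValueError(f"max_cycle must be <= 50, got {max_cycle}")
    if cq is None or (isinstance(cq, float) and np.isnan(cq)):
        return False
    if cq <= 0:
        raise ValueError(f"Cq must be positive, got {cq}")
    return cq <= max_cycle


def call_sample(
    sample_id: str,
    first_run: Sequence[bool],
    rerun: Sequence[bool] | None = None,
) -> SampleCall:
    """Apply the quadruplicate calling rule to one sample.

    >= 2 of 4 first-run wells amplified -> positive; 0 -> negative;
    exactly 1 -> re-run required, and the sample is positive if any
    re-run well amplifies, negative if none do.  A re-run supplied when
    the first run was already conclusive is ignored with a warning.
    """
    if len(first_run) != 4:
        raise ValueError(f"expected exactly 4 first-run wells, got {len(first_run)}")
    n = int(sum(bool(w) for w in first_run))
    if n >= 2:
        if rerun is not None:
            warnings.warn(f"{sample_id}: first run conclusive ({n}/4); re-run ignored")
        return SampleCall(sample_id, n, "positive")
    if n == 0:
        if rerun is not None:
            warnings.warn(f"{sample_id}: first run conclusive (0/4); re-run ignored")
        return SampleCall(sample_id, n, "negative")
    # exactly one amplified
    if rerun is None:
        return SampleCall(sample_id, n, "rerun_needed")
    status = "positive" if any(bool(w) for w in rerun) else "negative"
    return SampleCall(sample_id, n, status, rerun_applied=True)


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    passed: bool
    ntc_amplified: bool
    positive_control_failed: bool
    blank_amplified: bool
    field_negative_amplified: bool
    discarded_samples: tuple[str, ...] = ()
    messages: tuple[str, ...] = ()


def qc_plate(plate: QpcrPlate, max_cycle: float = 50.0) -> PlateQC:
    """Control checks for one plate.

    Flags NTC amplification, positive-control failure, and
    extraction-blank or field-negative amplification.  A field negative
    that amplifies invalidates its sampling event: all sample wells on
    the plate are listed as discarded (the caller maps these to event
    replicates).  A plate lacking an NTC or positive control is a QC
    failure but calls are still emitted, with a warning.
    """
    roles: dict[str, list[tuple[str, float | None]]] = {}
    for well_id, role, sample_id, cq in plate.wells:
        roles.setdefault(role, []).append((sample_id, cq))
    messages = []
    ntc_amp = any(call_well(cq, max_cycle) for _, cq in roles.get("ntc", []))
    pos_wells = roles.get("positive_control", [])
    pos_failed = bool(pos_wells) and not any(call_well(cq, max_cycle) for _, cq in pos_wells)
    blank_amp = any(call_well(cq, max_cycle) for _, cq in roles.get("extraction_blank", []))
    fneg_amp = any(call_well(cq, max_cycle) for _, cq in roles.get("field_negative", []))
    if "ntc" not in roles:
        messages.append("plate has no NTC wells")
        warnings.warn(f"{plate.plate_id}: no NTC wells; calls emitted but plate fails QC")
    if "positive_control" not in roles:
        messages.append("plate has no positive-control wells")
        warnings.warn(f"{plate.plate_id}: no positive control; calls emitted but plate fails QC")
    if ntc_amp:
        messages.append("NTC amplified")
    if pos_failed:
        messages.append("positive control failed to amplify")
    discarded: tuple[str, ...] = ()
    if fneg_amp or blank_amp:
        messages.append("negative control amplified; event replicates discarded")
        discarded = tuple(sorted({sid for sid, _ in roles.get("sample", [])}))
    passed = not (
        ntc_amp or pos_failed or blank_amp or fneg_amp
        or "ntc" not in roles or "positive_control" not in roles
    )
    return PlateQC(
        plate_id=plate.plate_id,
        passed=passed,
        ntc_amplified=ntc_amp,
        positive_control_failed=pos_failed,
        blank_amplified=blank_amp,
        field_negative_amplified=fneg_amp,
        discarded_samples=discarded,
        messages=tuple(messages),
    )


def classify_specimen(cq_quadruplicate: Sequence[float | None], assay: Assay) -> str:
    """Species-identify a tissue-derived specimen from quadruplicate Cqs.

    Target if the median Cq of amplifying wells is at or before the
    assay's tissue cutoff (20 cycles, 30 for the BRLY assay); non-target
    if nothing amplified before the earliest off-target cycle; otherwise
    indeterminate.  Median rather than mean keeps one aberrant well from
    flipping the call.
    """
    cqs = [c for c in cq_quadruplicate if c is not None and not np.isnan(c)]
    if not cqs:
        return "non_target"
    med = float(np.median(cqs))
    if med <= assay.positive_call_max_cycle:
        return "target"
    if min(cqs) >= assay.offtarget_floor_cycle:
        return "non_target"
    return "indeterminate"


def call_table(wells: pd.DataFrame, max_cycle: float = 50.0) -> pd.DataFrame:
    """Sample-level calls from a long-format qPCR table.

    ``wells`` follows the qPCR CSV schema (plate_id, well, assay,
    sample_id, role, cq, run).  Sample wells are grouped by (assay,
    sample_id); run 1 is the quadruplicate first run and run 2, when
    present, the re-run.  Samples on plates whose field negative (or
    extraction blank) amplified are marked ``discarded``.  Returns a
    DataFrame (sample_id, species, n_amplified_of_4, status).
    """
    wells = wells.copy()
    if "run" not in wells.columns:
        wells["run"] = 1
    discarded_by_plate: dict[str, set[str]] = {}
    for plate_id, sub in wells.groupby("plate_id"):
        assay = str(sub["assay"].iloc[0])
        plate = QpcrPlate(
            plate_id=str(plate_id),
            assay=assay,
            wells=[
                (str(r.well), str(r.role), str(r.sample_id), None if pd.isna(r.cq) else float(r.cq))
                for r in sub.itertuples()
            ],
        )
        qc = qc_plate(plate, max_cycle)
        if qc.discarded_samples:
            discarded_by_plate[str(plate_id)] = set(qc.discarded_samples)

    rows = []
    samples = wells[wells["role"] == "sample"]
    for (assay, sample_id), sub in samples.groupby(["assay", "sample_id"]):
        plate_ids = set(sub["plate_id"].astype(str))
        discarded = any(
            str(sample_id) in discarded_by_plate.get(pid, ()) for pid in plate_ids
        )
        first = sub[sub["run"] == 1]
        flags = [call_well(None if pd.isna(c) else float(c), max_cycle) for c in first["cq"]]
        rerun_rows = sub[sub["run"] == 2]
        rerun = None
        if len(rerun_rows):
            rerun = [call_well(None if pd.isna(c) else float(c), max_cycle) for c in rerun_rows["cq"]]
        if len(flags) != 4:
            warnings.warn(f"{sample_id}/{assay}: {len(flags)} first-run wells (expected 4); skipped")
            continue
        call = call_sample(str(sample_id), flags, rerun if sum(flags) == 1 else None)
        status = "discarded" if discarded else call.status
        rows.append(
            {
                "sample_id": str(sample_id),
                "species": str(assay),
                "n_amplified_of_4": call.n_amplified_of_4,
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "species", "n_amplified_of_4", "status"])
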