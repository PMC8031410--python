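"""Readers/writers for the pipeline's plain-text interchange formats.

Three CSV schemas cross the package boundary:

* **sample sheet** — one row per water replicate, with the field
  collection metadata (collection ID, pool, property, filter, protocol,
  date, pool area, volume, coordinates);
* **qPCR results** — one row per well (``plate_id, well, assay,
  sample_id, role, cq`` with an optional ``run`` column; an empty ``cq``
  cell means no amplification);
* **dip-net results** — one row per sampling event and species.

Dates are ISO-8601 and files are UTF-8 comma-separated with a header.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import DetectionHistory, SamplingEvent, WaterReplicate

__all__ = [
    "FormatError",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_qpcr_results",
    "read_dipnet",
    "attach_calls",
    "build_detection_history",
    "ConcordanceTable",
    "concordance_summary",
    "printed_percent",
    "load_config",
]


class FormatError(ValueError):
    """An input file does not match its documented schema."""


#: canonical sample-sheet column -> accepted aliases (all case-insensitive)
_SHEET_COLUMNS = {
    "collection_id": ("collection_id", "collection id", "unique collection id"),
    "pool_id": ("pool_id", "pool id", "vernal pool id"),
    "property": ("property", "property sampled"),
    "filter_type": ("filter_type", "filter type"),
    "protocol": ("protocol", "filtration protocol", "filtration"),
    "date": ("date", "sampling date"),
    "pool_area_m2": ("pool_area_m2", "pool area m2", "pool area (m2)", "pool area"),
    "volume_ml": ("volume_ml", "volume ml", "water volume (ml)", "water volume sampled (ml)", "volume"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon", "long"),
}
_OPTIONAL_SHEET_COLUMNS = ("latitude", "longitude")


def _canonicalize_columns(columns: Iterable[str]) -> dict[str, str]:
    lookup = {}
    for raw in columns:
        key = str(raw).strip().lower().replace("_", " ")
        for canon, aliases in _SHEET_COLUMNS.items():
            if key in tuple(a.replace("_", " ") for a in aliases):
                lookup[canon] = raw
    return lookup


def read_sample_sheet(path: str | Path) -> list[SamplingEvent]:
    """Read a field sample sheet into sampling events.

    One row per water replicate; rows sharing a pool ID and sampling
    date form one sampling event.  Unparseable rows are skipped with a
    warning.  Raises :class:`FormatError` on a missing mandatory column
    or a duplicated collection ID.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = _canonicalize_columns(df.columns)
    missing = [c for c in _SHEET_COLUMNS if c not in colmap and c not in _OPTIONAL_SHEET_COLUMNS]
    if missing:
        raise FormatError(f"sample sheet is missing mandatory column(s): {', '.join(missing)}")
    dupes = df[colmap["collection_id"]][df[colmap["collection_id"]].duplicated()]
    if len(dupes):
        raise FormatError(f"duplicate collection ID(s): {sorted(set(dupes))}")

    grouped: dict[tuple[str, str], SamplingEvent] = {}
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        try:
            pool = str(row[colmap["pool_id"]]).strip()
            date = _dt.date.fromisoformat(str(row[colmap["date"]]).strip())
            protocol = str(row[colmap["protocol"]]).strip().lower()
            rep = WaterReplicate(
                replicate_id=str(row[colmap["collection_id"]]).strip(),
                volume_ml=float(row[colmap["volume_ml"]]),
                protocol=protocol,
                filter_type=str(row[colmap["filter_type"]]).strip(),
            )
            key = (pool, date.isoformat())
            if key not in grouped:
                grouped[key] = SamplingEvent(
                    event_id=f"{pool}:{date.isoformat()}",
                    pool_id=pool,
                    property_name=str(row[colmap["property"]]).strip(),
                    date=date,
                    pool_area_m2=float(row[colmap["pool_area_m2"]]),
                    replicates=[rep],
                    latitude=_opt_float(row, colmap.get("latitude")),
                    longitude=_opt_float(row, colmap.get("longitude")),
                )
            else:
                grouped[key].replicates.append(rep)
        except (ValueError, KeyError):
            bad_rows.append(int(i))
    if bad_rows:
        warnings.warn(f"skipped {len(bad_rows)} unparseable sample-sheet row(s): {bad_rows}")
    return list(grouped.values())


def _opt_float(row: pd.Series, col: str | None) -> float | None:
    if col is None or pd.isna(row[col]):
        return None
    try:
        return float(row[col])
    except ValueError:
        return None


def write_sample_sheet(events: Sequence[SamplingEvent], path: str | Path) -> None:
    """Write events back to the sample-sheet CSV schema (round-trips
    :func:`read_sample_sheet`)."""
    rows = []
    for ev in events:
        for rep in ev.replicates:
            rows.append(
                {
                    "collection_id": rep.replicate_id,
                    "pool_id": ev.pool_id,
                    "property": ev.property_name,
                    "filter_type": rep.filter_type,
                    "protocol": rep.protocol,
                    "date": ev.date.isoformat(),
                    "pool_area_m2": ev.pool_area_m2,
                    "volume_ml": rep.volume_ml,
                    "latitude": ev.latitude,
                    "longitude": ev.longitude,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_QPCR_ROLES = ("sample", "ntc", "positive_control", "extraction_blank", "field_negative")


def read_qpcr_results(path: str | Path) -> pd.DataFrame:
    """Read the long-format qPCR results table.

    Returns a DataFrame with columns ``plate_id, well, assay, sample_id,
    role, cq, run``; an empty ``cq`` cell (no amplification) becomes NaN
    and a missing ``run`` column defaults to first run.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"plate_id", "well", "assay", "sample_id", "role", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"qPCR table is missing column(s): {', '.join(sorted(missing))}")
    bad_roles = set(df["role"].dropna()) - set(_QPCR_ROLES)
    if bad_roles:
        raise FormatError(f"unknown qPCR role(s): {sorted(bad_roles)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    if "run" not in df.columns:
        df["run"] = 1
    df["run"] = df["run"].fillna(1).astype(int)
    return df


def read_dipnet(path: str | Path) -> pd.DataFrame:
    """Read dip-net survey results (event_id, species, detected[, voucher_confirmed])."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"event_id", "species", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"dip-net table is missing column(s): {', '.join(sorted(missing))}")
    df["detected"] = df["detected"].astype(bool)
    return df


def attach_calls(
    events: Sequence[SamplingEvent],
    calls: pd.DataFrame,
    dipnet: pd.DataFrame | None = None,
) -> list[SamplingEvent]:
    """Attach per-replicate eDNA calls (and dip-net outcomes) to events.

    ``calls`` needs columns ``sample_id`` (= replicate collection ID),
    ``species`` and ``status`` in {positive, negative, discarded}.
    Mutates and returns the event list.
    """
    call_map: dict[str, dict[str, str]] = {}
    for r in calls.itertuples():
        call_map.setdefault(str(r.sample_id), {})[str(r.species)] = str(r.status)
    for ev in events:
        for rep in ev.replicates:
            rep.calls.update(call_map.get(rep.replicate_id, {}))
    if dipnet is not None:
        dn: dict[str, dict[str, bool]] = {}
        for r in dipnet.itertuples():
            dn.setdefault(str(r.event_id), {})[str(r.species)] = bool(r.detected)
        for ev in events:
            ev.dipnet.update(dn.get(ev.event_id, {}))
    return list(events)


def build_detection_history(
    events: Sequence[SamplingEvent],
    species: str,
    certain_from_dipnet: bool = True,
) -> DetectionHistory:
    """Code sampling events into an occupancy detection history.

    With ``certain_from_dipnet`` on, eDNA-positive replicates at
    dip-net-positive events are coded 2 (certain) and positives at
    dip-net-negative events 1 (uncertain); otherwise coding is binary.
    Dip-net-positive events are flagged ``known_occupied``.  Discarded
    or missing replicates are coded NaN; events whose replicates are all
    NaN are dropped.  Rows are ordered by event ID.
    """
    events = sorted(events, key=lambda e: e.event_id)
    max_reps = max(len(e.replicates) for e in events)
    n = len(events)
    obs = np.full((n, max_reps), np.nan)
    volume = np.full((n, max_reps), np.nan)
    protocol = np.full((n, max_reps), np.nan)
    avg_volume = np.full(n, np.nan)
    pool_area = np.full(n, np.nan)
    known = np.zeros(n, dtype=bool)
    n_discarded = 0

    for i, ev in enumerate(events):
        dip = bool(ev.dipnet.get(species, False))
        known[i] = dip
        vols = []
        for j, rep in enumerate(ev.replicates):
            call = rep.calls.get(species, "missing")
            if call == "positive":
                obs[i, j] = 2.0 if (certain_from_dipnet and dip) else 1.0
            elif call == "negative":
                obs[i, j] = 0.0
            else:
                if call == "discarded":
                    n_discarded += 1
                obs[i, j] = np.nan
            volume[i, j] = rep.volume_ml
            protocol[i, j] = 1.0 if rep.protocol == "lab" else 0.0
            vols.append(rep.volume_ml)
        avg_volume[i] = float(np.mean(vols))
        pool_area[i] = ev.pool_area_m2

    keep = ~np.all(np.isnan(obs), axis=1)
    history = DetectionHistory(
        site_ids=[ev.event_id for ev in events],
        observations=obs,
        covariates={
            "volume_per_replicate": volume,
            "avg_volume": avg_volume,
            "pool_area": pool_area,
            "protocol": protocol,
        },
        known_occupied=known,
        n_discarded=n_discarded,
    )
    if not keep.all():
        history = history.subset(np.flatnonzero(keep))
    return history


def printed_percent(numerator: int, denominator: int) -> float | None:
    """A percentage at report precision: round half-up to the nearest
    integer, except keep one decimal when the exact value has exactly
    one (e.g. 5/8 -> 62.5).  Returns None for an undefined (0/0) rate."""
    if denominator == 0:
        return None
    pct = 100.0 * numerator / denominator
    tenths = pct * 10
    if abs(tenths - round(tenths)) < 1e-9 and round(tenths) % 10 != 0:
        return round(tenths) / 10
    return float(math.floor(pct + 0.5))


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 eDNA (E) vs dip-net (D) concordance for one species.

    Counts are events; an event is eDNA-positive when at least one
    non-discarded replicate called positive.  Agreement with positive
    dip-net = E+D+ / (E+D+ + E-D+); agreement with negative dip-net =
    E-D- / (E+D- + E-D-).  Undefined rates (empty denominator) are None,
    never 0.
    """

    species: str
    e_pos_d_pos: int
    e_pos_d_neg: int
    e_neg_d_pos: int
    e_neg_d_neg: int

    @property
    def n_events(self) -> int:
        return self.e_pos_d_pos + self.e_pos_d_neg + self.e_neg_d_pos + self.e_neg_d_neg

    @property
    def agreement_with_positive(self) -> float | None:
        return printed_percent(self.e_pos_d_pos, self.e_pos_d_pos + self.e_neg_d_pos)

    @property
    def agreement_with_negative(self) -> float | None:
        return printed_percent(self.e_neg_d_neg, self.e_pos_d_neg + self.e_neg_d_neg)

    @property
    def disagreement_with_positive(self) -> float | None:
        return printed_percent(self.e_neg_d_pos, self.e_pos_d_pos + self.e_neg_d_pos)

    @property
    def disagreement_with_negative(self) -> float | None:
        return printed_percent(self.e_pos_d_neg, self.e_pos_d_neg + self.e_neg_d_neg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.e_pos_d_pos, self.e_pos_d_neg], [self.e_neg_d_pos, self.e_neg_d_neg]],
            index=["eDNA positive", "eDNA negative"],
            columns=["Dipnet positive", "Dipnet negative"],
        )


def concordance_summary(events: Sequence[SamplingEvent], species: str) -> ConcordanceTable:
    """Summarise eDNA vs dip-net agreement across sampling events.

    Events with no usable eDNA call (all replicates discarded/missing
    for this species) are excluded, so the four counts sum to the number
    of events with non-discarded data.
    """
    counts = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for ev in events:
        e = ev.edna_positive(species)
        if e is None:
            continue
        d = bool(ev.dipnet.get(species, False))
        counts[(e, d)] += 1
    return ConcordanceTable(
        species=species,
        e_pos_d_pos=counts[(True, True)],
        e_pos_d_neg=counts[(True, False)],
        e_neg_d_pos=counts[(False, True)],
        e_neg_d_neg=counts[(False, False)],
    )


_CONFIG_DEFAULTS = {
    "edna_cq_max_cycle": 50.0,   # any reported Cq within the 50-cycle run counts
    "bootstrap_reps": 200,
    "loq_cv_threshold": 0.35,
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """Load the YAML run configuration, filling documented defaults."""
    cfg = dict(_CONFIG_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError("config file must be a YAML mapping")
        cfg.update(user)
    return cfg
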