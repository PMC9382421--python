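"""File readers and writers.

Spike tables and result tables are long-format delimited text (CSV); raw
voltage traces are HDF5 (one dataset per electrode with the sampling rate as
an attribute) with a CSV fallback for small fixtures; manifests are JSON.
Reals are written with 12 significant digits so that result tables round-trip
to that precision and integers exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .config import RunManifest, StudyConfig
from .core import DEFAULT_ELECTRODES, VoltageTrace, WellRecording

logger = logging.getLogger("neuroquant")

SPIKE_COLUMNS = ("well_id", "electrode_id", "spike_time_s")
_METADATA_COLUMNS = ("genotype", "treatment", "timepoint_min")

FLOAT_FORMAT = "%.12g"


def read_spike_table(path: str | Path, duration: float) -> list[WellRecording]:
    """Read a long-format spike table into one ``WellRecording`` per well.

    Columns: well_id, electrode_id, spike_time_s, plus optional metadata
    columns (genotype, treatment, timepoint_min).  Electrodes of the default
    9-electrode layout absent from the file appear with empty trains.  Rows
    with non-numeric, negative or out-of-range times are rejected with their
    row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and not set(SPIKE_COLUMNS) <= set(df.columns):
        return []
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric spike time at row {bad[0] + 2}")
    out_of_range = df.index[(times < 0) | (times > duration)]
    if len(out_of_range):
        row = out_of_range[0]
        raise ValueError(
            f"{path}: spike time {times[row]:g} outside [0, {duration:g}] "
            f"at row {row + 2}"
        )
    df = df.assign(spike_time_s=times)
    recordings = []
    for well_id, sub in df.groupby("well_id", sort=True):
        trains: dict[str, np.ndarray] = {}
        electrodes = set(DEFAULT_ELECTRODES) | set(sub["electrode_id"])
        for eid, esub in sub.groupby("electrode_id"):
            t = np.sort(esub["spike_time_s"].to_numpy(dtype=float))
            if t.size > 1 and np.any(np.diff(t) == 0):
                raise ValueError(
                    f"{path}: duplicate spike time on {well_id}/{eid}")
            trains[eid] = t
        metadata = {}
        for col in _METADATA_COLUMNS:
            if col in sub.columns:
                vals = sub[col].dropna().unique()
                if len(vals):
                    metadata[col] = vals[0]
        recordings.append(WellRecording(
            well_id=str(well_id),
            spike_trains=trains,
            duration=duration,
            electrode_ids=sorted(electrodes),
            metadata=metadata,
        ))
    return recordings


def write_spike_table(recordings: list[WellRecording], path: str | Path) -> Path:
    rows = []
    for rec in recordings:
        for eid in rec.electrode_ids:
            for t in rec.spike_trains[eid]:
                row = {"well_id": rec.well_id, "electrode_id": eid,
                       "spike_time_s": t}
                row.update({k: v for k, v in rec.metadata.items()
                            if k in _METADATA_COLUMNS})
                rows.append(row)
    df = pd.DataFrame(rows, columns=list(SPIKE_COLUMNS) + [
        c for c in _METADATA_COLUMNS
        if any(c in r.metadata for r in recordings)
    ])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return Path(path)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: StudyConfig | None = None,
    seed: int | None = None,
    inputs: dict | None = None,
) -> RunManifest:
    """Write result tables as CSV plus a JSON manifest with config and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        outputs[name] = p.name
        logger.info("wrote %s (%d rows)", p, len(table))
    config = config or StudyConfig()
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.rng_seed if seed is None else seed,
        inputs=inputs or {},
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def read_results(out_dir: str | Path) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    out_dir = Path(out_dir)
    manifest = RunManifest.read(out_dir / "manifest.json")
    tables = {
        name: pd.read_csv(out_dir / fname)
        for name, fname in manifest.outputs.items()
    }
    return tables, manifest


def write_traces_h5(traces: Mapping[str, VoltageTrace], path: str | Path) -> Path:
    """One HDF5 dataset per electrode; sampling rate stored as an attribute."""
    with h5py.File(path, "w") as fh:
        for eid, tr in traces.items():
            ds = fh.create_dataset(eid, data=tr.samples)
            ds.attrs["sampling_rate_hz"] = tr.sampling_rate
    return Path(path)


def read_traces_h5(path: str | Path) -> dict[str, VoltageTrace]:
    out = {}
    with h5py.File(path, "r") as fh:
        for eid in fh:
            ds = fh[eid]
            out[eid] = VoltageTrace(ds[()], float(ds.attrs["sampling_rate_hz"]), eid)
    return out


def write_traces_csv(traces: Mapping[str, VoltageTrace], path: str | Path) -> Path:
    """CSV fallback for small fixtures: columns are electrodes; one header row
    carries the sampling rate."""
    rates = {tr.sampling_rate for tr in traces.values()}
    if len(rates) != 1:
        raise ValueError("CSV trace files require a single sampling rate")
    df = pd.DataFrame({eid: tr.samples for eid, tr in traces.items()})
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rates.pop():.12g}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    return Path(path)


def read_traces_csv(path: str | Path) -> dict[str, VoltageTrace]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sampling_rate_hz="):
            raise ValueError(f"{path}: missing sampling-rate header")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return {c: VoltageTrace(df[c].to_numpy(), fs, c) for c in df.columns}


def read_fluorescence_matrix(path: str | Path, frame_rate: float) -> pd.DataFrame:
    """Delimited frames x ROIs intensity matrix (frame rate from the manifest)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trace matrix")
    df.attrs["frame_rate"] = frame_rate
    return df
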