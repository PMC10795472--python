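"""Reading and writing of current traces, event tables and flat config files.

The canonical on-disk trace format is a two-column CSV (``time_s,current_pA``)
preceded by ``# key=value`` header lines carrying the sampling rate and any
free-form metadata.  A packed NumPy binary (``.npy`` plus a ``.cfg`` sidecar)
and an HDF5 container are offered for large traces.  Event tables are TSV with
a fixed header; run configuration is a flat ``key = value`` text format.

Currents are stored signed in pA.  Blockades are decreases toward zero from a
positive open-pore baseline (+100 mV convention); traces recorded with the
opposite polarity are flipped at read time and the flip recorded in metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "read_trace",
    "write_trace",
    "read_event_table",
    "write_event_table",
    "validate_event_table",
    "events_to_frame",
    "read_config",
    "write_config",
    "read_extrema",
    "write_extrema",
]


@dataclass
class CurrentTrace:
    """A uniformly sampled single-channel current recording.

    Parameters
    ----------
    samples : ndarray
        Current values in pA.
    sampling_rate : float
        Acquisition rate in Hz (e.g. 10000 for a 10 kHz recording).
    start_time : float
        Time of the first sample in seconds.
    metadata : dict
        Free-form key/value metadata (applied voltage, buffer label, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must hold at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


def _normalize_polarity(trace: CurrentTrace) -> CurrentTrace:
    """Flip the trace sign if the baseline is negative (recorded in metadata)."""
    if np.median(trace.samples) < 0:
        trace.samples = -trace.samples
        trace.metadata["polarity_flipped"] = True
    return trace


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".npy":
        return "npy"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer trace format from extension {suffix!r}")


def read_trace(path, format: str | None = None, sampling_rate: float | None = None) -> CurrentTrace:
    """Load a current trace from disk.

    ``format`` is one of ``{"csv", "npy", "hdf5"}``; if omitted it is inferred
    from the file extension.  A sampling rate must be present in the file, its
    sidecar, or supplied explicitly — otherwise this is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        trace = _read_trace_csv(path, sampling_rate)
    elif fmt == "npy":
        trace = _read_trace_npy(path, sampling_rate)
    elif fmt == "hdf5":
        trace = _read_trace_hdf5(path, sampling_rate)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return _normalize_polarity(trace)


def write_trace(trace: CurrentTrace, path, format: str | None = None) -> None:
    """Write a trace to disk in the requested (or extension-inferred) format."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_trace_csv(trace, path)
    elif fmt == "npy":
        _write_trace_npy(trace, path)
    elif fmt == "hdf5":
        _write_trace_hdf5(trace, path)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def _header_lines(trace: CurrentTrace) -> list[str]:
    lines = [
        "# poreptm-trace v1",
        f"# sampling_rate_hz={trace.sampling_rate!r}",
        f"# start_time_s={trace.start_time!r}",
    ]
    for key, value in trace.metadata.items():
        lines.append(f"# meta.{key}={value}")
    return lines


def _write_trace_csv(trace: CurrentTrace, path: Path) -> None:
    times = trace.times
    with open(path, "w") as fh:
        for line in _header_lines(trace):
            fh.write(line + "\n")
        fh.write("time_s,current_pA\n")
        for t, c in zip(times, trace.samples):
            # %.17g preserves float64 bit-exactly across the round trip
            fh.write(f"{t:.9f},{c:.17g}\n")


def _parse_meta(raw: dict[str, str]) -> tuple[float | None, float, dict]:
    rate = float(raw["sampling_rate_hz"]) if "sampling_rate_hz" in raw else None
    start = float(raw.get("start_time_s", 0.0))
    meta = {}
    for key, value in raw.items():
        if key.startswith("meta."):
            meta[key[5:]] = value
    return rate, start, meta


def _read_trace_csv(path: Path, sampling_rate: float | None) -> CurrentTrace:
    raw_meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                raw_meta[key.strip()] = value.strip()
    rate, start, meta = _parse_meta(raw_meta)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty trace: {path} contains a header but no samples")
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(numeric.isna().to_numpy())
        if bad.size:
            raise ValueError(f"non-numeric value in column {col!r} at data row {bad[0]}")
        df[col] = numeric
    if rate is None:
        rate = sampling_rate
    if rate is None:
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("sampling rate missing and cannot be derived from a single sample")
        rate = (t.size - 1) / (t[-1] - t[0])
    return CurrentTrace(df["current_pA"].to_numpy(), float(rate), start, meta)


def _write_trace_npy(trace: CurrentTrace, path: Path) -> None:
    np.save(path, trace.samples)
    cfg = {"sampling_rate_hz": trace.sampling_rate, "start_time_s": trace.start_time}
    cfg.update({f"meta.{k}": v for k, v in trace.metadata.items()})
    write_config(cfg, path.with_suffix(path.suffix + ".cfg"))


def _read_trace_npy(path: Path, sampling_rate: float | None) -> CurrentTrace:
    samples = np.load(path)
    sidecar = path.with_suffix(path.suffix + ".cfg")
    rate, start, meta = None, 0.0, {}
    if sidecar.exists():
        cfg = read_config(sidecar)
        raw = {str(k): str(v) for k, v in cfg.items()}
        rate, start, meta = _parse_meta(raw)
    if rate is None:
        rate = sampling_rate
    if rate is None:
        raise ValueError(f"sampling rate missing: no sidecar {sidecar.name} and none supplied")
    if samples.size == 0:
        raise ValueError(f"empty trace: {path}")
    return CurrentTrace(samples, float(rate), start, meta)


def _write_trace_hdf5(trace: CurrentTrace, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("current_pA", data=trace.samples)
        dset.attrs["sampling_rate_hz"] = trace.sampling_rate
        dset.attrs["start_time_s"] = trace.start_time
        dset.attrs["metadata_json"] = json.dumps(trace.metadata, default=str)


def _read_trace_hdf5(path: Path, sampling_rate: float | None) -> CurrentTrace:
    with h5py.File(path, "r") as fh:
        dset = fh["current_pA"]
        samples = dset[...]
        rate = float(dset.attrs.get("sampling_rate_hz", 0.0)) or sampling_rate
        start = float(dset.attrs.get("start_time_s", 0.0))
        meta = json.loads(dset.attrs.get("metadata_json", "{}"))
    if rate is None or not rate:
        raise ValueError("sampling rate missing from HDF5 attributes and none supplied")
    if samples.size == 0:
        raise ValueError(f"empty trace: {path}")
    return CurrentTrace(samples, float(rate), start, meta)


# ---------------------------------------------------------------------------
# Event tables

REQUIRED_COLUMNS = (
    "event_id",
    "trace_id",
    "start_index",
    "end_index",
    "dwell_ms",
    "mean_residual_pA",
    "rel_current_pct",
    "rel_sigma",
    "n_extrema",
)
OPTIONAL_COLUMNS = ("label", "prediction", "assessment_score")


def validate_event_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming the offending column on any schema violation.

    Optional columns (label, prediction, assessment_score) may be absent, but
    when present must be fully populated.  ``rel_sigma`` may be NaN (undefined
    when the open-pore SD is zero).
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event table missing required column {col!r}")
    unknown = set(df.columns) - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        raise ValueError(f"event table has unknown column(s) {sorted(unknown)!r}")
    if len(df) == 0:
        return
    if not (df["start_index"] < df["end_index"]).all():
        raise ValueError("invalid column 'start_index'/'end_index': need start_index < end_index")
    if not (df["dwell_ms"] > 0).all():
        raise ValueError("invalid column 'dwell_ms': must be > 0")
    if not (df["rel_current_pct"] >= 0).all():
        raise ValueError("invalid column 'rel_current_pct': must be >= 0")
    for col in OPTIONAL_COLUMNS:
        if col in df.columns and df[col].isna().any():
            raise ValueError(f"optional column {col!r} is partially present (contains missing values)")
    if "assessment_score" in df.columns:
        s = df["assessment_score"]
        if not ((s >= 0) & (s <= 1)).all():
            raise ValueError("invalid column 'assessment_score': must lie in [0, 1]")


def write_event_table(df: pd.DataFrame, path) -> None:
    validate_event_table(df)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    validate_event_table(df)
    return df


def events_to_frame(events, trace_id: str = "trace") -> pd.DataFrame:
    """Build an event-table DataFrame from a list of feature-populated events."""
    rows = []
    for k, ev in enumerate(events):
        row = {
            "event_id": k,
            "trace_id": trace_id,
            "start_index": ev.start_index,
            "end_index": ev.end_index,
            "dwell_ms": ev.dwell_ms,
            "mean_residual_pA": ev.mean_residual_pA,
            "rel_current_pct": ev.rel_current_pct,
            "rel_sigma": np.nan if ev.rel_sigma is None else ev.rel_sigma,
            "n_extrema": len(ev.extrema),
        }
        if ev.label is not None:
            row["label"] = ev.label
        if ev.prediction is not None:
            row["prediction"] = ev.prediction
        if ev.assessment_score is not None:
            row["assessment_score"] = ev.assessment_score
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + [
        c for c in OPTIONAL_COLUMNS if rows and c in rows[0]
    ])
    validate_event_table(df)
    return df


# ---------------------------------------------------------------------------
# Flat key = value configuration files


def _parse_value(text: str):
    text = text.strip()
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    if text.lower() in ("none", ""):
        return None
    return text


def read_config(path) -> dict:
    cfg = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            cfg[key.strip()] = _parse_value(value)
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


# ---------------------------------------------------------------------------
# Extrema sidecar (event_id, time within event, relative current)


def write_extrema(extrema_by_event: dict[int, np.ndarray], path) -> None:
    """Write per-event extrema as TSV rows of (event_id, t_s, rel_current_pct)."""
    with open(path, "w") as fh:
        fh.write("event_id\tt_s\trel_current_pct\n")
        for event_id, arr in extrema_by_event.items():
            for t, c in np.atleast_2d(np.asarray(arr, dtype=float)) if len(arr) else []:
                fh.write(f"{event_id}\t{t:.9g}\t{c:.9g}\n")


def read_extrema(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, np.ndarray] = {}
    for event_id, grp in df.groupby("event_id", sort=True):
        out[int(event_id)] = grp[["t_s", "rel_current_pct"]].to_numpy(dtype=float)
    return out
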