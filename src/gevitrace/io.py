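"""Trace-table and report I/O.

Traces travel as tidy delimited text (columns ``time_s``, ``value``, and
optional ``voxel_id``/``trial_id``) with a sidecar JSON metadata record
(value kind, frame rate, events, schedule, seed, config hash). Reports are
JSON. All writers are deterministic: identical inputs and config produce
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .trace import Event, Trace

REQUIRED_COLUMNS = ("time_s", "value")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "value": tr.values,
                    "voxel_id": tr.voxel_id if tr.voxel_id is not None else 0,
                    "trial_id": tr.trial_id if tr.trial_id is not None else 0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trace_table(
    traces: list[Trace],
    path: str | Path,
    metadata: dict | None = None,
    sep: str = "\t",
) -> Path:
    """Write traces as a tidy table plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    df = traces_to_frame(traces)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    first = traces[0]
    meta = {
        "version": __version__,
        "kind": first.kind,
        "frame_rate_hz": first.frame_rate,
        "polarity": first.polarity,
        "events": [
            {"kind": ev.kind, "time": ev.time} for ev in first.events
        ],
        "n_traces": len(traces),
        **(metadata or {}),
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_trace_table(
    path: str | Path,
    kind: str | None = None,
    sep: str = "\t",
) -> list[Trace]:
    """Read a tidy trace table back into validated :class:`Trace` objects.

    The value kind and events come from the sidecar when present, otherwise
    from the ``kind`` argument. Structural problems (missing header,
    duplicated timestamps, non-monotone time) raise :class:`ParseError`
    naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"could not read {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    trace_kind = kind or meta.get("kind", "counts")
    events = [Event(e["kind"], e["time"]) for e in meta.get("events", [])]
    polarity = int(meta.get("polarity", -1))

    if "voxel_id" not in df.columns:
        df["voxel_id"] = 0
    if "trial_id" not in df.columns:
        df["trial_id"] = 0

    traces = []
    for (voxel, trial), grp in df.groupby(["voxel_id", "trial_id"], sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            row = grp.index[dup[0] + 1]
            raise ParseError(
                f"{path}: duplicated timestamp {t[dup[0]]:g} at row {row + 2} "
                f"(voxel {voxel}, trial {trial})"
            )
        bad = np.flatnonzero(np.diff(t) < 0)
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise ParseError(
                f"{path}: non-monotone time at row {row + 2} (voxel {voxel}, trial {trial})"
            )
        tr_events = [ev for ev in events if t[0] <= ev.time <= t[-1]]
        traces.append(
            Trace(
                times=t,
                values=grp["value"].to_numpy(dtype=float),
                kind=trace_kind,
                voxel_id=voxel,
                trial_id=trial,
                events=tr_events,
                polarity=polarity,
                meta={k: v for k, v in meta.items() if k not in ("events", "kind", "polarity")},
            )
        )
    if not traces:
        raise ParseError(f"{path}: table contains no rows")
    return traces


def write_report(report: dict, path: str | Path, config: dict | None = None) -> Path:
    """Write a JSON report with provenance (version, config hash, seed)."""
    path = Path(path)
    payload = dict(report)
    payload.setdefault("provenance", {})
    payload["provenance"].setdefault("version", __version__)
    if config is not None:
        payload["provenance"]["config_hash"] = config_hash(config)
        if "seed" in config:
            payload["provenance"]["seed"] = config["seed"]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON config ({exc})") from exc
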