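"""Serialization of recordings, feature tables and run manifests.

Recordings are stored as HDF5 (``/signals`` float32 channels x samples in
uV, ``/meta/fs_hz``, channel-metadata and poration-event tables), with an
NPZ fallback carrying identical keys. Feature tables are plain CSV with a
stable column order, suitable as human-diffable fixtures. All times are
seconds (float64); channel indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .synth_interface import ElectrodeState, PorationEvent, Recording

__all__ = [
    "RunManifest",
    "config_hash",
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_COLUMNS",
]

#: Stable column order of the per-electrode, per-timepoint feature table.
FEATURE_COLUMNS = [
    "electrode_id",
    "repeat_idx",
    "phase",
    "label",
    "ap_amplitude_mv",
    "apd90_ms",
    "tdep_ms",
    "fp_amplitude_uv",
    "n_beats_averaged",
    "t_measure_s",
]

_CHANNEL_FIELDS = [
    ("electrode_id", "i8"),
    ("x_um", "f8"),
    ("y_um", "f8"),
    ("seal_quality", "f8"),
    ("k_ec", "f8"),
    ("k_ic", "f8"),
    ("tau_reseal_s", "f8"),
    ("noise_sd_uv", "f8"),
]

_EVENT_FIELDS = [
    ("electrode_id", "i8"),
    ("t_end_s", "f8"),
    ("success", "i1"),
    ("g0_realized", "f8"),
    ("offset_mv", "f8"),
    ("offset_tau_s", "f8"),
]


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (key-sorted) JSON rendering of a config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    run_id: str
    seed: int
    config_hash: str
    created_utc: str = ""
    inputs: List[str] = dataclasses.field(default_factory=list)
    outputs: List[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.created_utc:
            self.created_utc = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _channel_meta_array(meta: List[ElectrodeState]) -> np.ndarray:
    arr = np.zeros(len(meta), dtype=_CHANNEL_FIELDS)
    for i, s in enumerate(meta):
        for name, _ in _CHANNEL_FIELDS:
            arr[i][name] = getattr(s, name)
    return arr


def _events_array(events: List[PorationEvent]) -> np.ndarray:
    arr = np.zeros(len(events), dtype=_EVENT_FIELDS)
    for i, e in enumerate(events):
        arr[i]["electrode_id"] = e.electrode_id
        arr[i]["t_end_s"] = e.t_end_s
        arr[i]["success"] = int(e.success)
        arr[i]["g0_realized"] = e.g0_realized
        arr[i]["offset_mv"] = e.offset_mv
        arr[i]["offset_tau_s"] = e.offset_tau_s
    return arr


def _meta_from_array(arr: np.ndarray) -> List[ElectrodeState]:
    return [
        ElectrodeState(
            electrode_id=int(r["electrode_id"]),
            x_um=float(r["x_um"]),
            y_um=float(r["y_um"]),
            seal_quality=float(r["seal_quality"]),
            k_ec=float(r["k_ec"]),
            k_ic=float(r["k_ic"]),
            tau_reseal_s=float(r["tau_reseal_s"]),
            noise_sd_uv=float(r["noise_sd_uv"]),
        )
        for r in arr
    ]


def _events_from_array(arr: np.ndarray) -> List[PorationEvent]:
    return [
        PorationEvent(
            electrode_id=int(r["electrode_id"]),
            t_end_s=float(r["t_end_s"]),
            success=bool(r["success"]),
            g0_realized=float(r["g0_realized"]),
            offset_mv=float(r["offset_mv"]),
            offset_tau_s=float(r["offset_tau_s"]),
        )
        for r in arr
    ]


_KNOWN_EXTRA_SCALARS = ("phase", "repeat_idx")


def write_recording(recording: Recording, path: Union[str, Path]) -> Path:
    """Write a Recording container (HDF5, or NPZ if the suffix is .npz)."""
    path = Path(path)
    sig = np.asarray(recording.signals, dtype=np.float32)
    if path.suffix == ".npz":
        payload: Dict[str, object] = {
            "signals": sig,
            "fs_hz": recording.fs_hz,
            "t0_s": recording.t0_s,
            "protocol_ref": recording.protocol_ref,
            "channel_meta": _channel_meta_array(recording.channel_meta),
            "poration_events": _events_array(recording.poration_events),
        }
        for key, val in recording.extra.items():
            payload[f"extra_{key}"] = val
        np.savez(path, **payload)
        return path

    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=sig)
        meta = f.create_group("meta")
        meta.create_dataset("fs_hz", data=float(recording.fs_hz))
        meta.attrs["t0_s"] = float(recording.t0_s)
        meta.attrs["protocol_ref"] = recording.protocol_ref
        f.create_dataset("channel_meta", data=_channel_meta_array(recording.channel_meta))
        f.create_dataset("poration_events", data=_events_array(recording.poration_events))
        extra = f.create_group("extra")
        for key, val in recording.extra.items():
            if isinstance(val, (np.ndarray, list, tuple)):
                extra.create_dataset(key, data=np.asarray(val))
            else:
                extra.attrs[key] = val
    return path


def read_recording(path: Union[str, Path]) -> Recording:
    """Read a Recording; round trip is lossless for the float32 payload.

    Missing mandatory members raise :class:`FormatError` naming the key; a
    missing poration-event table reads as an empty event list.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for key in ("signals", "fs_hz"):
                if key not in z:
                    raise FormatError(f"missing key {key!r} in {path}")
            extra = {
                k[len("extra_") :]: _denumpy(z[k]) for k in z.files if k.startswith("extra_")
            }
            meta = _meta_from_array(z["channel_meta"]) if "channel_meta" in z.files else []
            events = (
                _events_from_array(z["poration_events"])
                if "poration_events" in z.files
                else []
            )
            rec = _build_recording(
                path,
                signals=z["signals"],
                fs_hz=float(z["fs_hz"]),
                t0_s=float(z["t0_s"]) if "t0_s" in z.files else 0.0,
                channel_meta=meta,
                poration_events=events,
                protocol_ref=str(z["protocol_ref"]) if "protocol_ref" in z.files else "",
                extra=extra,
            )
        _validate(rec, path)
        return rec

    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"missing dataset '/signals' in {path}")
        if "meta" not in f or "fs_hz" not in f["meta"]:
            raise FormatError(f"missing dataset '/meta/fs_hz' in {path}")
        extra: Dict[str, object] = {}
        if "extra" in f:
            for key in f["extra"]:
                extra[key] = f["extra"][key][()]
            for key, val in f["extra"].attrs.items():
                extra[key] = _denumpy(val)
        rec = _build_recording(
            path,
            signals=f["signals"][()],
            fs_hz=float(f["meta"]["fs_hz"][()]),
            t0_s=float(f["meta"].attrs.get("t0_s", 0.0)),
            channel_meta=_meta_from_array(f["channel_meta"][()]) if "channel_meta" in f else [],
            poration_events=_events_from_array(f["poration_events"][()])
            if "poration_events" in f
            else [],
            protocol_ref=str(f["meta"].attrs.get("protocol_ref", "")),
            extra=extra,
        )
    _validate(rec, path)
    return rec


def _build_recording(path: Path, **kwargs) -> Recording:
    try:
        return Recording(**kwargs)
    except ParameterError as exc:  # structural problems surface as format errors
        raise FormatError(f"{path}: {exc}") from exc


def _denumpy(val):
    if isinstance(val, np.ndarray) and val.ndim == 0:
        val = val[()]
    if isinstance(val, bytes):
        return val.decode()
    if isinstance(val, np.generic):
        return val.item()
    return val


def _validate(rec: Recording, path: Path) -> None:
    if rec.channel_meta and len(rec.channel_meta) != rec.signals.shape[0]:
        raise FormatError(
            f"{path}: channel_meta lists {len(rec.channel_meta)} channels but "
            f"signals has {rec.signals.shape[0]}"
        )


def write_feature_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a feature table as CSV with the canonical column order.

    Canonical columns come first (missing ones are added empty); any extra
    columns follow in their existing order.
    """
    path = Path(path)
    df = table.copy()
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    ordered = FEATURE_COLUMNS + [c for c in df.columns if c not in FEATURE_COLUMNS]
    df[ordered].to_csv(path, index=False)
    return path


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} lacks columns {missing}")
    return df
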