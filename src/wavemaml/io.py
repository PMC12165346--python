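"""Recording and checkpoint I/O.

Recordings can be stored two ways:

* a ``.npy`` matrix plus a ``.json`` sidecar (sampling rate, channel names,
  label, subject) — lossless, the preferred interchange format here;
* minimal EDF (16-bit, one data record per second) for interoperability
  with standard EEG viewers. The EDF path quantizes to the per-channel
  physical range and truncates to whole seconds, so round-trips are
  approximate by design.

Checkpoints bundle both base models' parameter archives, the mixing logits
and the training history.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .maml import DualWeights, MetaState
from .models import ArchitectureConfig, MetaParams, load_params, save_params
from .recording import EEGRecording

__all__ = [
    "save_recording",
    "load_recording",
    "write_edf",
    "read_edf",
    "save_checkpoint",
    "load_checkpoint",
]


def save_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write signal as ``<path>.npy`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.signal)
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "label": int(rec.label),
        "subject_id": rec.subject_id,
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EEGRecording(
        signal=np.load(path.with_suffix(".npy")),
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        label=meta.get("label", 0),
        subject_id=meta.get("subject_id", ""),
    )


def _pad(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a minimal EDF file (one 1 s data record per whole second)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = rec.n_channels
    sig = rec.signal[:, : n_records * spr]
    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    scaled = (sig - phys_min[:, None]) / span[:, None] * (dig_max - dig_min) + dig_min
    digital = np.round(scaled).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(rec.subject_id or "X", 80),
        _pad(f"Startdate X label {rec.label}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(name, 16) for name in rec.channel_names],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:.8g}", 8) for v in phys_min],
        [_pad(f"{v:.8g}", 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file written by :func:`write_edf` (or compatible)."""
    raw = Path(path).read_bytes()

    def field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    subject = field(8, 80)
    n_records = int(field(236, 8))
    ns = int(field(252, 4))
    base = 256
    labels = [field(base + 16 * i, 16) for i in range(ns)]
    off = base + ns * (16 + 80 + 8)
    phys_min = np.array([float(field(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    phys_max = np.array([float(field(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_min = np.array([float(field(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_max = np.array([float(field(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8 + ns * 80
    spr = np.array([int(field(off + 8 * i, 8)) for i in range(ns)])
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    record_duration = float(field(244, 8))
    fs = spr0 / record_duration
    data_start = 256 * (1 + ns)
    data = np.frombuffer(raw, dtype="<i2", offset=data_start)
    data = data.reshape(n_records, ns, spr0)
    digital = np.concatenate([data[r] for r in range(n_records)], axis=1).astype(float)
    span_d = np.where(dig_max > dig_min, dig_max - dig_min, 1.0)
    span_p = phys_max - phys_min
    signal = (digital - dig_min[:, None]) / span_d[:, None] * span_p[:, None] + phys_min[:, None]
    label_field = field(88, 80)
    label = int(label_field.rsplit(" ", 1)[-1]) if "label" in label_field else 0
    return EEGRecording(
        signal=signal, fs=fs, channel_names=tuple(labels), label=label, subject_id=subject
    )


def save_checkpoint(state: MetaState, out_dir: str | Path) -> None:
    """Persist both base models, the mixing logits and the history."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_params(state.params_a, out_dir / "model_a")
    save_params(state.params_b, out_dir / "model_b")
    np.save(out_dir / "mixing_logits.npy", state.weights.logits.data)
    pd.DataFrame(state.history).to_csv(out_dir / "history.csv", index=False)


def load_checkpoint(out_dir: str | Path, arch_cfg: ArchitectureConfig) -> MetaState:
    out_dir = Path(out_dir)
    params_a = load_params(out_dir / "model_a", arch_cfg)
    params_b = load_params(out_dir / "model_b", arch_cfg)
    logits = np.load(out_dir / "mixing_logits.npy")
    history_path = out_dir / "history.csv"
    history = (
        pd.read_csv(history_path).to_dict("records") if history_path.exists() else []
    )
    return MetaState(
        params_a=params_a,
        params_b=params_b,
        weights=DualWeights(Tensor(logits.copy(), requires_grad=True)),
        history=history,
    )
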