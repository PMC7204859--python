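"""File formats: the canonical HDF5 trial-set container and an EDF adapter.

The HDF5 layout is the package's exchange format: datasets ``/data`` (trials
x channels x samples, microvolts), ``/labels``, and scalar attributes/datasets
``/fs``, ``/sensitivity``, ``/scope``, ``/channel_names``, ``/subject_id``.

EDF (European Data Format, 16-bit) is a courtesy adapter for interoperating
with clinical tooling: each trial is stored as one data record, and the
trial labels plus container metadata that EDF cannot carry travel in a JSON
sidecar (``<name>.labels.json``).  The writer emits standard EDF; mne can
read the files back.
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .trialset import EEGTrialSet

__all__ = ["read_trialset", "write_trialset", "read_edf", "write_edf"]

_REQUIRED = ("data", "labels", "fs", "sensitivity", "scope")


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_trialset(ts: EEGTrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("labels", data=np.asarray(ts.labels))
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("sensitivity", data=float(ts.sensitivity))
        f.create_dataset("scope", data=np.asarray(ts.scope, dtype=np.float64))
        f.create_dataset(
            "channel_names",
            data=np.array([c.encode() for c in ts.channel_names]),
        )
        f.create_dataset("subject_id", data=ts.subject_id.encode())


def read_trialset(path) -> EEGTrialSet:
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED if k not in f]
        if missing:
            raise ValueError(f"container missing mandatory fields: {missing}")
        names = [c.decode() for c in f["channel_names"][()]] if "channel_names" in f else []
        subject = f["subject_id"][()].decode() if "subject_id" in f else ""
        return EEGTrialSet(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f["fs"][()]),
            sensitivity=float(f["sensitivity"][()]),
            scope=tuple(f["scope"][()]),
            channel_names=names,
            subject_id=subject,
        )


# ---------------------------------------------------------------------------
# EDF adapter (16-bit, one data record per trial)
# ---------------------------------------------------------------------------


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(ts: EEGTrialSet, path) -> None:
    """Write a trial set as 16-bit EDF plus a JSON label sidecar."""
    path = pathlib.Path(path)
    n_sig = ts.n_channels
    n_rec = ts.n_trials
    spr = ts.n_samples  # samples per record per signal
    rec_dur = ts.n_samples / ts.fs
    lo, hi = ts.scope
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),  # patient id (anonymous)
            _pad(f"Startdate X X X X {ts.subject_id or 'X'}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad(f"{rec_dur:.6f}"[:8], 8),
            _pad(str(n_sig), 4),
        ]
    )
    sig_fields = [
        b"".join(_pad(c, 16) for c in ts.channel_names),  # label
        b"".join(_pad("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_pad("uV", 8) for _ in range(n_sig)),
        b"".join(_pad(f"{lo:g}"[:8], 8) for _ in range(n_sig)),  # physical min
        b"".join(_pad(f"{hi:g}"[:8], 8) for _ in range(n_sig)),
        b"".join(_pad(str(dmin), 8) for _ in range(n_sig)),
        b"".join(_pad(str(dmax), 8) for _ in range(n_sig)),
        b"".join(_pad("", 80) for _ in range(n_sig)),  # prefiltering
        b"".join(_pad(str(spr), 8) for _ in range(n_sig)),
        b"".join(_pad("", 32) for _ in range(n_sig)),  # reserved
    ]
    gain = (dmax - dmin) / (hi - lo)
    digital = np.clip(
        np.round((np.clip(ts.data, lo, hi) - lo) * gain + dmin), dmin, dmax
    ).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for blk in sig_fields:
            f.write(blk)
        for r in range(n_rec):
            f.write(digital[r].tobytes())  # channel-major within the record

    sidecar = {
        "labels": np.asarray(ts.labels).tolist(),
        "fs": ts.fs,
        "sensitivity": ts.sensitivity,
        "scope": list(ts.scope),
        "subject_id": ts.subject_id,
    }
    path.with_suffix(path.suffix + ".labels.json").write_text(json.dumps(sidecar))


def read_edf(path) -> EEGTrialSet:
    """Read an EDF file written by :func:`write_edf` (trials = data records).

    Requires the JSON label sidecar; amplitudes are mapped back to
    microvolts from the declared physical range.
    """
    path = pathlib.Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".labels.json")
    if not sidecar_path.exists():
        raise ValueError(f"EDF without sidecar labels: expected {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())

    with open(path, "rb") as f:
        head = f.read(256)
        n_rec = int(head[236:244].decode().strip())
        n_sig = int(head[252:256].decode().strip())
        sig = f.read(256 * n_sig)

        def field(offset, width):
            base = offset * n_sig
            return [
                sig[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(n_sig)
            ]

        labels16 = field(0, 16)
        phys_min = [float(v) for v in field(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in field(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in field(16 + 80 + 8 + 8 + 8, 8)]
        dig_max = [int(v) for v in field(16 + 80 + 8 + 8 + 8 + 8, 8)]
        spr = [int(v) for v in field(16 + 80 + 8 + 4 * 8 + 80, 8)]
        raw = np.frombuffer(f.read(), dtype="<i2")

    spr0 = spr[0]
    data = raw.reshape(n_rec, n_sig, spr0).astype(np.float64)
    for c in range(n_sig):
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        data[:, c] = (data[:, c] - dig_min[c]) * gain + phys_min[c]
    return EEGTrialSet(
        data=data,
        labels=np.asarray(meta["labels"]),
        fs=float(meta["fs"]),
        sensitivity=float(meta["sensitivity"]),
        scope=tuple(meta["scope"]),
        channel_names=labels16,
        subject_id=meta.get("subject_id", ""),
    )
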