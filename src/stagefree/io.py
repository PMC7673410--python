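"""Reading and writing: internal HDF5 recording container, EDF ingest,
TSV tables, plain-text key-value configs, and run manifests.

Recordings are written to an internal hierarchical (HDF5) container; EDF
files are read through MNE.  Tables (features, metadata, reports) are
tab-separated UTF-8 text with a JSON sidecar for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import Recording


def save_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["night"] = rec.night
        f.attrs["fs"] = rec.fs
        f.attrs["channel_labels"] = [c.encode() for c in rec.channel_labels]
        f.create_dataset("samples", data=rec.samples, compression="gzip", compression_opts=4)


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    with h5py.File(path, "r") as f:
        return Recording(
            subject_id=str(f.attrs["subject_id"]),
            night=int(f.attrs["night"]),
            fs=float(f.attrs["fs"]),
            channel_labels=[c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_labels"]],
            samples=f["samples"][()],
        )


def read_edf(path: str | Path, subject_id: str | None = None, night: int = 1) -> Recording:
    """Read an EDF recording via MNE; amplitudes converted to microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    path = Path(path)
    return Recording(
        subject_id=subject_id or path.stem,
        night=night,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        samples=np.asarray(data),
    )


def write_table(table: pd.DataFrame, path: str | Path, sidecar: dict | None = None) -> None:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, default=str)
        )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_keyvalue(d: dict, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in d.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalue(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
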