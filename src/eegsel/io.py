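"""Reading and writing recordings, cohorts and manifests.

Two on-disk recording formats are supported:

* EDF (``.edf``) — read through :mod:`mne` (header supplies montage and fs).
  Import is lazy so the core package does not depend on mne.
* Delimited numeric matrix (``.csv``/``.tsv``) — channels x samples, no
  header — accompanied by a JSON sidecar ``<stem>.json`` declaring ``fs`` and
  ``montage`` (and optionally ``subject_id``/``label``).

A cohort on disk is a directory of per-subject files plus a delimited
manifest with columns ``subject_id,label,path`` (paths relative to the
manifest's directory).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording

MANIFEST_COLUMNS = ("subject_id", "label", "path")


def _read_delimited(path: Path, montage=None, fs=None) -> tuple[np.ndarray, dict]:
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if montage is not None:
        meta["montage"] = list(montage)
    if fs is not None:
        meta["fs"] = fs
    if "montage" not in meta or "fs" not in meta:
        raise ValueError(
            f"{path}: delimited recordings need a JSON sidecar (or explicit "
            "arguments) declaring 'montage' and 'fs'")
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    data = np.loadtxt(path, delimiter=delim, ndmin=2)
    return data, meta


def _read_edf(path: Path, montage=None) -> tuple[np.ndarray, dict]:
    import mne  # lazy: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    meta = {"montage": raw.ch_names, "fs": float(raw.info["sfreq"])}
    if montage is not None:
        meta["montage"] = list(montage)
    return raw.get_data(), meta


def read_recording(path, subject_id=None, label=None, montage=None, fs=None) -> Recording:
    """Load one recording from EDF or delimited matrix.

    Header/sidecar metadata can be overridden by the keyword arguments; a
    channel-count mismatch between the data and the declared montage is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        data, meta = _read_edf(path, montage)
    else:
        data, meta = _read_delimited(path, montage, fs)
    names = tuple(meta["montage"])
    if data.shape[0] != len(names):
        raise ValueError(
            f"{path}: {data.shape[0]} data rows but montage declares {len(names)} channels")
    return Recording(
        subject_id=str(subject_id if subject_id is not None
                       else meta.get("subject_id", path.stem)),
        label=int(label if label is not None else meta.get("label", 0)),
        montage=names, fs=float(meta["fs"]), data=data)


def write_recording(rec: Recording, path) -> Path:
    """Write one recording as a delimited matrix + JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    np.savetxt(path, rec.data, delimiter=delim, fmt="%.9e")
    sidecar = {"subject_id": rec.subject_id, "label": rec.label,
               "fs": rec.fs, "montage": list(rec.montage)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_cohort(recs: "list[Recording]", out_dir) -> Path:
    """Write every recording plus a ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        fname = f"{rec.subject_id}.csv"
        write_recording(rec, out_dir / fname)
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path) -> "list[Recording]":
    """Load every recording listed in a ``subject_id,label,path`` manifest."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    return [read_recording(base / row.path, subject_id=row.subject_id, label=row.label)
            for row in table.itertuples(index=False)]
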