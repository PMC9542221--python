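"""Volume, table and manifest I/O.

Volumes are written as NIfTI-1; the survival table and feature tables as
CSV (features with a sidecar JSON schema); run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .phantom import SubjectRecord
from .radiomics import parse_feature_name

__all__ = ["save_volume", "load_volume", "save_subject", "save_feature_table",
           "load_feature_table", "write_manifest"]

_EYE = np.eye(4)


def save_volume(arr: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), _EYE), str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_subject(record: SubjectRecord, out_dir: str | Path) -> Path:
    """Write maps, labels and weighted contrasts of one subject."""
    d = Path(out_dir) / record.subject_id
    for name, arr in (("t1map", record.maps.t1), ("t2map", record.maps.t2),
                      ("pdmap", record.maps.pd)):
        save_volume(arr, d / f"{name}.nii.gz")
    save_volume(record.labels.astype(np.float32), d / "labels.nii.gz")
    for contrast, img in record.weighted.items():
        save_volume(img.intensities, d / f"{contrast}.nii.gz")
    return d


def load_subject(subject_dir: str | Path,
                 survival_row: pd.Series | None = None) -> SubjectRecord:
    """Round-trip a subject written by :func:`save_subject`."""
    from .phantom import LABEL_CODES
    from .physics import RelaxometryMaps, WeightedImage, default_protocol

    d = Path(subject_dir)
    t1 = load_volume(d / "t1map.nii.gz")
    t2 = load_volume(d / "t2map.nii.gz")
    pd_map = load_volume(d / "pdmap.nii.gz")
    labels = load_volume(d / "labels.nii.gz").astype(np.int16)
    fg = labels > 0
    maps = RelaxometryMaps(t1, t2, pd_map, fg)
    tumor = ((labels == LABEL_CODES["ET"]) | (labels == LABEL_CODES["NET"])
             | (labels == LABEL_CODES["ED"]))
    xs = np.nonzero(tumor)[0]
    hemi = "left" if (xs.size and xs.mean() < labels.shape[0] / 2) else "right"
    rec = SubjectRecord(d.name, maps, labels, hemi)
    protocol = default_protocol()
    for contrast, params in protocol.items():
        p = d / f"{contrast}.nii.gz"
        if p.exists():
            rec.weighted[contrast] = WeightedImage(load_volume(p), contrast, params, fg)
    if survival_row is not None:
        rec.survival_days = int(survival_row["survival_days"])
        rec.censored = int(survival_row["censored"])
    return rec


def save_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="subject_id")
    schema = {
        "columns": [dict(zip(("contrast", "roi", "family", "feature"),
                             parse_feature_name(c)), name=c)
                    for c in table.columns],
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    return path


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_manifest(out_dir: str | Path, config: dict, seed: int,
                   threshold_days: int = 480) -> Path:
    """Record config hash, seed, package version and the survival threshold."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "qmrsynth",
        "version": __version__,
        "seed": seed,
        "threshold_days": threshold_days,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob) if blob.startswith("{") else blob,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
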