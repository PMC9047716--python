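"""NIfTI and table I/O, run manifests, and fixture-set writing.

All volumes travel as NIfTI-1: intensity as float32, label maps as
int16 (read back as integers).  Cohort tables are UTF-8 CSV with a
header row; any table this package writes starts with a
``# manifest_hash=...`` comment line tying it to its run manifest, and
the readers here skip ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .catalog import SCORE_COLUMNS, TEST_KEYS

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "grade", "age", "sex"] + [
    SCORE_COLUMNS[t] for t in TEST_KEYS
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a volume; label images (integer on disk) come back as int."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if np.issubdtype(img.get_data_dtype(), np.integer):
        data = data.astype(np.int64)
    return data, img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_image_pair(
    image_path, labels_path, affine_tol: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity volume + integer label map, validated to share a grid.

    Affine disagreement beyond ``affine_tol`` (in affine-entry units,
    i.e. mm for the translation column) is rejected.
    """
    intensity, affine_i = read_nifti(image_path)
    labels, affine_l = read_nifti(labels_path)
    if intensity.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: image {intensity.shape} vs labels {labels.shape}"
        )
    if np.max(np.abs(affine_i - affine_l)) > affine_tol:
        raise ValueError("affine mismatch between image and labels exceeds tolerance")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label volume must be integer-typed")
    return intensity, labels, affine_i


def voxel_spacing(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; missing cells are rejected by row."""
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    bad_rows = df.index[df[COHORT_COLUMNS].isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValueError(f"cohort table has missing values in rows {bad_rows}")
    return df


def write_table(df: pd.DataFrame, path, manifest_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if manifest_hash:
            fh.write(f"# manifest_hash={manifest_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _canonical(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _canonical(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def spec_hash(obj) -> str:
    """Stable SHA-256 of a (nested) spec object; dataclasses welcome."""
    payload = json.dumps(_canonical(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(_canonical(manifest), indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fixture_set(cohort: pd.DataFrame, phantoms, out_dir, spec, seed: int) -> dict:
    """Write one intensity + one label NIfTI per subject, plus cohort CSV
    and a manifest recording the seed and the phantom-spec hash.

    ``phantoms`` is an iterable of (intensity, labels) aligned with the
    cohort rows.  An existing manifest with a different spec hash means
    the directory holds a different fixture set; refuse to overwrite.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = spec_hash(spec)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        previous = read_manifest(manifest_path)
        if previous.get("spec_hash") != h:
            raise FileExistsError(
                f"{manifest_path} belongs to a different phantom spec; refusing to overwrite"
            )

    files = []
    for (_, row), (intensity, labels) in zip(cohort.iterrows(), phantoms):
        sid = row["subject_id"]
        img_path = out_dir / f"{sid}_T1w.nii.gz"
        lab_path = out_dir / f"{sid}_labels.nii.gz"
        write_nifti(img_path, np.asarray(intensity, dtype=np.float32))
        write_nifti(lab_path, np.asarray(labels, dtype=np.int16))
        files.extend([img_path.name, lab_path.name])

    cohort_path = out_dir / "cohort.csv"
    write_table(cohort, cohort_path)
    files.append(cohort_path.name)

    manifest = {
        "seed": int(seed),
        "spec_hash": h,
        "n_subjects": int(len(cohort)),
        "files": sorted(files),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    write_manifest(manifest_path, manifest)
    return manifest
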