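"""Readers and writers for the standard formats the pipeline touches.

Streamlines travel as TCK (world-space mm, RAS+), voxel fields as NIfTI-1
4D volumes (SH coefficients or tensor components on the 4th axis), tabular
outputs as TSV with '.' decimals, and configuration as YAML.  Every output
directory gets a JSON provenance record (config hash, version, seeds,
timestamps, output digests).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fod_metrics import FODField, TensorField
from .shbasis import order_from_ncoef
from .tractometry import ProfileMatrix, StreamlineBundle

TENSOR_COMPONENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


class DataFormatError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# TCK
# ---------------------------------------------------------------------------

def read_tck(path: str | Path, name: str | None = None) -> StreamlineBundle:
    """Read a TCK file into a bundle of world-space (mm) polylines."""
    path = Path(path)
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises various header errors
        raise DataFormatError(f"cannot parse TCK file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    return StreamlineBundle(name or path.stem, streamlines)


def write_tck(bundle: StreamlineBundle, path: str | Path) -> Path:
    """Write a bundle to TCK (coordinates already in RAS+ mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tractogram = nib.streamlines.Tractogram(
        bundle.streamlines, affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))
    return path


# ---------------------------------------------------------------------------
# NIfTI fields
# ---------------------------------------------------------------------------

def read_nifti_field(path: str | Path, kind: str) -> FODField | TensorField:
    """Load a 4D NIfTI as an SH (``kind='sh'``) or tensor (``kind='tensor'``) field.

    The affine is nibabel's best transform (sform preferred over qform).
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise DataFormatError(f"{path}: expected a 4D volume, found {data.ndim}D")
    if kind == "sh":
        try:
            order = order_from_ncoef(data.shape[3])
        except ValueError as exc:
            raise DataFormatError(
                f"{path}: 4th dimension {data.shape[3]} is not an even-order "
                f"SH coefficient count"
            ) from exc
        return FODField(data, np.asarray(img.affine), order)
    if kind == "tensor":
        if data.shape[3] != 6:
            raise DataFormatError(
                f"{path}: tensor volume needs 6 components, found {data.shape[3]}"
            )
        return TensorField(data, np.asarray(img.affine))
    raise ValueError(f"kind must be 'sh' or 'tensor', got {kind!r}")


def write_nifti_field(field: FODField | TensorField, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = field.coefficients if isinstance(field, FODField) else field.tensors
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), field.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "group", "hl_db", "thi", "duration_y", "age_y"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"cohort table {path} lacks columns: {sorted(missing)}")
    return df


def write_profile_tsv(profile: ProfileMatrix, path: str | Path) -> Path:
    """Profile matrix as TSV: rows = subjects, columns seg000..seg099."""
    cols = [f"seg{j:03d}" for j in range(profile.values.shape[1])]
    df = pd.DataFrame(profile.values, columns=cols)
    df.insert(0, "subject", profile.subject_ids)
    df.attrs["bundle"] = profile.bundle_name
    df.attrs["metric"] = profile.metric_name
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# bundle={profile.bundle_name}\tmetric={profile.metric_name}\t"
                 f"tractoprofile={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_profile_tsv(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataFormatError(f"{path}: missing provenance header line")
        meta = dict(
            item.split("=", 1) for item in header[1:].strip().split("\t") if "=" in item
        )
        df = pd.read_csv(fh, sep="\t")
    values = df.drop(columns=["subject"]).to_numpy(dtype=float)
    return ProfileMatrix(
        meta.get("bundle", path.stem),
        meta.get("metric", "unknown"),
        values,
        df["subject"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# Config + provenance
# ---------------------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: top-level YAML structure must be a mapping")
    return data


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_provenance(
    out_dir: str | Path, config: dict, seed: int, outputs: list[Path]
) -> Path:
    out_dir = Path(out_dir)
    record = {
        "software": "tractoprofile",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_digest(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "outputs": {
            str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in outputs
            if p.is_file()
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
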