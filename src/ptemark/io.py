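"""Reading and writing the pipeline's on-disk artifacts.

Volumes (3-D anatomy, 4-D time series, integer parcellations) go to NIfTI
with an identity affine in the synthetic grid — real-data users must
pre-register their volumes to a common grid themselves.  Tables go to
CSV/TSV with stable column order; reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume",
    "load_volume",
    "save_table",
    "load_table",
    "save_json",
    "load_json",
    "io_roundtrip",
    "save_orthoslices",
]


def save_volume(array: np.ndarray, path, spacing: float = 1.0) -> Path:
    path = Path(path)
    array = np.asarray(array)
    if array.dtype == bool:
        array = array.astype(np.uint8)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    nib.save(nib.Nifti1Image(array, affine), str(path))
    return path


def load_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj)


def save_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=index)
    return path


def load_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_json(path):
    return json.loads(Path(path).read_text())


def io_roundtrip(obj, path):
    """Write ``obj`` to ``path`` (format by extension) and read it back.

    Tables reproduce bitwise including column order; volumes to float
    precision of the stored dtype.  Unsupported extensions raise.
    """
    path = Path(path)
    suffix = "".join(path.suffixes)
    if suffix.endswith((".nii", ".nii.gz")):
        save_volume(obj, path)
        return load_volume(path)
    if path.suffix in (".csv", ".tsv"):
        save_table(obj, path)
        return load_table(path)
    if path.suffix == ".json":
        save_json(obj, path)
        return load_json(path)
    raise ValueError(f"unsupported extension for {path.name!r}")


def save_orthoslices(volume: np.ndarray, path, title: str | None = None) -> Path:
    """Simple three-panel orthogonal mid-slice PNG of a 3-D volume."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    volume = np.asarray(volume, dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    mids = [s // 2 for s in volume.shape]
    views = [volume[mids[0], :, :], volume[:, mids[1], :], volume[:, :, mids[2]]]
    for ax, view in zip(axes, views):
        ax.imshow(view.T, origin="lower", cmap="gray")
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
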