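"""Volume and table I/O: NIfTI volumes, PNG previews, CSV manifests, and
YAML run configurations.

Volumes are stored as 16-bit signed NIfTI with pixel spacing and slice
thickness in the header zooms, which round-trips HU values exactly after
integer rounding.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import HU_MAX, HU_MIN, HUImage
from .phantom import PairedSlice

__all__ = ["read_volume", "write_volume", "write_preview",
           "write_dataset", "read_dataset", "load_config", "save_config"]


def write_volume(volume: list[HUImage] | HUImage, path) -> Path:
    """Write a slice stack as int16 NIfTI; geometry goes into the header."""
    path = Path(path)
    slices = [volume] if isinstance(volume, HUImage) else list(volume)
    if not slices:
        raise ValueError("empty volume")
    sx, sy = slices[0].pixel_spacing
    dz = slices[0].slice_thickness
    data = np.stack([np.clip(np.rint(s.pixels), HU_MIN, HU_MAX)
                     for s in slices], axis=-1).astype(np.int16)
    # nibabel axis order (x, y, z) with row-major slices -> transpose rows/cols
    data = np.transpose(data, (1, 0, 2))
    affine = np.diag([sx, sy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, dz))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_volume(path) -> list[HUImage]:
    """Read a NIfTI volume into a list of per-slice HU images."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    zooms = img.header.get_zooms()
    if len(zooms) >= 3 and all(z > 0 for z in zooms[:3]):
        sx, sy, dz = (float(z) for z in zooms[:3])
    else:
        warnings.warn(f"{path}: missing geometry; assuming 1x1 mm, 3 mm slices")
        sx, sy, dz = 1.0, 1.0, 3.0
    data = np.transpose(data, (1, 0, 2))
    return [HUImage(data[:, :, k], (sx, sy), dz) for k in range(data.shape[2])]


def write_preview(image: HUImage, path, window: float = 2000.0,
                  level: float = 0.0) -> Path:
    """8-bit PNG preview with a display window/level in HU."""
    path = Path(path)
    lo, hi = level - window / 2.0, level + window / 2.0
    arr = np.clip((image.pixels - lo) / (hi - lo), 0, 1)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (arr * 255).astype(np.uint8))
    return path


def write_dataset(pairs: list[PairedSlice], out_dir, previews: bool = False,
                  extra: dict | None = None) -> Path:
    """Write paired slices as per-slice NIfTI files plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index_by_subject: dict[str, int] = {}
    for pair in pairs:
        k = index_by_subject.get(pair.subject_id, 0)
        index_by_subject[pair.subject_id] = k + 1
        stem = f"{pair.subject_id}_z{k:03d}"
        ct_path = out_dir / f"{stem}_ct.nii.gz"
        cbct_path = out_dir / f"{stem}_cbct.nii.gz"
        write_volume(pair.ct, ct_path)
        write_volume(pair.cbct, cbct_path)
        if previews:
            write_preview(pair.ct, out_dir / f"{stem}_ct.png")
            write_preview(pair.cbct, out_dir / f"{stem}_cbct.png")
        rows.append({"subject_id": pair.subject_id, "slice_index": k,
                     "ct_path": ct_path.name, "cbct_path": cbct_path.name,
                     "isocenter_dx": pair.isocenter_offset[0],
                     "isocenter_dy": pair.isocenter_offset[1],
                     "seed": pair.seed, **(extra or {})})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path) -> list[PairedSlice]:
    """Load a paired dataset back from its manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    pairs = []
    for _, row in df.iterrows():
        ct = read_volume(base / row["ct_path"])[0]
        cbct = read_volume(base / row["cbct_path"])[0]
        pairs.append(PairedSlice(
            ct=ct, cbct=cbct, subject_id=str(row["subject_id"]),
            isocenter_offset=(int(row["isocenter_dx"]), int(row["isocenter_dy"])),
            seed=int(row.get("seed", 0))))
    return pairs


def save_config(config: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    return yaml.safe_load(path.read_text()) or {}


def save_weights(model, path, config_repr: str = "") -> Path:
    """Model weights as an .npz plus a sidecar JSON with a config hash and
    the parameter count."""
    from .nn import count_trainable_parameters

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state()
    np.savez(path, *state)
    sidecar = {"config": config_repr,
               "config_hash": abs(hash(config_repr)) % (16 ** 8),
               "n_parameters": count_trainable_parameters(model),
               "n_tensors": len(state)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_weights(model, path) -> None:
    with np.load(path) as data:
        state = [data[k] for k in data.files]
    model.load_state(state)
    model.trained = True
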