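"""Reading and writing the standard on-disk formats.

NIfTI volumes through nibabel, FSL-style plain-text bval/bvec files,
a JSON manifest for the tract atlas, and CSV tables through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .noddi import DiffusionScheme
from .phantom import TractAtlas

__all__ = [
    "save_volume",
    "load_volume",
    "save_scheme",
    "load_scheme",
    "save_atlas",
    "load_atlas",
]


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_scheme(scheme: DiffusionScheme, prefix: str | Path) -> tuple[Path, Path]:
    """FSL convention: bvals on one row, bvecs as three rows (x, y, z)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")
    return bval_path, bvec_path


def load_scheme(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvals, bvecs)


def save_atlas(atlas: TractAtlas, affine: np.ndarray, outdir: str | Path) -> Path:
    """One NIfTI per tract plus a JSON manifest and the level/cord masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tracts": {}, "level_mask": "level_mask.nii.gz",
                      "cord_mask": "cord_mask.nii.gz"}
    for key, vol in atlas.tracts.items():
        fname = f"{key}.nii.gz"
        save_volume(vol, affine, outdir / fname)
        tract, side = key.rsplit("_", 1)
        manifest["tracts"][key] = {"file": fname, "tract": tract, "side": side}
    save_volume(atlas.level_mask.astype(float), affine, outdir / "level_mask.nii.gz")
    save_volume(atlas.cord_mask.astype(float), affine, outdir / "cord_mask.nii.gz")
    manifest_path = outdir / "atlas_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_atlas(manifest_path: str | Path) -> TractAtlas:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    tracts = {
        key: load_volume(base / entry["file"])[0]
        for key, entry in manifest["tracts"].items()
    }
    level, _ = load_volume(base / manifest["level_mask"])
    cord, _ = load_volume(base / manifest["cord_mask"])
    return TractAtlas(tracts=tracts, level_mask=level > 0.5, cord_mask=cord > 0.5)
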