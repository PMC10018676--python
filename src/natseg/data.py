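"""Reading and writing cases as NIfTI volumes plus PNG previews.

A case is a directory with four files: one volume per modality
(``bssfp.nii.gz``, ``lge.nii.gz``, ``t2.nii.gz``) and one integer label
volume (``label.nii.gz``).  Synthetic phantoms export to the same layout the
real-data reader ingests; native MyoPS label values (200/500/600/1220/2221)
are remapped to the package vocabulary on load.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import MODALITY_NAMES, PhantomCase
from .vocab import MYOPS_REMAP, NUM_CLASSES

__all__ = ["save_case", "load_case", "list_cases", "save_preview", "save_label"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing[0], spacing[1]
    return aff


def save_case(case: PhantomCase, case_dir, spacing=(1.0, 1.0)) -> Path:
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(spacing)
    for name, img in zip(MODALITY_NAMES, case.images):
        nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), aff),
                 case_dir / f"{name}.nii.gz")
    nib.save(nib.Nifti1Image(case.label.astype(np.int16), aff), case_dir / "label.nii.gz")
    return case_dir


def _remap_labels(label: np.ndarray) -> np.ndarray:
    values = np.unique(label)
    if values.max(initial=0) < NUM_CLASSES:
        return label.astype(np.int64)
    out = np.zeros_like(label, dtype=np.int64)
    for native, coded in MYOPS_REMAP.items():
        out[label == native] = coded
    return out


def load_case(case_dir):
    """Load one case directory -> (images, label, spacing).

    3-D volumes are returned as-is (callers slice to 2-D); 2-D stays 2-D.
    """
    case_dir = Path(case_dir)
    images = []
    spacing = (1.0, 1.0)
    for name in MODALITY_NAMES:
        path = case_dir / f"{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing modality file {path}")
        vol = nib.load(path)
        images.append(np.asarray(vol.dataobj, dtype=np.float32))
        zooms = vol.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
    label_path = case_dir / "label.nii.gz"
    if not label_path.exists():
        raise FileNotFoundError(f"missing label file {label_path}")
    label = _remap_labels(np.asarray(nib.load(label_path).dataobj).astype(np.int64))
    return images, label, spacing


def list_cases(root) -> list:
    root = Path(root)
    return sorted(d for d in root.iterdir()
                  if d.is_dir() and (d / "label.nii.gz").exists())


_PALETTE = np.array([
    [0, 0, 0], [200, 40, 40], [40, 80, 200], [90, 160, 90],
    [240, 200, 60], [240, 240, 240]], dtype=np.uint8)


def save_label(label: np.ndarray, path, spacing=(1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(label, dtype=np.int16), _affine(spacing)), path)


def save_preview(path, images, label=None) -> None:
    """Side-by-side PNG of the three modalities (and a colored label panel)."""
    panels = [np.clip(np.asarray(im, dtype=float), 0, 1) for im in images]
    panels = [np.repeat(p[..., None], 3, axis=-1) for p in panels]
    if label is not None:
        panels.append(_PALETTE[np.asarray(label, dtype=int)] / 255.0)
    strip = np.concatenate(panels, axis=1)
    iio.imwrite(path, (strip * 255).astype(np.uint8))
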