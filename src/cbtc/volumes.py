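"""NIfTI volume helpers: left-right flipping and integer label volumes.

Imaging inputs are assumed preprocessed and co-registered on a common grid.
The only spatial operation owned here is the mid-sagittal mirror used to pool
left- and right-lesioned patients into a single "ipsilesional = R" frame.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib
import pandas as pd

from .regions import RegionLabel, parse_region


class OrientationError(ValueError):
    pass


def lr_axis(affine: np.ndarray) -> int:
    """Voxel axis closest to the anatomical left-right direction."""
    if affine is None:
        raise OrientationError(
            "volume has no affine; set the image orientation before flipping"
        )
    codes = nib.orientations.aff2axcodes(affine)
    for axis, code in enumerate(codes):
        if code in ("L", "R"):
            return axis
    raise OrientationError(
        f"no left-right axis in orientation {codes}; set the image orientation"
    )


def flip_lr(img: nib.Nifti1Image) -> nib.Nifti1Image:
    """Mirror a 3D/4D image along the mid-sagittal plane.

    The voxel array is reversed along the axis the affine identifies as
    left-right; the affine and header are kept, so on a grid symmetric about
    the mid-sagittal plane this swaps hemispheres in place.  The operation is
    an involution: flipping twice restores the original voxel data.
    """
    axis = lr_axis(img.affine)
    data = np.flip(np.asanyarray(img.dataobj), axis=axis)
    out = nib.Nifti1Image(np.ascontiguousarray(data), img.affine, img.header)
    return out


def flip_lr_array(data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Array-level variant of :func:`flip_lr` for callers holding raw voxel data."""
    return np.flip(data, axis=lr_axis(affine))


def load_label_volume(nifti_path, sidecar_path) -> tuple[np.ndarray, dict[int, RegionLabel]]:
    """Load an integer label volume and its sidecar TSV mapping labels to regions.

    Sidecar columns: ``label name kind hemisphere parent tag`` (parent/tag may
    be empty for non-subdivision rows).
    """
    img = nib.load(str(nifti_path))
    labels = np.asanyarray(img.dataobj).astype(int)
    df = pd.read_csv(sidecar_path, sep="\t", comment="#", dtype=str).fillna("")
    mapping: dict[int, RegionLabel] = {}
    for row in df.itertuples(index=False):
        mapping[int(row.label)] = parse_region(str(row.name), str(row.hemisphere))
    present = set(np.unique(labels)) - {0}
    unknown = present - set(mapping)
    if unknown:
        raise ValueError(f"label volume contains labels {sorted(unknown)} absent from sidecar")
    return labels, mapping


def save_label_volume(labels: np.ndarray, mapping: dict[int, RegionLabel],
                      nifti_path, sidecar_path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(nifti_path))
    rows = []
    for label, region in sorted(mapping.items()):
        rows.append({
            "label": label, "name": region.name, "kind": region.kind,
            "hemisphere": region.hemisphere,
            "parent": region.parent or "", "tag": region.tag or "",
        })
    pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)
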