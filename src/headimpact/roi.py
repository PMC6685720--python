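"""Atlas-driven ROI construction and mean-FA extraction.

Volumes and masks live on a shared voxel grid in a common standard space
(e.g. MNI152); registration and diffusion preprocessing happen upstream.
The ROI of interest here is the midbrain segment of the corticospinal
tract, built by intersecting a midbrain mask with an atlas tract mask and
splitting the result by hemisphere along the world x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

AFFINE_ATOL = 1e-4


@dataclass
class FaVolume:
    """Scalar fractional-anisotropy field on a voxel grid.

    FA is dimensionless in [0, 1]; the affine maps voxel indices to world
    (mm) coordinates, with left-right along world x.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = "MNI152"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("FA volume must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FA volume contains non-finite values")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("FA values must lie in [0, 1]")

    @classmethod
    def from_nifti(cls, path, space: str = "MNI152") -> "FaVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, space)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class RoiMask:
    """Binary region-of-interest mask on a voxel grid."""

    data: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1; threshold probabilistic "
                             "atlases first (see binarize)")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_nifti(cls, path, label: str = "", threshold: float | None = None) -> "RoiMask":
        """Load a mask; non-binary (probabilistic) images require ``threshold``."""
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if threshold is not None:
            arr = arr >= threshold
        return cls(arr, img.affine, label or str(path))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


def binarize(volume: np.ndarray, affine: np.ndarray, threshold: float = 0.5,
             label: str = "") -> RoiMask:
    """Threshold a probabilistic atlas image into a binary mask (>= threshold)."""
    return RoiMask(np.asarray(volume, dtype=float) >= threshold, affine, label)


def _check_same_grid(a, b):
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid shapes differ: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.affine, b.affine, atol=AFFINE_ATOL):
        raise ValueError("grid-to-world transforms differ beyond tolerance")


def intersect_masks(a: RoiMask, b: RoiMask) -> RoiMask:
    """Voxelwise AND of two masks on the same grid (mask multiplication)."""
    _check_same_grid(a, b)
    label = f"{a.label} & {b.label}".strip(" &")
    return RoiMask(a.data & b.data, a.affine, label)


def voxel_world_coordinates(mask: RoiMask) -> np.ndarray:
    """World (mm) coordinates of every voxel center, shaped like the grid + (3,)."""
    shape = mask.data.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ mask.affine.T
    return world[..., :3]


def hemisphere_split(mask: RoiMask, midline_world_x: float = 0.0):
    """Split a mask into (left, right) hemisphere masks along world x.

    Voxels whose center has world x < midline go left, x > midline right;
    voxels exactly on the midline plane are excluded from both (avoiding
    double counting). Returns ``(left, right, n_midline)``.
    """
    A = mask.affine
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("degenerate grid-to-world transform")
    x = voxel_world_coordinates(mask)[..., 0]
    left = RoiMask(mask.data & (x < midline_world_x), A, f"{mask.label} L")
    right = RoiMask(mask.data & (x > midline_world_x), A, f"{mask.label} R")
    n_mid = int((mask.data & (x == midline_world_x)).sum())
    return left, right, n_mid


def mean_in_mask(volume: FaVolume, mask: RoiMask) -> float:
    """Arithmetic mean of the FA values at the mask voxels.

    An empty mask is an error: it signals an ROI or registration failure
    upstream, not a zero measurement.
    """
    _check_same_grid(volume, mask)
    if mask.n_voxels == 0:
        raise ValueError("mask is empty; cannot average FA over zero voxels")
    return float(volume.data[mask.data].mean())


def delta_fa(pre, post):
    """FA change, postseason minus preseason; negative = integrity loss."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre < 0) or np.any(pre > 1) or np.any(post < 0) or np.any(post > 1):
        raise ValueError("FA values must lie in [0, 1]")
    out = post - pre
    return float(out) if out.ndim == 0 else out


def extract_roi_table(volumes: dict, masks: dict, midline_world_x: float = 0.0):
    """Mean FA per participant, hemisphere and timepoint.

    ``volumes`` maps ``(participant, timepoint) -> FaVolume``; ``masks``
    maps a label to an already-intersected ROI mask (one shared grid).
    Returns a tidy table: participant, timepoint, roi, hemisphere, mean_fa,
    n_voxels.
    """
    import pandas as pd

    rows = []
    for label, mask in masks.items():
        left, right, _ = hemisphere_split(mask, midline_world_x)
        for (participant, timepoint), vol in volumes.items():
            for hemi, m in (("left", left), ("right", right)):
                rows.append({
                    "participant": participant, "timepoint": timepoint,
                    "roi": label, "hemisphere": hemi,
                    "mean_fa": mean_in_mask(vol, m), "n_voxels": m.n_voxels,
                })
    return pd.DataFrame(rows)
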