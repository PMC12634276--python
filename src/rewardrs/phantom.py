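"""Digital phantom brains with labeled reward-circuit ROIs.

The phantom plays the role of the study's atlas-derived reward mask:
a small 3-D voxel grid carrying disjoint labeled regions named for the
reward and cognitive-reward-control areas (NAcc, VTA, basolateral
amygdala, mOFC, dlPFC, vlPFC, SMA). Volumes are already "aligned": no
registration step exists downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: ROI roles present in the reward mask.
ROI_ROLES = ("NAcc", "VTA", "basolateral_amygdala", "mOFC",
             "dlPFC", "vlPFC", "SMA")

#: 2 mm isotropic voxels, axis-aligned.
DEFAULT_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


@dataclass
class PhantomSpec:
    """Grid shape plus the voxel set of every labeled ROI."""

    grid_shape: tuple[int, int, int]
    roi_voxels: dict[str, np.ndarray]  # role -> (n, 3) int array of voxel triples

    def __post_init__(self) -> None:
        self.roi_voxels = {k: np.atleast_2d(np.asarray(v, dtype=int))
                           for k, v in self.roi_voxels.items()}


def _box(corner: tuple[int, int, int], size: int) -> np.ndarray:
    """All voxel triples of a cubic box."""
    r = [np.arange(c, c + size) for c in corner]
    return np.stack(np.meshgrid(*r, indexing="ij"), -1).reshape(-1, 3)


def default_phantom_spec(grid_shape: tuple[int, int, int] = (24, 24, 24),
                         roi_size: int = 5) -> PhantomSpec:
    """Seven disjoint cubic ROIs spread over the grid.

    Cubes of ``roi_size`` voxels per side are placed with a margin from
    the grid border and from each other, so interior searchlight spheres
    of 2-voxel radius fit fully inside each ROI when ``roi_size >= 5``.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 3 * roi_size:
        raise ValueError("grid too small to host the default ROI layout")
    # Lay cubes on a coarse 2x2x2 lattice of anchor corners.
    anchors = []
    for ix in (nx // 6, 4 * nx // 6):
        for iy in (ny // 6, 4 * ny // 6):
            for iz in (nz // 6, 4 * nz // 6):
                anchors.append((ix, iy, iz))
    rois = {role: _box(anchors[i], roi_size) for i, role in enumerate(ROI_ROLES)}
    return PhantomSpec(grid_shape, rois)


@dataclass
class Phantom:
    """Integer label volume plus the role -> label legend."""

    labels: np.ndarray            # int volume, 0 = background
    legend: dict[str, int]        # role -> positive label
    affine: np.ndarray = field(default_factory=lambda: DEFAULT_AFFINE.copy())

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, role: str) -> np.ndarray:
        return self.labels == self.legend[role]

    def roi_indices(self, role: str) -> np.ndarray:
        """(n, 3) voxel triples of one ROI, in C order."""
        return np.argwhere(self.roi_mask(role))

    def union_indices(self) -> np.ndarray:
        return np.argwhere(self.union_mask)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a PhantomSpec into a labeled volume.

    Raises on out-of-grid voxels or overlapping ROI definitions.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    legend: dict[str, int] = {}
    shape = np.asarray(spec.grid_shape)
    for lab, (role, vox) in enumerate(sorted(spec.roi_voxels.items()), start=1):
        if vox.size == 0:
            raise ValueError(f"ROI {role!r} has no voxels")
        if (vox < 0).any() or (vox >= shape).any():
            raise ValueError(f"ROI {role!r} exceeds the grid {spec.grid_shape}")
        idx = tuple(vox.T)
        if (labels[idx] != 0).any():
            clash = [r for r, l in legend.items()
                     if np.isin(labels[idx], l).any()]
            raise ValueError(f"ROI {role!r} overlaps {clash}")
        labels[idx] = lab
        legend[role] = lab
    return Phantom(labels, legend)


def save_phantom(phantom: Phantom, path) -> None:
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), phantom.affine)
    img.header["descrip"] = b"rewardrs phantom labels"
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    """Boolean mask from a NIfTI label or binary volume."""
    return np.asarray(nib.load(str(path)).dataobj) > 0
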