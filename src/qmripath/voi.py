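"""Volume-of-interest handling: rigid mask propagation between grids and
clean value extraction from parametric maps.

A lesion contour drawn on the DCE parameter maps is carried over to the
DKI grid by a rigid world-space transform with nearest-neighbour
resampling (binary labels must stay binary).  Extraction drops
not-a-number voxels — invalid fits — and reports how many were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ParametricMap:
    """A 3D scalar field with its grid geometry (NIfTI-style affine)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or self.affine.shape != (4, 4):
            raise ValueError("ParametricMap needs a 3D field and a 4x4 affine")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class VOIMask:
    """Boolean lesion mask with its grid geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or self.affine.shape != (4, 4):
            raise ValueError("VOIMask needs a 3D field and a 4x4 affine")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def propagate_mask(mask: VOIMask, target_affine, target_shape,
                   transform=None) -> VOIMask:
    """Resample ``mask`` onto a target grid through a rigid transform.

    ``transform`` is a 4x4 matrix mapping source-world to target-world
    coordinates (identity by default, i.e. header geometry only).  Each
    target voxel centre is pulled back into the source grid and looked up
    with nearest-neighbour interpolation.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    transform = np.eye(4) if transform is None else np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform is not invertible")

    # target voxel -> target world -> source world -> source voxel
    m = np.linalg.inv(mask.affine) @ np.linalg.inv(transform) @ target_affine
    idx = np.indices(target_shape).reshape(3, -1)
    src = m[:3, :3] @ idx + m[:3, 3:4]
    src = np.round(src).astype(int)
    inside = np.all((src >= 0) & (src < np.asarray(mask.data.shape)[:, None]), axis=0)
    out = np.zeros(np.prod(target_shape), dtype=bool)
    sj = src[:, inside]
    out[inside] = mask.data[sj[0], sj[1], sj[2]]
    out = out.reshape(target_shape)
    if not out.any():
        raise ValueError(
            "propagated mask is empty on the target grid; the contour "
            "likely needs manual adjustment for the geometry in use"
        )
    return VOIMask(data=out, affine=target_affine)


def extract_values(pmap, mask) -> tuple[np.ndarray, int]:
    """Masked voxel values with non-finite entries removed.

    Accepts :class:`ParametricMap`/`VOIMask` or bare arrays.  Returns
    ``(values, n_excluded)``; raises if every masked value is invalid.
    """
    data = pmap.data if isinstance(pmap, ParametricMap) else np.asarray(pmap, dtype=float)
    m = mask.data if isinstance(mask, VOIMask) else np.asarray(mask).astype(bool)
    if data.shape != m.shape:
        raise ValueError("map and mask shapes differ")
    vals = data[m]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("no valid voxels inside the VOI")
    return vals, n_excluded
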