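"""NIfTI I/O and masking.

Converts between 4-D BOLD volumes on disk and the time-by-voxel matrices
every algorithm in this package consumes.  Voxel ordering is a pure function
of the mask: ascending linear index in C (array-native) order, 0-based.
Data are stored float32 on disk and promoted to float64 in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["BoldSeries", "load_masked_series", "save_component_maps", "mask_to_indices"]


@dataclass
class BoldSeries:
    """One subject's masked BOLD data.

    Attributes
    ----------
    data : (T, V) float64 array
        Column j is the time series of the j-th in-mask voxel.
    tr_seconds : float
        Repetition time (sampling interval).
    mask_voxel_indices : (V,) int array
        Linear indices (C order) of in-mask voxels in the 3-D grid.
    grid_shape : tuple of 3 ints
    subject_id : str
    """

    data: np.ndarray
    tr_seconds: float
    mask_voxel_indices: np.ndarray
    grid_shape: tuple
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask_voxel_indices = np.asarray(self.mask_voxel_indices, dtype=np.intp)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T, V), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError(f"need at least 2 time points, got T={self.data.shape[0]}")
        if self.data.shape[1] != self.mask_voxel_indices.size:
            raise ValueError(
                f"V={self.data.shape[1]} columns but mask has "
                f"{self.mask_voxel_indices.size} voxels"
            )
        if not np.all(np.isfinite(self.data)):
            n_bad = int(np.sum(~np.isfinite(self.data).all(axis=0)))
            raise ValueError(f"non-finite values in {n_bad} voxel time series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def mask_to_indices(mask: np.ndarray) -> np.ndarray:
    """Linear indices of nonzero mask voxels, ascending C order."""
    return np.flatnonzero(np.asarray(mask).ravel(order="C") != 0)


def load_masked_series(
    volume_path,
    mask_path,
    subject_id: str = "",
    zscore: bool = True,
) -> BoldSeries:
    """Load a 4-D NIfTI volume, apply a 3-D mask, return a BoldSeries.

    Each voxel time series is variance-normalized (z-scored over time) when
    ``zscore`` is True — a standard precondition for ICA.  Pass False to get
    the raw stored intensities (e.g. for round-trip checks).

    Raises
    ------
    ValueError
        On grid-shape mismatch, an empty mask, or non-finite voxels.
    """
    img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asanyarray(img.dataobj).astype(np.float64)
    mask = np.asanyarray(mask_img.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"expected 4-D volume, got shape {vol.shape}")
    if mask.ndim != 3:
        raise ValueError(f"expected 3-D mask, got shape {mask.shape}")
    if vol.shape[:3] != mask.shape:
        raise ValueError(f"volume grid {vol.shape[:3]} != mask grid {mask.shape}")
    idx = mask_to_indices(mask)
    if idx.size == 0:
        raise ValueError("mask is empty (no nonzero voxels)")
    T = vol.shape[3]
    flat = vol.reshape(-1, T, order="C")  # (voxel, time)
    data = flat[idx].T.copy()  # (T, V)
    finite_cols = np.isfinite(data).all(axis=0)
    if not finite_cols.all():
        raise ValueError(
            f"{int(np.sum(~finite_cols))} in-mask voxels contain non-finite values"
        )
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if zscore:
        mu = data.mean(axis=0)
        sd = data.std(axis=0)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    return BoldSeries(
        data=data,
        tr_seconds=tr,
        mask_voxel_indices=idx,
        grid_shape=mask.shape,
        subject_id=subject_id,
    )


def save_bold_series(
    data: np.ndarray,
    mask_voxel_indices: np.ndarray,
    grid_shape,
    path,
    tr_seconds: float = 2.0,
) -> None:
    """Write a (T, V) matrix back into a 4-D NIfTI volume (float32 on disk)."""
    data = np.asarray(data, dtype=np.float64)
    T, V = data.shape
    if V != len(mask_voxel_indices):
        raise ValueError(f"{V} columns but mask has {len(mask_voxel_indices)} voxels")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    vol = np.zeros((int(np.prod(grid_shape)), T), dtype=np.float32)
    vol[np.asarray(mask_voxel_indices, dtype=np.intp)] = data.T.astype(np.float32)
    vol4d = vol.reshape(tuple(grid_shape) + (T,), order="C")
    img = nib.Nifti1Image(vol4d, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr_seconds)))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def save_component_maps(maps: np.ndarray, mask_voxel_indices, grid_shape, path) -> None:
    """Write an (N, V) stack of component maps as a 4-D NIfTI file.

    Out-of-mask voxels are written as 0; in-mask values round-trip through
    float32.  A single map (N=1) yields a 4-D file with a singleton last axis,
    readable by standard viewers.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
    N, V = maps.shape
    idx = np.asarray(mask_voxel_indices, dtype=np.intp)
    if V != idx.size:
        raise ValueError(f"maps have {V} columns but mask has {idx.size} voxels")
    if not np.all(np.isfinite(maps)):
        raise ValueError("maps contain non-finite values")
    vol = np.zeros((int(np.prod(grid_shape)), N), dtype=np.float32)
    vol[idx] = maps.T.astype(np.float32)
    img = nib.Nifti1Image(vol.reshape(tuple(grid_shape) + (N,), order="C"), np.eye(4))
    nib.save(img, str(path))


def load_component_maps(path, mask_voxel_indices, grid_shape=None) -> np.ndarray:
    """Inverse of :func:`save_component_maps`: returns the (N, V) matrix."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj).astype(np.float64)
    if vol.ndim == 3:
        vol = vol[..., None]
    flat = vol.reshape(-1, vol.shape[3], order="C")
    return flat[np.asarray(mask_voxel_indices, dtype=np.intp)].T.copy()
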