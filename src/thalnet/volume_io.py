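"""NIfTI volume, mask and label-volume handling.

All volumes live on a common already-registered grid (MNI space in the real
study; an arbitrary grid for synthetic cohorts). Voxel indexing is 0-based
throughout; world (scanner/MNI) coordinates are only ever obtained through
the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

FrameMeaning = Literal["time", "stacked_maps"]


@dataclass
class Volume4D:
    """A 4D image: 3D spatial grid x frames.

    Frames are timepoints (``frame_axis_meaning="time"``) or stacked
    statistical maps (``"stacked_maps"``), depending on the pipeline stage.
    3D images are represented with a single frame.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_axis_meaning: FrameMeaning = "time"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        if min(self.data.shape[:3]) < 1 or self.data.shape[3] < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class Mask:
    """A binary 3D mask on the same grid as the volumes it is applied to."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.n_voxels < 1:
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape

    def indices(self) -> np.ndarray:
        """Coordinates of true voxels, sorted ascending by (x, y, z) index.

        The ordering is the contract used to align stacked connectivity maps
        with thalamic voxels across subjects.
        """
        idx = np.argwhere(self.data)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        return idx[order]


@dataclass
class LabelVolume:
    """Integer-labelled 3D volume with a label table (e.g. thalamic nuclei)."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.int32)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"label values missing from table: {sorted(missing)}")


def read_volume(path: str | Path, frame_axis_meaning: FrameMeaning = "time") -> Volume4D:
    """Load a NIfTI-1 file as a :class:`Volume4D` (3D files get one frame).

    Raises if the file is missing, not NIfTI, or contains non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    n_bad = int((~np.isfinite(data)).sum())
    if n_bad:
        raise ValueError(f"{path} contains {n_bad} non-finite voxels")
    return Volume4D(data=data, affine=img.affine, frame_axis_meaning=frame_axis_meaning)


def write_volume(vol: Volume4D, path: str | Path) -> None:
    """Write a volume as 32-bit float NIfTI; single-frame volumes as 3D."""
    data = vol.data.astype(np.float32)
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask:
    vol = read_volume(path)
    return Mask(data=vol.data[..., 0] > 0.5, affine=vol.affine)


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_label_volume(path: str | Path, table_path: str | Path) -> LabelVolume:
    """Load an integer label NIfTI plus its 2-column TSV table (value, name)."""
    vol = read_volume(path)
    table = pd.read_csv(table_path, sep="\t", header=None, names=["value", "name"])
    label_table = dict(zip(table["value"].astype(int), table["name"].astype(str)))
    return LabelVolume(data=np.round(vol.data[..., 0]), affine=vol.affine,
                       label_table=label_table)


def resample_mask(mask: Mask, target_shape: Sequence[int], target_affine: np.ndarray,
                  method: Literal["nearest"] = "nearest") -> Mask:
    """Resample a mask onto a target grid by nearest-neighbour assignment.

    Each target voxel centre is mapped through the composed affines into the
    source grid and takes the value of the nearest source voxel; centres that
    fall outside the source grid are false. Identity resampling (same grid)
    returns the mask unchanged.
    """
    if method != "nearest":
        raise ValueError("only nearest-neighbour resampling is supported")
    target_affine = np.asarray(target_affine, dtype=np.float64)
    target_shape = tuple(int(s) for s in target_shape)
    if target_shape == mask.shape3d and np.allclose(target_affine, mask.affine):
        return Mask(data=mask.data.copy(), affine=mask.affine.copy())
    if abs(np.linalg.det(mask.affine[:3, :3])) < 1e-12:
        raise ValueError("source affine is not invertible")
    # composed transform: target ijk -> world -> source ijk
    composed = np.linalg.inv(mask.affine) @ target_affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target_shape), indexing="ij")
    tgt = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    src = composed @ tgt
    src_idx = np.round(src[:3]).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(mask.shape3d)[:, None]), axis=0)
    out = np.zeros(target_shape, dtype=bool)
    vals = np.zeros(ii.size, dtype=bool)
    vals[inside] = mask.data[src_idx[0, inside], src_idx[1, inside], src_idx[2, inside]]
    out.ravel()[:] = vals
    if not out.any():
        raise ValueError("resampled mask is empty: no overlap with the target grid")
    return Mask(data=out, affine=target_affine)


def lookup_labels(coords: Sequence[Sequence[int]], labels: LabelVolume
                  ) -> list[tuple[str, int]]:
    """Tally the region names at the given voxel coordinates.

    Returns (name, count) pairs sorted by count descending (name ascending on
    ties); voxels with label value 0 are reported as ``"unlabeled"``.
    """
    counts: dict[str, int] = {}
    shape = labels.data.shape
    for c in coords:
        i, j, k = (int(v) for v in c)
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            raise IndexError(f"coordinate {(i, j, k)} outside grid {shape}")
        val = int(labels.data[i, j, k])
        if val == 0:
            name = "unlabeled"
        elif val in labels.label_table:
            name = labels.label_table[val]
        else:
            raise KeyError(f"label value {val} absent from label table")
        counts[name] = counts.get(name, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
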