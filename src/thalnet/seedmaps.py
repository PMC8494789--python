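"""Thalamic-voxel seed connectivity maps and the concatenated ICA input.

For each thalamic voxel, the Pearson correlation of its time series with
every brain voxel is Fisher z-transformed into a whole-brain map; a
subject's maps are stacked on the frame axis (one frame per thalamic voxel,
in ascending (x, y, z) voxel order), and subjects' stacks are concatenated
subject-major into the group dataset decomposed by spatial ICA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import Mask, Volume4D, read_volume, write_volume

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh so the
#: seed's self-correlation maps to a large finite z rather than infinity
R_CLIP_EPS = 1e-7


@dataclass
class ConnectivityMapSet:
    """Per-subject stack of Fisher-z seed maps, one frame per thalamic voxel."""

    subject_id: str
    maps: Volume4D
    thal_voxel_index: np.ndarray  # (n_thal, 3) aligned with frames

    def __post_init__(self) -> None:
        if self.maps.n_frames != len(self.thal_voxel_index):
            raise ValueError("frame count must equal number of thalamic voxels")


@dataclass
class GroupStack:
    """Subject-major concatenation of connectivity map sets."""

    maps: Volume4D
    subject_ids: list[str]
    subject_boundaries: list[int]  # start frame of each subject's block
    thal_voxel_index: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_maps_per_subject(self) -> int:
        return len(self.thal_voxel_index)


def thalamic_seed_maps(vol: Volume4D, thal: Mask, brain: Mask,
                       subject_id: str = "") -> ConnectivityMapSet:
    """Correlate every thalamic voxel with every brain voxel.

    Returns Fisher z maps (``atanh`` of the clipped Pearson r); voxels
    outside the brain mask are 0. Zero-variance series (possible at masked
    edges) contribute r = 0 with a warning rather than an error.
    """
    if vol.frame_axis_meaning != "time":
        raise ValueError("seed maps require a time-axis volume")
    if thal.shape3d != vol.shape3d or brain.shape3d != vol.shape3d:
        raise ValueError("masks must be on the volume grid")
    T = vol.n_frames
    thal_idx = thal.indices()
    brain_flat = brain.data.ravel()
    X = vol.data.reshape(-1, T)[brain_flat]            # brain voxels x time
    S = vol.data[thal_idx[:, 0], thal_idx[:, 1], thal_idx[:, 2]]  # seeds x time

    def _standardize(M: np.ndarray, what: str) -> np.ndarray:
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = Mc.std(axis=1)
        n_zero = int((sd == 0).sum())
        if n_zero:
            warnings.warn(f"{n_zero} zero-variance {what} series; their r set to 0",
                          stacklevel=3)
        sd[sd == 0] = np.inf
        return Mc / sd[:, None]

    Sz = _standardize(S, "seed")
    Xz = _standardize(X, "target")
    r = (Sz @ Xz.T) / T                                 # seeds x brain voxels
    np.clip(r, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS, out=r)
    z = np.arctanh(r)

    out = np.zeros(vol.shape3d + (len(thal_idx),))
    out.reshape(-1, len(thal_idx))[brain_flat] = z.T
    maps = Volume4D(data=out, affine=vol.affine, frame_axis_meaning="stacked_maps")
    return ConnectivityMapSet(subject_id=subject_id, maps=maps,
                              thal_voxel_index=thal_idx)


def concatenate_group(mapsets: list[ConnectivityMapSet]) -> GroupStack:
    """Concatenate subjects' map stacks on the frame axis, subject-major."""
    if not mapsets:
        raise ValueError("no map sets given")
    first = mapsets[0]
    for ms in mapsets[1:]:
        if ms.maps.shape3d != first.maps.shape3d:
            raise ValueError("map sets are on different grids")
        if not np.array_equal(ms.thal_voxel_index, first.thal_voxel_index):
            raise ValueError("map sets use different thalamic voxel orderings")
    data = np.concatenate([ms.maps.data for ms in mapsets], axis=3)
    n = first.maps.n_frames
    boundaries = [i * n for i in range(len(mapsets))]
    return GroupStack(
        maps=Volume4D(data=data, affine=first.maps.affine,
                      frame_axis_meaning="stacked_maps"),
        subject_ids=[ms.subject_id for ms in mapsets],
        subject_boundaries=boundaries,
        thal_voxel_index=first.thal_voxel_index.copy())


def save_group_stack(stack: GroupStack, prefix: str | Path) -> None:
    """Persist as NIfTI + JSON sidecar (subject boundaries, voxel ordering)."""
    prefix = Path(prefix)
    write_volume(stack.maps, prefix.with_suffix(".nii.gz"))
    sidecar = {
        "subject_ids": stack.subject_ids,
        "subject_boundaries": stack.subject_boundaries,
        "thal_voxel_index": stack.thal_voxel_index.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_group_stack(prefix: str | Path) -> GroupStack:
    prefix = Path(prefix)
    maps = read_volume(prefix.with_suffix(".nii.gz"), frame_axis_meaning="stacked_maps")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return GroupStack(maps=maps, subject_ids=sidecar["subject_ids"],
                      subject_boundaries=sidecar["subject_boundaries"],
                      thal_voxel_index=np.asarray(sidecar["thal_voxel_index"]))
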