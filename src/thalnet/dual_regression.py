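"""Dual regression: subject-specific timecourses and thalamic subdivision maps.

Stage 1 regresses each timepoint's brain image on the group IC spatial maps
(plus intercept), giving one timecourse per component; stage 2 regresses
each voxel's series on all timecourses jointly (plus intercept), giving one
beta map per component. The stage-2 stack restricted to the thalamus is the
subject's set of functional thalamic subdivisions.

Stage-1 timecourses are variance-normalized before stage 2 (the usual
dual-regression "des-norm" convention) so stage-2 betas are comparable
across subjects — required because they are compared between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial_ica import ICADecomposition
from .volume_io import Mask, Volume4D

#: condition-number ceiling on the stage-2 timecourse design
MAX_CONDITION = 1e8


@dataclass
class SubjectTimecourses:
    """Stage-1 output: (timepoints x components) weights."""

    tc: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.tc = np.asarray(self.tc, dtype=np.float64)
        if self.tc.ndim != 2:
            raise ValueError("timecourses must be 2D (timepoints x components)")
        if not np.isfinite(self.tc).all():
            raise ValueError("timecourses contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.tc.shape[1]

    def variance_normalized(self) -> "SubjectTimecourses":
        sd = self.tc.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return SubjectTimecourses(tc=self.tc / sd, normalized=True)


@dataclass
class SubdivisionMaps:
    """Stage-2 output: per-component beta maps, thalamus-restricted stack."""

    subject_id: str
    thal_betas: np.ndarray   # (K, x, y, z), zero outside thalamus
    thalamus: Mask
    brain_betas: np.ndarray | None = None  # (K, x, y, z) whole-brain, optional

    def __post_init__(self) -> None:
        if not np.isfinite(self.thal_betas).all():
            raise ValueError("subdivision betas contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.thal_betas.shape[0]

    def thal_vector(self, k: int) -> np.ndarray:
        """Component-k betas at the thalamus voxels, in mask index order."""
        idx = self.thalamus.indices()
        return self.thal_betas[k][idx[:, 0], idx[:, 1], idx[:, 2]]


def stage1_timecourses(bold: Volume4D, dec: ICADecomposition, brain: Mask
                       ) -> SubjectTimecourses:
    """Spatial regression: IC maps as regressors, one fit per timepoint."""
    if bold.shape3d != brain.shape3d:
        raise ValueError("volume and brain mask are on different grids")
    brain_flat = brain.data.ravel()
    K = dec.n_components
    design = np.column_stack(
        [np.ones(int(brain_flat.sum()))]
        + [dec.maps[k].ravel()[brain_flat] for k in range(K)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("IC spatial design is rank-deficient")
    Y = bold.data.reshape(-1, bold.n_frames)[brain_flat]  # voxels x time
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)     # (1+K) x time
    return SubjectTimecourses(tc=beta[1:].T)


def stage2_subdivisions(bold: Volume4D, tc: SubjectTimecourses, thal: Mask,
                        brain: Mask | None = None, subject_id: str = "",
                        keep_brain: bool = False) -> SubdivisionMaps:
    """Temporal regression: all timecourses jointly per voxel.

    The joint (multiple-regression) fit matters: with correlated
    timecourses, the joint betas differ from per-component marginal ones.
    """
    T = bold.n_frames
    if tc.tc.shape[0] != T:
        raise ValueError(
            f"timecourses have {tc.tc.shape[0]} rows, volume has {T} frames")
    tcs = tc.variance_normalized().tc if not tc.normalized else tc.tc
    X = np.column_stack([np.ones(T), tcs])
    cond = np.linalg.cond(X)
    if cond > MAX_CONDITION:
        C = np.corrcoef(tcs, rowvar=False)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.abs(C).argmax(), C.shape)
        raise ValueError(
            f"timecourse design is near-singular (condition {cond:.2e}); "
            f"worst pair: components {i} and {j} (r={C[i, j]:.4f})")
    fit_mask = (brain.data if brain is not None else
                np.ones(bold.shape3d, dtype=bool)).ravel()
    Y = bold.data.reshape(-1, T)[fit_mask].T              # time x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)          # (1+K) x voxels
    K = tc.n_components
    full = np.zeros((K,) + bold.shape3d)
    for k in range(K):
        m = np.zeros(fit_mask.size)
        m[fit_mask] = beta[1 + k]
        full[k] = m.reshape(bold.shape3d)
    thal_betas = np.where(thal.data[None], full, 0.0)
    return SubdivisionMaps(subject_id=subject_id, thal_betas=thal_betas,
                           thalamus=thal,
                           brain_betas=full if keep_brain else None)


def dual_regress(bold: Volume4D, dec: ICADecomposition, brain: Mask, thal: Mask,
                 subject_id: str = "", keep_brain: bool = False
                 ) -> tuple[SubjectTimecourses, SubdivisionMaps]:
    """Both stages for one subject.

    Stage 1 is fit on cortex (brain minus thalamus): the component maps are
    cortical, and excluding the thalamus keeps its signal — the very thing
    stage 2 estimates — from leaking into the timecourses.
    """
    cortex_data = brain.data & ~thal.data
    fit_mask = (Mask(data=cortex_data, affine=brain.affine)
                if cortex_data.any() else brain)
    tc = stage1_timecourses(bold, dec, fit_mask)
    sub = stage2_subdivisions(bold, tc, thal, brain=brain, subject_id=subject_id,
                              keep_brain=keep_brain)
    return tc, sub
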