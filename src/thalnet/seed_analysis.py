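"""Seed-based follow-up: thalamic seeds from subdivision maps, seed-to-brain
connectivity per subject, and group comparison.

For each component, the thalamic voxels whose subdivision betas survive a
one-sample sign-flip permutation test (TFCE, corrected p < 0.05, all
subjects pooled) form the seed. Each subject's mean seed series is then
regressed against every brain voxel, and the resulting seed-beta maps are
compared between groups with covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dual_regression import SubdivisionMaps
from .inference import PermutationResult, GroupDesign, one_sample_design, permutation_test
from .volume_io import Mask, Volume4D


@dataclass
class SeedDefinition:
    """Binary thalamic seed for one component, with its provenance."""

    component: int
    mask: Mask
    provenance: dict

    def __post_init__(self) -> None:
        if self.mask.n_voxels < 1:
            raise ValueError("seed is empty")


class EmptySeedError(ValueError):
    """One-sample test found no significant thalamic voxels."""


def extract_seed(subdivisions: list[SubdivisionMaps], component: int, *,
                 n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
                 ) -> SeedDefinition:
    """Seed = thalamic voxels with one-sample corrected p < alpha.

    Pools all subjects' component betas, runs a sign-flip permutation test
    with TFCE restricted to the thalamus mask.
    """
    if len(subdivisions) < 5:
        raise ValueError("need at least 5 subjects to extract a seed")
    thal = subdivisions[0].thalamus
    stack = np.stack([s.thal_betas[component] for s in subdivisions], axis=3)
    design = one_sample_design(len(subdivisions))
    res = permutation_test(stack, design, thal, enhancement="tfce",
                           n_perm=n_perm, seed=seed, alpha=alpha)
    sig = (res.corrected_p < alpha) & thal.data
    if not sig.any():
        raise EmptySeedError(
            f"no thalamic voxel significant at corrected p < {alpha} for "
            f"component {component}; consider relaxing the threshold")
    return SeedDefinition(
        component=component, mask=Mask(data=sig, affine=thal.affine),
        provenance={"test": "one-sample sign-flip", "enhancement": "tfce",
                    "alpha": alpha, "n_perm": res.n_permutations,
                    "n_subjects": len(subdivisions), "seed": seed})


def seed_connectivity_map(bold: Volume4D, seed_def: SeedDefinition, brain: Mask
                          ) -> np.ndarray:
    """Per-voxel GLM beta of the voxel series on the mean seed series.

    Design is [intercept | seed mean]; returns the 3D seed-regressor beta
    map (0 outside the brain mask).
    """
    if bold.shape3d != brain.shape3d:
        raise ValueError("volume and mask grids differ")
    idx = seed_def.mask.indices()
    s = bold.data[idx[:, 0], idx[:, 1], idx[:, 2]].mean(axis=0)
    if s.std() == 0:
        raise ValueError("seed mean series has zero variance")
    X = np.column_stack([np.ones(bold.n_frames), s])
    flat = brain.data.ravel()
    Y = bold.data.reshape(-1, bold.n_frames)[flat].T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = np.zeros(np.prod(bold.shape3d))
    out[flat] = beta[1]
    return out.reshape(bold.shape3d)


def compare_seed_maps(maps: np.ndarray, design: GroupDesign, brain: Mask, *,
                      n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
                      ) -> PermutationResult:
    """Group comparison of subjects' seed-beta maps (TFCE permutation test).

    ``maps`` is an (x, y, z, subjects) stack aligned with the design rows.
    """
    return permutation_test(maps, design, brain, enhancement="tfce",
                            n_perm=n_perm, seed=seed, alpha=alpha)
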