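"""Group spatial ICA of the concatenated connectivity stack.

The stack's frames (one Fisher-z map per thalamic voxel per subject) are the
observations and brain voxels the variables: principal-component reduction
to ``n_components`` followed by a fixed-point symmetric ICA rotation with a
tanh (logcosh) contrast yields spatially independent component maps — the
thalamus-related network ROIs — plus the mixing weights of each frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .seedmaps import GroupStack
from .volume_io import Mask, Volume4D, write_volume

ICA_TOL = 1e-6
ICA_MAX_ITER = 1000
ICA_MAX_RESTARTS = 5


@dataclass
class ICADecomposition:
    """Spatial ICA result: component maps, mixing weights, diagnostics."""

    maps: np.ndarray        # (K, x, y, z) unit-variance spatial maps, 0 off-brain
    zmaps: np.ndarray       # (K, x, y, z) maps scaled by robust noise SD
    mixing: np.ndarray      # (frames, K)
    brain: Mask
    seed: int
    n_iter: int
    retained_variance: float  # fraction of stack variance kept by the reduction
    restarts_used: int = 0

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, k: int, z: bool = True) -> Volume4D:
        source = self.zmaps if z else self.maps
        return Volume4D(data=source[k][..., None], affine=self.brain.affine,
                        frame_axis_meaning="stacked_maps")


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad) if mad > 0 else float(x.std())


def fit_spatial_ica(stack: GroupStack, brain: Mask, n_components: int = 20,
                    seed: int = 0) -> ICADecomposition:
    """Decompose the group stack into spatially independent components.

    Each frame is variance-normalized within the brain mask (equalizing
    subjects' global correlation levels), reduced to ``n_components``
    principal components and rotated by fixed-point symmetric ICA
    (tanh contrast, tol 1e-6, max 1000 iterations; up to 5 seeded restarts
    on non-convergence). Maps are fixed to unit variance over brain voxels
    with the largest-magnitude voxel positive; z-maps additionally scale by
    a per-map robust (MAD-based) noise SD.
    """
    n_frames = stack.maps.n_frames
    brain_flat = brain.data.ravel()
    n_brain = int(brain_flat.sum())
    if not (0 < n_components < min(n_frames, n_brain)):
        raise ValueError(
            f"n_components={n_components} must be < min(frames={n_frames}, "
            f"brain voxels={n_brain})")
    Y = stack.maps.data.reshape(-1, n_frames)[brain_flat].T  # frames x voxels
    sd = Y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Y = Y / sd

    X = Y.T  # voxels as samples, frames as features (spatial independence)
    last_exc: Exception | None = None
    for attempt in range(ICA_MAX_RESTARTS):
        ica = FastICA(n_components=n_components, fun="logcosh", tol=ICA_TOL,
                      max_iter=ICA_MAX_ITER, whiten="unit-variance",
                      random_state=seed + attempt)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(X)  # voxels x K
            except ConvergenceWarning as exc:
                last_exc = exc
                continue
        break
    else:
        raise RuntimeError(
            f"spatial ICA failed to converge within {ICA_MAX_ITER} iterations "
            f"(tol {ICA_TOL}) after {ICA_MAX_RESTARTS} restarts: {last_exc}")

    mixing = ica.mixing_  # frames x K
    # sign convention: largest-|value| voxel of each map is positive
    signs = np.sign(S[np.abs(S).argmax(axis=0), np.arange(n_components)])
    signs[signs == 0] = 1.0
    S = S * signs
    mixing = mixing * signs
    # unit variance over brain voxels
    scale = S.std(axis=0)
    scale[scale == 0] = 1.0
    S = S / scale
    mixing = mixing * scale

    recon = S @ mixing.T + ica.mean_[None, :]
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    resid = float(((X - recon) ** 2).sum())
    retained = 1.0 - resid / total if total > 0 else 1.0

    maps = np.zeros((n_components,) + brain.shape3d)
    zmaps = np.zeros_like(maps)
    for k in range(n_components):
        m = np.zeros(brain_flat.size)
        m[brain_flat] = S[:, k]
        maps[k] = m.reshape(brain.shape3d)
        zmaps[k] = maps[k] / _robust_sd(S[:, k])
    return ICADecomposition(maps=maps, zmaps=zmaps, mixing=mixing, brain=brain,
                            seed=seed, n_iter=ica.n_iter_,
                            retained_variance=retained, restarts_used=attempt)


def match_components(dec: ICADecomposition, reference_maps: np.ndarray,
                     brain: Mask | None = None
                     ) -> list[tuple[int, int, float]]:
    """Optimally assign components to reference maps by absolute spatial r.

    Returns (component, reference, r) triples — the one-to-one assignment
    maximizing total |r| (Hungarian algorithm), with the sign of r reported.
    """
    reference_maps = np.asarray(reference_maps)
    if reference_maps.ndim == 3:
        reference_maps = reference_maps[None]
    if reference_maps.shape[0] > dec.n_components:
        raise ValueError("fewer components than reference maps")
    if reference_maps.shape[1:] != dec.brain.shape3d:
        raise ValueError("reference maps are on a different grid")
    mask = (brain or dec.brain).data.ravel()
    C = dec.maps.reshape(dec.n_components, -1)[:, mask]
    R = reference_maps.reshape(reference_maps.shape[0], -1)[:, mask]
    Cz = (C - C.mean(axis=1, keepdims=True))
    Rz = (R - R.mean(axis=1, keepdims=True))
    Cz /= np.linalg.norm(Cz, axis=1, keepdims=True)
    Rz /= np.linalg.norm(Rz, axis=1, keepdims=True)
    corr = Cz @ Rz.T  # K x n_ref
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return [(int(i), int(j), float(corr[i, j])) for i, j in zip(rows, cols)]


def save_decomposition(dec: ICADecomposition, out_dir: str | Path) -> None:
    """Write per-component z-map NIfTIs and the mixing matrix TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k in range(dec.n_components):
        write_volume(dec.map_volume(k, z=True), out_dir / f"ic{k:02d}_zmap.nii.gz")
    np.savetxt(out_dir / "mixing.tsv", dec.mixing, delimiter="\t", fmt="%.6f")
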