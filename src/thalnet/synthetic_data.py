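"""Synthetic two-group resting-state cohorts with planted thalamocortical networks.

Every downstream stage of the pipeline is validated against cohorts built
here: K spatial networks, each driven by its own autocorrelated latent time
course, load on a cortical blob outside the thalamus and on a weight map
inside it. A multiplicative group factor on the thalamic weights of selected
components plants a connectivity alteration in the "patient" group,
mirroring the hypo-/hyperconnectivity readout of a two-group study.

The generator emulates structure, not scanner physics: no hemodynamic
response, no motion, white Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import STANDARD_CONFOUNDS, ConfoundTable
from .volume_io import Mask, Volume4D, write_mask, write_volume

Group = Literal["control", "patient"]


@dataclass
class GroundTruth:
    """Planted generative model of a cohort."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    thalamus: Mask
    brain: Mask
    network_maps: np.ndarray        # (K, x, y, z) nonnegative, support outside thalamus
    thalamic_weights: np.ndarray    # (K, x, y, z) nonnegative, support inside thalamus
    ar_coeff: float
    group_effect: dict[int, float]  # component -> multiplicative factor for patients
    noise_sd: float
    n_timepoints: int
    tr_s: float
    seed: int

    @property
    def n_components(self) -> int:
        return self.network_maps.shape[0]

    def loading_map(self, k: int, group: Group) -> np.ndarray:
        """Per-voxel loading of component k: cortical blob outside the
        thalamus, (group-scaled) thalamic weight inside."""
        g = self.group_effect.get(k, 1.0) if group == "patient" else 1.0
        a = self.network_maps[k].copy()
        a[self.thalamus.data] = g * self.thalamic_weights[k][self.thalamus.data]
        return a


@dataclass
class CohortSpec:
    """Cohort size and demographics for :func:`simulate_cohort`."""

    n_per_group: int = 12
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 22.58, "patient": 22.88})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"control": 3.94, "patient": 5.64})
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.5, "patient": 0.45})

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 for any inference test")


def _gaussian_blob(shape: Sequence[int], center: np.ndarray, sd: float) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sd**2))


def make_ground_truth(*, shape: tuple[int, int, int] = (18, 22, 18),
                      n_components: int = 3,
                      group_effect: dict[int, float] | None = None,
                      noise_sd: float = 0.5, ar_coeff: float = 0.3,
                      n_timepoints: int = 116, tr_s: float = 3.5,
                      blob_sd: float = 1.8, seed: int = 0) -> GroundTruth:
    """Build a reproducible ground truth on a 3 mm grid.

    The thalamus is a central ellipsoid; the K cortical networks are
    Gaussian blobs placed on a ring around it at maximally separated angles,
    thresholded at 5% of peak so each has compact suprathreshold support.
    Thalamic weight maps are Gaussian bumps around K distinct loci inside
    the ellipsoid; together they cover its full support.
    """
    if min(shape) < 12:
        raise ValueError("grid must be at least 12 voxels per axis to fit blobs")
    if n_components < 2:
        raise ValueError("need at least 2 components")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    center = (np.array(shape) - 1) / 2.0

    # thalamus: central ellipsoid with semi-axes ~1/6 of the grid
    semi = np.maximum(np.array(shape) / 6.0, 2.0)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ell = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    thal = Mask(data=ell <= 1.0, affine=affine)

    # brain: large central ellipsoid leaving a 1-voxel rim
    semi_b = (np.array(shape) - 2) / 2.0
    ell_b = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_b))
    brain = Mask(data=ell_b <= 1.0, affine=affine)

    # cortical blobs on a ring in the x-y plane, alternating in z
    radius = min(shape[0], shape[1]) / 2.0 - blob_sd - 1.5
    if radius <= semi[:2].max():
        raise ValueError(f"grid {shape} too small to place blobs clear of the thalamus")
    nets = np.zeros((n_components,) + shape)
    for k in range(n_components):
        ang = 2.0 * np.pi * k / n_components + np.pi / n_components
        c = center + np.array([radius * np.cos(ang), radius * np.sin(ang),
                               (shape[2] / 6.0) * (1 if k % 2 else -1)])
        blob = _gaussian_blob(shape, c, blob_sd)
        blob[blob < 0.05] = 0.0
        blob[thal.data] = 0.0
        blob[~brain.data] = 0.0
        if not (blob > 0.05).any():
            raise ValueError(f"network blob {k} fell outside the brain mask")
        nets[k] = blob

    # thalamic weights: bumps around K loci spread along the ellipsoid's long axis
    thal_idx = thal.indices().astype(float)
    axis = np.argmax(semi)
    order = np.argsort(thal_idx[:, axis] + 1e-6 * rng.standard_normal(len(thal_idx)))
    loci = thal_idx[order[np.linspace(0, len(order) - 1, n_components).astype(int)]]
    weights = np.zeros((n_components,) + shape)
    for k in range(n_components):
        bump = _gaussian_blob(shape, loci[k], max(semi.min(), 1.5))
        bump[~thal.data] = 0.0
        weights[k] = bump / bump.max()
    # guarantee full coverage of the thalamic support
    total = weights.sum(axis=0)
    assert (total[thal.data] > 0).all()

    effect = dict(group_effect) if group_effect else {0: 0.5}
    for k, g in effect.items():
        if not (0 <= k < n_components) or g <= 0:
            raise ValueError(f"invalid group effect ({k}: {g})")
    return GroundTruth(shape=shape, affine=affine, thalamus=thal, brain=brain,
                       network_maps=nets, thalamic_weights=weights,
                       ar_coeff=ar_coeff, group_effect=effect, noise_sd=noise_sd,
                       n_timepoints=n_timepoints, tr_s=tr_s, seed=seed)


def _ar1(n: int, coeff: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(1.0 - coeff**2) if abs(coeff) < 1 else innov[0]
    for t in range(1, n):
        x[t] = coeff * x[t - 1] + innov[t]
    return x


def _smooth_series(n: int, rng: np.random.Generator, window: int = 9) -> np.ndarray:
    raw = rng.standard_normal(n + window)
    kernel = np.hanning(window)
    kernel /= kernel.sum()
    return np.convolve(raw, kernel, mode="same")[:n]


def simulate_subject(gt: GroundTruth, group: Group, seed: int,
                     confound_leak: float = 0.1
                     ) -> tuple[Volume4D, ConfoundTable]:
    """Simulate one subject's 4D series and confound table.

    Voxel series = sum_k loading_k(voxel) * c_k(t) + leak * confound drift
    + white noise, with c_k AR(1) latent time courses and the loading
    including the patient group factor on affected components' thalamic
    weights. The confound leak is a small shared drift so that confound
    regression has real work to do.
    """
    if group not in ("control", "patient"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    T = gt.n_timepoints
    tcs = np.stack([_ar1(T, gt.ar_coeff, rng) for _ in range(gt.n_components)])

    data = np.zeros(gt.shape + (T,))
    for k in range(gt.n_components):
        a = gt.loading_map(k, group)
        data += a[..., None] * tcs[k]

    conf = pd.DataFrame(
        {name: _smooth_series(T, rng) for name in STANDARD_CONFOUNDS})
    drift = conf[["wm", "csf"]].to_numpy().sum(axis=1)
    spatial = rng.uniform(0.5, 1.5, size=gt.shape)
    data += confound_leak * spatial[..., None] * drift

    if gt.noise_sd > 0:
        data += gt.noise_sd * rng.standard_normal(data.shape)
    data[~gt.brain.data] = 0.0
    vol = Volume4D(data=data, affine=gt.affine, frame_axis_meaning="time")
    return vol, ConfoundTable(conf)


def simulate_cohort(gt: GroundTruth, spec: CohortSpec, out_dir: str | Path,
                    seed: int = 0) -> pd.DataFrame:
    """Write a full cohort to disk and return its design table.

    Layout: ``data/sub-XX_bold.nii.gz``, ``data/sub-XX_confounds.tsv``,
    ``design.tsv`` (subject_id, group, age, sex), ``thalamus.nii.gz``,
    ``brain.nii.gz`` and a ``manifest.yaml`` recording every seed so the
    cohort can be regenerated bit-for-bit.
    """
    out_dir = Path(out_dir)
    (out_dir / "data").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    subject_seeds: dict[str, int] = {}
    i = 0
    for group in ("control", "patient"):
        for _ in range(spec.n_per_group):
            i += 1
            sid = f"sub-{i:02d}"
            sseed = int(rng.integers(0, 2**31 - 1))
            subject_seeds[sid] = sseed
            vol, conf = simulate_subject(gt, group, sseed)
            write_volume(vol, out_dir / "data" / f"{sid}_bold.nii.gz")
            conf.write(out_dir / "data" / f"{sid}_confounds.tsv")
            age = spec.age_mean[group] + spec.age_sd[group] * rng.standard_normal()
            sex = "M" if rng.random() < spec.male_fraction[group] else "F"
            rows.append({"subject_id": sid, "group": group,
                         "age": round(float(age), 2), "sex": sex})
    design = pd.DataFrame(rows)
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    write_mask(gt.thalamus, out_dir / "thalamus.nii.gz")
    write_mask(gt.brain, out_dir / "brain.nii.gz")
    manifest = {
        "cohort_seed": int(seed),
        "ground_truth_seed": int(gt.seed),
        "n_per_group": spec.n_per_group,
        "n_components": gt.n_components,
        "group_effect": {int(k): float(v) for k, v in gt.group_effect.items()},
        "noise_sd": float(gt.noise_sd),
        "n_timepoints": int(gt.n_timepoints),
        "tr_s": float(gt.tr_s),
        "shape": [int(s) for s in gt.shape],
        "subject_seeds": subject_seeds,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return design
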