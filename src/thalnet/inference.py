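"""Nonparametric group inference on voxel maps.

A GLM with covariates gives a per-voxel t map for a contrast; the null
distribution of the maximum enhanced statistic (TFCE, cluster extent, or
raw voxel |t|) over Freedman-Lane permutations (or sign flips for
one-sample designs) yields family-wise-error corrected p values — the
nonparametric inference core of the pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import Mask

Scheme = Literal["label_permutation", "sign_flip"]
Enhancement = Literal["tfce", "cluster_extent", "voxel"]

TFCE_E = 0.5
TFCE_H = 2.0
DEFAULT_FORMING_T = 2.3


@dataclass
class GroupDesign:
    """Design matrix, contrast and exchangeability scheme for a group GLM."""

    matrix: np.ndarray            # subjects x regressors
    contrast: np.ndarray
    scheme: Scheme = "label_permutation"
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.contrast.shape != (self.matrix.shape[1],):
            raise ValueError("contrast length must equal regressor count")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank-deficient")
        if self.scheme == "sign_flip":
            for c in self.interest_columns:
                if not np.allclose(self.matrix[:, c], self.matrix[0, c]):
                    raise ValueError(
                        "sign_flip exchangeability is incompatible with a "
                        "non-constant (group) interest regressor; use "
                        "label_permutation")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def interest_columns(self) -> np.ndarray:
        """Columns with nonzero contrast weight (the tested effect)."""
        return np.flatnonzero(self.contrast)

    @property
    def nuisance_columns(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.matrix.shape[1]), self.interest_columns)


def make_group_design(design_table: pd.DataFrame, *,
                      contrast: str = "control>patient",
                      covariates: tuple[str, ...] = ("age", "sex")
                      ) -> GroupDesign:
    """Two-sample design from a cohort design table (group, age, sex).

    Columns: intercept, group indicator (control = 1), then centred
    covariates; the contrast tests the group column, signed so that a
    positive t means the first-named group is larger.
    """
    groups = design_table["group"].astype(str).to_numpy()
    known = {"control", "patient"}
    if not set(groups) <= known:
        raise ValueError(f"unknown group labels: {sorted(set(groups) - known)}")
    a, _, b = contrast.partition(">")
    if {a, b} != known:
        raise ValueError(f"contrast must compare control and patient, got {contrast!r}")
    indicator = (groups == "control").astype(float)
    cols = [np.ones(len(groups)), indicator]
    names = ["intercept", "group_control"]
    for cov in covariates:
        if cov not in design_table.columns:
            continue
        v = design_table[cov]
        v = ((v == v.iloc[0]).astype(float) if v.dtype == object
             else v.astype(float))
        cols.append(v.to_numpy() - v.to_numpy().mean())
        names.append(cov)
    c = np.zeros(len(cols))
    c[1] = 1.0 if a == "control" else -1.0
    return GroupDesign(matrix=np.column_stack(cols), contrast=c,
                       scheme="label_permutation", column_names=names)


def one_sample_design(n: int) -> GroupDesign:
    """One-sample mean design tested by sign flipping."""
    return GroupDesign(matrix=np.ones((n, 1)), contrast=np.array([1.0]),
                       scheme="sign_flip", column_names=["mean"])


@dataclass
class StatMap:
    """A 3D t-statistic map with its degrees of freedom and mask."""

    t: np.ndarray
    df: int
    mask: Mask

    def __post_init__(self) -> None:
        if not np.isfinite(self.t[self.mask.data]).all():
            raise ValueError("non-finite t values inside the mask")


@dataclass
class PermutationResult:
    observed: StatMap
    enhanced: np.ndarray          # signed enhanced map
    corrected_p: np.ndarray       # FWE-corrected p (1 outside mask)
    cluster_table: pd.DataFrame   # cluster_id, size, peak_ijk, peak_stat, corrected_p
    n_permutations: int
    seed: int
    exhaustive: bool = False


def _fit_t(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray
           ) -> tuple[np.ndarray, int]:
    """Per-column OLS t statistics. Y: (n, V); X: (n, p)."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = float(contrast @ np.linalg.inv(X.T @ X) @ contrast)
    se = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
    # exact fits leave se at rounding scale: treat as zero-variance voxels
    floor = 1e-10 * (np.abs(Y).max(axis=0) + np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > floor, (contrast @ beta) / se, 0.0)
    return t, df


def glm_tmap(data: np.ndarray, design: GroupDesign, mask: Mask) -> StatMap:
    """Voxelwise GLM t map for the design's contrast.

    ``data`` is a (x, y, z, subjects) stack aligned with the design rows.
    """
    if data.shape[3] != design.n_subjects:
        raise ValueError(
            f"stack has {data.shape[3]} frames but design has "
            f"{design.n_subjects} rows")
    flat = mask.data.ravel()
    Y = data.reshape(-1, data.shape[3])[flat].T
    t, df = _fit_t(Y, design.matrix, design.contrast)
    out = np.zeros(mask.shape3d)
    out.ravel()[flat] = t
    return StatMap(t=out, df=df, mask=mask)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def tfce(stat: np.ndarray, E: float = TFCE_E, H: float = TFCE_H,
         dh: float | None = None, connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of a (possibly signed) 3D map.

    TFCE(p) = sum over thresholds h of e(h, p)^E * h^H * dh, where e(h, p)
    is the size of the connected component of {stat >= h} containing p.
    The negative tail is enhanced by applying the same to the negated map;
    the output is signed. ``dh`` defaults to h_max / 100 per tail.
    """
    if E < 0 or H < 0:
        raise ValueError("E and H must be non-negative")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    stat = np.asarray(stat, dtype=np.float64)
    structure = _connectivity_structure(connectivity)

    def _one_tail(m: np.ndarray) -> np.ndarray:
        hmax = m.max()
        if hmax <= 0:
            return np.zeros_like(m)
        step = dh if dh is not None else hmax / 100.0
        out = np.zeros_like(m)
        h = step
        while h <= hmax + 1e-12:
            labels, n = ndimage.label(m >= h, structure=structure)
            if n == 0:
                break
            sizes = np.bincount(labels.ravel())
            enh = np.zeros(n + 1)
            enh[1:] = sizes[1:] ** float(E) * h ** float(H) * step
            out += enh[labels]
            h += step
        return out

    return _one_tail(stat) - _one_tail(-stat)


def _cluster_enhance(stat: np.ndarray, forming_t: float, connectivity: int
                     ) -> np.ndarray:
    """Map each voxel to the size of its |stat| >= forming_t cluster (signed)."""
    structure = _connectivity_structure(connectivity)
    out = np.zeros_like(stat)
    for sign in (1.0, -1.0):
        labels, n = ndimage.label(sign * stat >= forming_t, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel()).astype(float)
            sizes[0] = 0.0
            out += sign * sizes[labels]
    return out


def _enhancer(enhancement: Enhancement, forming_t: float, connectivity: int,
              tfce_dh: float | None) -> Callable[[np.ndarray], np.ndarray]:
    if enhancement == "tfce":
        return lambda m: tfce(m, dh=tfce_dh, connectivity=connectivity)
    if enhancement == "cluster_extent":
        return lambda m: _cluster_enhance(m, forming_t, connectivity)
    if enhancement == "voxel":
        return lambda m: m
    raise ValueError(f"unknown enhancement {enhancement!r}")


def _sign_flip_space(n: int) -> np.ndarray:
    return np.array(list(itertools.product([1.0, -1.0], repeat=n)))


def permutation_test(data: np.ndarray, design: GroupDesign, mask: Mask, *,
                     enhancement: Enhancement = "tfce",
                     forming_t: float = DEFAULT_FORMING_T,
                     connectivity: int = 26, tfce_dh: float | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> PermutationResult:
    """FWE-corrected inference by the max-statistic permutation null.

    Nuisance covariates are handled by the Freedman-Lane scheme: the data
    are residualized against the nuisance regressors, the residuals are
    permuted (or sign-flipped) and the nuisance fit added back before
    refitting the full model. Corrected
    p(v) = (1 + #{perm max >= observed(v)}) / (n_perm + 1); when the
    requested permutations exceed the exchangeability space (n! labelings /
    2^n flips) the space is enumerated exhaustively and p is exact.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = design.n_subjects
    if data.shape[3] != n:
        raise ValueError("stack frame count must equal design rows")
    # enhancement runs on the mask's bounding box: suprathreshold clusters
    # cannot extend through or connect across zero-filled off-mask space,
    # so cropping leaves TFCE and cluster sizes unchanged
    nz = np.argwhere(mask.data)
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask.data[box]
    sub_flat = sub_mask.ravel()
    Y = data[box].reshape(-1, n)[sub_flat].T             # subjects x voxels
    X = design.matrix
    enhance = _enhancer(enhancement, forming_t, connectivity, tfce_dh)

    def _map_t(Yp: np.ndarray) -> np.ndarray:
        t, _ = _fit_t(Yp, X, design.contrast)
        out = np.zeros(sub_mask.shape)
        out.ravel()[sub_flat] = t
        return out

    obs_t, df = _fit_t(Y, X, design.contrast)
    observed_sub = np.zeros(sub_mask.shape)
    observed_sub.ravel()[sub_flat] = obs_t
    observed_sub_enh = enhance(observed_sub)
    observed_map = np.zeros(mask.shape3d)
    observed_map[box] = observed_sub
    observed_enh = np.zeros(mask.shape3d)
    observed_enh[box] = observed_sub_enh

    # Freedman-Lane residualization against the nuisance-only model
    Z = X[:, design.nuisance_columns]
    if Z.shape[1]:
        Hz = Z @ np.linalg.pinv(Z)
        fitted = Hz @ Y
        resid = Y - fitted
    else:
        fitted = np.zeros_like(Y)
        resid = Y

    rng = np.random.default_rng(seed)
    if design.scheme == "sign_flip":
        exhaustive = n_perm >= 2**n
        if exhaustive:
            flips = _sign_flip_space(n)
        else:
            flips = rng.choice([1.0, -1.0], size=(n_perm, n))
        null_max = np.empty(len(flips))
        for i, s in enumerate(flips):
            enh = enhance(_map_t(fitted + s[:, None] * resid))
            null_max[i] = np.abs(enh).max()
        n_eff = len(flips)
    else:
        from math import factorial
        exhaustive = factorial(n) <= n_perm
        if exhaustive:
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        null_max = np.empty(len(perms))
        for i, p in enumerate(perms):
            enh = enhance(_map_t(fitted + resid[p]))
            null_max[i] = np.abs(enh).max()
        n_eff = len(perms)

    abs_enh = np.abs(observed_sub_enh.ravel()[sub_flat])
    exceed = (null_max[None, :] >= abs_enh[:, None]).sum(axis=1)
    if exhaustive:
        p_flat = exceed / n_eff  # identity is in the space: p >= 1/n_eff
    else:
        p_flat = (1.0 + exceed) / (n_eff + 1.0)
    # C-order enumeration of in-mask voxels is preserved by the crop
    corrected_p = np.ones(mask.shape3d)
    corrected_p[mask.data] = p_flat

    table = _cluster_table(observed_map, observed_enh, corrected_p, mask,
                           enhancement, forming_t, connectivity, alpha)
    return PermutationResult(
        observed=StatMap(t=observed_map, df=df, mask=mask),
        enhanced=observed_enh, corrected_p=corrected_p, cluster_table=table,
        n_permutations=n_eff, seed=seed, exhaustive=exhaustive)


def _cluster_table(tmap: np.ndarray, enhanced: np.ndarray, corrected_p: np.ndarray,
                   mask: Mask, enhancement: Enhancement, forming_t: float,
                   connectivity: int, alpha: float) -> pd.DataFrame:
    """Table of significant clusters (corrected p < alpha), sorted by p."""
    structure = _connectivity_structure(connectivity)
    sig = (corrected_p < alpha) & mask.data
    rows = []
    labels, n = ndimage.label(sig, structure=structure)
    for cid in range(1, n + 1):
        members = labels == cid
        peak_flat = np.abs(np.where(members, tmap, 0.0)).argmax()
        peak = np.unravel_index(peak_flat, tmap.shape)
        rows.append({
            "cluster_id": cid,
            "size": int(members.sum()),
            "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
            "peak_t": float(tmap[peak]),
            "corrected_p": float(corrected_p[members].min()),
        })
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_i", "peak_j",
                                        "peak_k", "peak_t", "corrected_p"])
    return table.sort_values("corrected_p", ignore_index=True) if rows else table


def cluster_extent_correct(data: np.ndarray, design: GroupDesign, mask: Mask, *,
                           forming_t: float = DEFAULT_FORMING_T,
                           connectivity: int = 26, n_perm: int = 1000,
                           seed: int = 0, alpha: float = 0.05
                           ) -> PermutationResult:
    """Cluster-extent FWE correction: |t| >= forming_t clusters against the
    max-cluster-size permutation null."""
    if forming_t <= 0:
        raise ValueError("forming threshold must be positive")
    return permutation_test(data, design, mask, enhancement="cluster_extent",
                            forming_t=forming_t, connectivity=connectivity,
                            n_perm=n_perm, seed=seed, alpha=alpha)
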