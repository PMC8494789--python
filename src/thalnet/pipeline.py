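"""End-to-end orchestration of the thalamocortical connectivity analysis.

Stage order: preprocess -> thalamic seed maps -> group spatial ICA ->
dual regression -> primary inference (per component, group difference of
thalamic subdivision maps) -> seed analysis (per component). A manifest
records the configuration hash and every seed so reruns reproduce all
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dual_regression, seed_analysis, seedmaps, spatial_ica
from .inference import (DEFAULT_FORMING_T, cluster_extent_correct,
                        make_group_design)
from .preprocess import ConfoundTable, preprocess_subject
from .volume_io import Mask, read_mask, read_volume, write_mask, write_volume

log = logging.getLogger("thalnet")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the reference analysis."""

    data_dir: str
    out_dir: str
    thalamus_mask: str
    brain_mask: str
    design_table: str
    trim: int = 4
    highpass_hz: float | None = 0.01
    tr_s: float = 3.5
    n_components: int = 20
    ica_seed: int = 0
    n_perm: int = 1000
    forming_t: float = DEFAULT_FORMING_T
    inference_seed: int = 0
    alpha: float = 0.05
    ica_controls_only: bool = False
    run_seed_analysis: bool = True

    def validate(self) -> None:
        for name in ("data_dir", "thalamus_mask", "brain_mask", "design_table"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: pd.DataFrame
    decomposition: spatial_ica.ICADecomposition
    subdivisions: list[dual_regression.SubdivisionMaps]
    primary: dict[int, object] = field(default_factory=dict)    # component -> PermutationResult
    seeds: dict[int, object] = field(default_factory=dict)      # component -> SeedDefinition
    seed_results: dict[int, object] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; writes an output tree plus manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir)
    thal = read_mask(config.thalamus_mask)
    brain = read_mask(config.brain_mask)
    design_tab = pd.read_csv(config.design_table, sep="\t")
    if (design_tab["group"].value_counts() < 2).any():
        raise ValueError("need at least 2 subjects per group")

    # preprocess + seed maps per subject
    cleaned: dict[str, object] = {}
    mapsets = []
    for _, row in design_tab.iterrows():
        sid = row["subject_id"]
        bold_path = data_dir / f"{sid}_bold.nii.gz"
        conf_path = data_dir / f"{sid}_confounds.tsv"
        if not bold_path.exists():
            raise FileNotFoundError(f"stage preprocess: missing volume for {sid}")
        if not conf_path.exists():
            raise FileNotFoundError(f"stage preprocess: missing confound file for {sid}")
        log.info("preprocess %s", sid)
        vol = read_volume(bold_path)
        conf = ConfoundTable.read(conf_path)
        clean = preprocess_subject(vol, conf, trim=config.trim,
                                   highpass_hz=config.highpass_hz, tr_s=config.tr_s)
        cleaned[sid] = clean
        log.info("seedmaps %s", sid)
        mapsets.append(seedmaps.thalamic_seed_maps(clean, thal, brain, subject_id=sid))

    # group ICA on cortex: the components are cortical networks, and the
    # seed voxel's self-correlation spike (inside the thalamus) would
    # otherwise dominate the reduction at small grid scales
    cortex = Mask(data=brain.data & ~thal.data, affine=brain.affine)
    if config.ica_controls_only:
        keep = set(design_tab.loc[design_tab["group"] == "control", "subject_id"])
        ica_sets = [m for m in mapsets if m.subject_id in keep]
    else:
        ica_sets = mapsets
    stack = seedmaps.concatenate_group(ica_sets)
    log.info("spatial ICA: %d frames, %d components", stack.maps.n_frames,
             config.n_components)
    dec = spatial_ica.fit_spatial_ica(stack, cortex, config.n_components,
                                      seed=config.ica_seed)
    spatial_ica.save_decomposition(dec, out / "ica")

    # dual regression
    subdivisions = []
    for _, row in design_tab.iterrows():
        sid = row["subject_id"]
        log.info("dual regression %s", sid)
        _, sub = dual_regression.dual_regress(cleaned[sid], dec, brain, thal,
                                              subject_id=sid)
        subdivisions.append(sub)

    design = make_group_design(design_tab)
    result = PipelineResult(config=config, design=design_tab,
                            decomposition=dec, subdivisions=subdivisions)

    # primary inference: group difference of subdivision maps per component
    prim_dir = out / "primary"
    prim_dir.mkdir(exist_ok=True)
    for k in range(dec.n_components):
        log.info("primary inference, component %d", k)
        stack_k = np.stack([s.thal_betas[k] for s in subdivisions], axis=3)
        res = cluster_extent_correct(stack_k, design, thal,
                                     forming_t=config.forming_t,
                                     n_perm=config.n_perm,
                                     seed=config.inference_seed + k,
                                     alpha=config.alpha)
        res.cluster_table.to_csv(prim_dir / f"ic{k:02d}_clusters.tsv",
                                 sep="\t", index=False)
        write_volume(_p_volume(res, thal), prim_dir / f"ic{k:02d}_1minusp.nii.gz")
        result.primary[k] = res

    # seed analysis per component
    if config.run_seed_analysis:
        seed_dir = out / "seed_analysis"
        seed_dir.mkdir(exist_ok=True)
        for k in range(dec.n_components):
            log.info("seed analysis, component %d", k)
            try:
                sd = seed_analysis.extract_seed(subdivisions, k,
                                                n_perm=config.n_perm,
                                                seed=config.inference_seed + 1000 + k,
                                                alpha=config.alpha)
            except seed_analysis.EmptySeedError as exc:
                log.warning("component %d: %s", k, exc)
                continue
            write_mask(sd.mask, seed_dir / f"ic{k:02d}_seed.nii.gz")
            result.seeds[k] = sd
            maps = np.stack(
                [seed_analysis.seed_connectivity_map(cleaned[sid], sd, brain)
                 for sid in design_tab["subject_id"]], axis=3)
            res = seed_analysis.compare_seed_maps(
                maps, design, brain, n_perm=config.n_perm,
                seed=config.inference_seed + 2000 + k, alpha=config.alpha)
            res.cluster_table.to_csv(seed_dir / f"ic{k:02d}_clusters.tsv",
                                     sep="\t", index=False)
            write_volume(_p_volume(res, brain), seed_dir / f"ic{k:02d}_1minusp.nii.gz")
            result.seed_results[k] = res

    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "n_subjects": len(design_tab),
                "ica_retained_variance": float(dec.retained_variance)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return result


def _p_volume(res, mask: Mask):
    from .volume_io import Volume4D
    return Volume4D(data=(1.0 - res.corrected_p)[..., None], affine=mask.affine,
                    frame_axis_meaning="stacked_maps")
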