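"""End-to-end study pipeline on synthetic cohorts.

``run_study`` chains every stage the analysis defines: cohort generation,
motion QC and eligibility filtering, nuisance denoising, voxel-wise metric
computation, metric-map smoothing, ComBat site harmonization, the group
GLM with GRF cluster correction, and cluster-level effect sizes. It exists
both as the integration surface for users and as the object the
acceptance checks exercise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import qc
from .cohort import (
    BehaviorSpec,
    CohortSpec,
    EffectSpec,
    SiteSpec,
    default_cohort_spec,
    default_effects,
    default_sites,
    generate_behavior,
    generate_bold,
    generate_motion,
    generate_phenotypes,
)
from .denoise import bandpass, build_nuisance_design, nuisance_regress, smooth
from .effects import ClusterEffects, extract_cluster_means
from .glm import GroupGLM, GroupGLMResults
from .metrics import compute_metric

__all__ = ["StudyResult", "simulate_metric_dataset", "run_study"]


@dataclass
class StudyResult:
    """Everything the pipeline produced for one simulated cohort."""

    table: pd.DataFrame
    mask: np.ndarray
    matrices: dict[str, np.ndarray]  # metric -> (N, V) in-mask matrix
    harmonized: dict[str, np.ndarray]
    glm: dict[str, GroupGLMResults]
    cluster_effects: dict[str, list] = field(default_factory=dict)
    effects_spec: EffectSpec | None = None
    dropped_sites: list[str] = field(default_factory=list)
    mfd_threshold: float = np.nan

    def interaction_clusters(self, metric: str = "vmhc"):
        return self.glm[metric].significant_clusters("dx_by_sex")


def _noise_shell(mask: np.ndarray) -> np.ndarray:
    """Peripheral shell of the brain mask used as the CompCor compartment."""
    eroded = ndimage.binary_erosion(mask, iterations=2)
    shell = mask & ~eroded
    return shell if shell.any() else mask


def simulate_metric_dataset(
    spec: CohortSpec,
    sites: list[SiteSpec],
    effects: EffectSpec,
    seed: int,
    metric_names: tuple[str, ...] = ("vmhc",),
    smooth_fwhm: float = 6.0,
    gsr: bool = False,
    n_compcor: int = 5,
    apply_qc: bool = True,
    behavior: BehaviorSpec | None = None,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, np.ndarray]]:
    """Generate a cohort and compute its subject-level metric matrices.

    Returns the post-QC phenotype table (with realized mean FD), the
    analysis mask, and one (N, V) matrix per requested metric, rows
    aligned with the table.
    """
    spec = dataclasses.replace(spec, rng_seed=seed)
    master = np.random.default_rng(seed)
    table = generate_phenotypes(spec, sites)
    site_index = {f"site{s:02d}": sites[s] for s in range(spec.n_sites)}

    motions = {
        row["subject_id"]: generate_motion(spec, row, master)
        for _, row in table.iterrows()
    }
    table = table.assign(mfd=[qc.mean_fd(motions[s]) for s in table["subject_id"]])

    if apply_qc:
        report = qc.eligibility_filter(table)
        table = report.table
        table, _dropped = qc.site_cell_filter(table)

    mask = None
    rows_maps: dict[str, list[np.ndarray]] = {m: [] for m in metric_names}
    seed_mask = effects.rois.get("seed") if effects.rois else None
    for _, row in table.iterrows():
        site = site_index[row["site"]]
        rng = np.random.default_rng(master.integers(2**31))
        motion = motions[row["subject_id"]]
        bold = generate_bold(row, spec, effects, site, rng, motion=motion)
        if mask is None:
            mask = bold.mask
        design = build_nuisance_design(
            bold, motion, noise_mask=_noise_shell(mask), n_compcor=n_compcor, gsr=gsr
        )
        denoised = nuisance_regress(bold, design)
        filtered = bandpass(denoised, *effects.band)
        for name in metric_names:
            m = compute_metric(
                name,
                filtered,
                bold_unfiltered=denoised,
                seed_mask=seed_mask,
            )
            smoothed = (
                smooth(m.data, smooth_fwhm, spec.voxel_size)
                if smooth_fwhm > 0
                else m.data
            )
            rows_maps[name].append(smoothed[mask])

    matrices = {m: np.vstack(v) for m, v in rows_maps.items()}

    if behavior is not None and "vmhc" in matrices:
        roi = effects.rois.get("dlo")
        if roi is not None:
            roi_cols = roi[mask]
            roi_signal = matrices["vmhc"][:, roi_cols].mean(axis=1)
            table = generate_behavior(table, roi_signal, behavior, master)
    return table, mask, matrices


def run_study(
    spec: CohortSpec | None = None,
    sites: list[SiteSpec] | None = None,
    effects: EffectSpec | None = None,
    behavior: BehaviorSpec | None = None,
    seed: int = 0,
    metric_names: tuple[str, ...] = ("vmhc",),
    smooth_fwhm: float = 6.0,
    gsr: bool = False,
    include_fiq: bool = False,
    z_thresh: float = 3.1,
    cluster_alpha: float = 0.01,
) -> StudyResult:
    """Full discovery analysis on one simulated cohort."""
    spec = spec or default_cohort_spec()
    sites = sites or default_sites(spec.n_sites)
    effects = effects or default_effects(spec.grid_dims)
    table, mask, matrices = simulate_metric_dataset(
        spec, sites, effects, seed, metric_names, smooth_fwhm, gsr,
        behavior=behavior,
    )

    # protect the effects of interest plus covariates during harmonization
    dx = (table["dx"] == "ASD").astype(float).to_numpy()
    sex = (table["sex"] == "F").astype(float).to_numpy()
    age = table["age"].to_numpy(float)
    mfd = table["mfd"].to_numpy(float)
    protect = np.column_stack(
        [dx, sex, dx * sex, age - age.mean(), mfd - mfd.mean()]
    )

    from .harmonize import ComBat

    harmonized = {}
    glm_results = {}
    cluster_effects: dict[str, list] = {}
    for name, mat in matrices.items():
        if table["site"].nunique() > 1:
            fit = ComBat(mat, table["site"].to_numpy(), protect).fit()
            hmat = fit.transform(mat, table["site"].to_numpy(), protect)
        else:
            hmat = mat
        harmonized[name] = hmat
        model = GroupGLM(hmat, table, mask, spec.voxel_size, include_fiq=include_fiq)
        res = model.fit(z_thresh=z_thresh, cluster_alpha=cluster_alpha)
        glm_results[name] = res
        effs = []
        for term in ("dx", "sex", "dx_by_sex"):
            for rec in res.significant_clusters(term):
                means = extract_cluster_means(hmat, rec.mask[mask])
                fitres = ClusterEffects(means, table).fit()
                eff = fitres[term]
                eff.cluster_id = rec.label
                effs.append(eff)
        cluster_effects[name] = effs

    return StudyResult(
        table=table,
        mask=mask,
        matrices=matrices,
        harmonized=harmonized,
        glm=glm_results,
        cluster_effects=cluster_effects,
        effects_spec=effects,
    )
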