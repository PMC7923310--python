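"""Synthetic multi-site resting-state cohorts with known ground truth.

The generator emulates a 2 (diagnosis: ASD/NT) x 2 (sex: M/F) multi-site
case-control design of the kind aggregated by large autism data-sharing
initiatives: per-site phenotypes (age, full-scale IQ, head motion), realistic
motion traces, ADOS-style behaviour scores for the clinical group, and 4D
BOLD volumes on a left-right symmetric grid.

The BOLD model is deliberately low-rank: each voxel mixes a small set of
band-limited (0.01-0.1 Hz) latent signals -- a mirror-pair latent (homotopic
coupling, the VMHC channel), a hemisphere-specific regional latent
(neighbourhood coherence, the ReHo channel), a global seed latent (the
seed-iFC channel), a hub latent (the degree-centrality channel) -- with a
broadband AR(1) noise floor whose variance share sets the in-band fraction
(the fALFF channel). Group effects enter as additive shifts of the relevant
coupling parameter inside named regions of interest; site batch effects
enter as location/scale perturbations of the coupling on its Fisher-z scale,
which is where correlation-derived metric maps live.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SiteSpec",
    "ChannelEffect",
    "EffectSpec",
    "BehaviorSpec",
    "BoldImage",
    "default_cohort_spec",
    "default_sites",
    "default_mask",
    "default_effects",
    "generate_phenotypes",
    "generate_motion",
    "generate_bold",
    "generate_behavior",
]

CELL_ORDER = (("ASD", "M"), ("ASD", "F"), ("NT", "M"), ("NT", "F"))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic multi-site cohort.

    ``cell_sizes[s]`` gives the four cell counts for site ``s`` in the order
    (ASD-M, ASD-F, NT-M, NT-F).
    """

    n_sites: int = 4
    cell_sizes: Sequence[Sequence[int]] = ((10, 10, 10, 10),) * 4
    age_range: tuple[float, float] = (7.0, 18.0)
    fiq_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 106.0, "NT": 112.0}
    )
    fiq_sd: float = 13.0
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size: float = 3.0
    n_timepoints: int = 150
    tr: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        nx = self.grid_dims[0]
        if nx % 2 != 0:
            raise ValueError("grid_dims[0] must be even (exact mirror pairs)")
        if len(self.cell_sizes) != self.n_sites:
            raise ValueError("cell_sizes must have one entry per site")
        for cells in self.cell_sizes:
            if len(cells) != 4 or any(int(c) < 0 for c in cells):
                raise ValueError("each site needs four non-negative cell counts")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        lo, hi = self.age_range
        if not (0 < lo < hi < 100):
            raise ValueError("age_range must lie within (0, 100)")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")


@dataclass(frozen=True)
class SiteSpec:
    """Batch parameters of one acquisition site.

    ``gamma`` is an additive offset on the Fisher-z coupling scale (the
    location parameter a ComBat-style model should recover), ``delta`` a
    multiplicative scale on between-subject coupling variation, and
    ``motion_shift`` an offset (mm) on the site's mean-FD distribution.
    """

    gamma: float = 0.0
    delta: float = 1.0
    motion_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class ChannelEffect:
    """Group effect on one generative coupling parameter inside one ROI.

    The coupling inside the ROI is ``base + beta_dx*dx + beta_sex*sex +
    beta_int*dx*sex`` with dx = 1 for ASD and sex = 1 for female.
    """

    roi: str
    beta_dx: float = 0.0
    beta_sex: float = 0.0
    beta_int: float = 0.0

    def shift(self, dx: int, sex: int) -> float:
        return self.beta_dx * dx + self.beta_sex * sex + self.beta_int * dx * sex


@dataclass
class EffectSpec:
    """Ground-truth effect structure of the generator.

    ``rois`` maps ROI names to boolean masks on the cohort grid. Each
    channel list injects effects on one generative parameter: ``homotopic``
    (mirror-pair coupling, VMHC), ``regional`` (neighbourhood coherence,
    ReHo), ``seed`` (coupling to the seed latent, seed-iFC), ``hub``
    (coupling to the hub latent, DC), ``inband`` (in-band variance
    fraction, fALFF).
    """

    rois: dict[str, np.ndarray]
    homotopic: Sequence[ChannelEffect] = ()
    regional: Sequence[ChannelEffect] = ()
    seed: Sequence[ChannelEffect] = ()
    hub: Sequence[ChannelEffect] = ()
    inband: Sequence[ChannelEffect] = ()
    base_coupling: float = 0.35
    base_inband: float = 0.55
    seed_roi: str | None = "seed"
    seed_self_share: float = 0.6
    subject_sd: float = 0.08
    motion_amp: float = 0.25
    ar_coef: float = 0.3
    band: tuple[float, float] = (0.01, 0.1)


@dataclass(frozen=True)
class BehaviorSpec:
    """Targets for sex-differential brain-behaviour coupling (ADOS scores)."""

    r_female: float = -0.3
    r_male: float = 0.0
    score_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "ados_css": (1, 10),
            "ados_sa": (1, 20),
            "ados_rrb": (0, 8),
        }
    )
    score_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ados_css": (6.9, 2.0),
            "ados_sa": (9.0, 3.5),
            "ados_rrb": (3.0, 1.7),
        }
    )
    module_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.1, 3: 0.3, 4: 0.6}
    )

    def __post_init__(self) -> None:
        if abs(self.r_female) >= 1 or abs(self.r_male) >= 1:
            raise ValueError("target correlations must satisfy |r| < 1")
        if abs(sum(self.module_probs.values()) - 1.0) > 1e-9:
            raise ValueError("module_probs must sum to 1")


@dataclass
class BoldImage:
    """4D BOLD series on a regular grid with its brain mask."""

    data: np.ndarray  # (nx, ny, nz, T)
    mask: np.ndarray  # (nx, ny, nz) bool
    voxel_size: float
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def in_mask(self) -> np.ndarray:
        """Return the (n_voxels, T) matrix of in-mask time series."""
        return self.data[self.mask]


def default_cohort_spec(**overrides) -> CohortSpec:
    """The desk-scale study fixture: 4 sites x 10 per cell (N = 160)."""
    return dataclasses.replace(CohortSpec(), **overrides) if overrides else CohortSpec()


def default_sites(n_sites: int = 4) -> list[SiteSpec]:
    """Mildly heterogeneous sites with non-zero batch effects."""
    gammas = np.linspace(-0.3, 0.3, n_sites) if n_sites > 1 else [0.0]
    deltas = np.linspace(0.85, 1.2, n_sites) if n_sites > 1 else [1.0]
    shifts = np.linspace(-0.01, 0.02, n_sites) if n_sites > 1 else [0.0]
    return [
        SiteSpec(gamma=float(g), delta=float(d), motion_shift=float(m))
        for g, d, m in zip(gammas, deltas, shifts)
    ]


def default_mask(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Left-right symmetric ellipsoidal brain mask on the grid."""
    nx, ny, nz = grid_dims
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    mask = (
        ((x - cx) / (nx / 2.0 - 0.5)) ** 2
        + ((y - cy) / (ny / 2.0 - 0.5)) ** 2
        + ((z - cz) / (nz / 2.0 - 0.5)) ** 2
    ) <= 1.0
    # enforce exact mirror symmetry about the x mid-plane
    return mask & mask[::-1]


def _box(grid_dims, xs, ys, zs) -> np.ndarray:
    m = np.zeros(grid_dims, dtype=bool)
    m[xs[0] : xs[1], ys[0] : ys[1], zs[0] : zs[1]] = True
    return m


def default_effects(grid_dims: tuple[int, int, int] = (24, 24, 16)) -> EffectSpec:
    """Ground truth mirroring the qualitative target pattern.

    A bilateral dorsolateral-occipital-like ROI carries a negative
    diagnosis-by-sex interaction on homotopic coupling (NT-F highest,
    ASD-F lowest), and a midline ROI carries main diagnosis (ASD < NT)
    and sex (M < F) effects.
    """
    nx, ny, nz = grid_dims
    mask = default_mask(grid_dims)
    # lateral posterior box, mirrored to the other hemisphere
    lat = _box(
        grid_dims,
        (2, max(3, nx // 4)),
        (ny - max(6, ny // 3), ny - 2),
        (nz // 3, nz - nz // 3),
    )
    dlo = (lat | lat[::-1]) & mask
    mid = (
        _box(
            grid_dims,
            (nx // 2 - 3, nx // 2 + 3),
            (3, 3 + ny // 4),
            (nz // 3, nz - nz // 3),
        )
        & mask
    )
    seed = (
        _box(
            grid_dims,
            (nx // 2 - 2, nx // 2 + 2),
            (ny - 3 - ny // 6, ny - 3),
            (nz // 3, nz // 3 + 3),
        )
        & mask
    )
    return EffectSpec(
        rois={"dlo": dlo, "midline": mid, "seed": seed},
        homotopic=(
            ChannelEffect("dlo", beta_dx=0.02, beta_sex=0.10, beta_int=-0.30),
            ChannelEffect("midline", beta_dx=-0.15, beta_sex=0.12),
        ),
    )


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(
    spec: CohortSpec, sites: Sequence[SiteSpec] | None = None
) -> pd.DataFrame:
    """Generate the subject phenotype table for a cohort specification.

    Ages are uniform over ``age_range``; FIQ is normal with the
    diagnosis-group mean; the target mean FD of each subject is drawn from a
    right-skewed (gamma) distribution with a small positive shift in the
    clinical group, plus the per-site motion offset.
    """
    if sites is None:
        sites = default_sites(spec.n_sites)
    if len(sites) != spec.n_sites:
        raise ValueError("need one SiteSpec per site")
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    sid = 0
    for s, (cells, site) in enumerate(zip(spec.cell_sizes, sites)):
        for (dx, sex), n_cell in zip(CELL_ORDER, cells):
            for _ in range(int(n_cell)):
                age = rng.uniform(*spec.age_range)
                fiq = rng.normal(spec.fiq_mean_by_group[dx], spec.fiq_sd)
                mfd = rng.gamma(4.0, 0.0275) + (0.02 if dx == "ASD" else 0.0)
                mfd = float(np.clip(mfd + site.motion_shift, 0.02, 0.35))
                rows.append(
                    {
                        "subject_id": f"sub-{sid:04d}",
                        "site": f"site{s:02d}",
                        "dx": dx,
                        "sex": sex,
                        "age": age,
                        "fiq": fiq,
                        "target_mfd": mfd,
                    }
                )
                sid += 1
    table = pd.DataFrame(rows)
    for col in ("ados_css", "ados_sa", "ados_rrb", "ados_module"):
        table[col] = np.nan
    return table


# ---------------------------------------------------------------------------
# motion


def generate_motion(
    spec: CohortSpec, subject: Mapping, rng: np.random.Generator
) -> np.ndarray:
    """Six-parameter rigid-body motion trace as a bounded random walk.

    Returns a (T, 6) array of 3 translations (mm) and 3 rotations (rad)
    whose realized mean framewise displacement (Power convention, 50 mm
    head radius) matches the subject's ``target_mfd``; a zero target gives
    a constant (all-zero) trace.
    """
    T = spec.n_timepoints
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    target = float(subject["target_mfd"])
    if target < 0:
        raise ValueError("target mean FD must be non-negative")
    if target == 0.0:
        return np.zeros((T, 6))
    steps = rng.standard_normal((T - 1, 6))
    steps[:, 3:] /= 50.0  # rotations contribute via the 50 mm lever arm
    fd_raw = np.abs(steps[:, :3]).sum(axis=1) + 50.0 * np.abs(steps[:, 3:]).sum(axis=1)
    steps *= target / fd_raw.mean()
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    # fold the walk back into a physical range (triangle wrap); the bound is
    # wide enough that folding is rare and the realized mFD stays on target
    bounds = np.array([3.0, 3.0, 3.0, 0.06, 0.06, 0.06])
    params = bounds - np.abs(np.mod(params + bounds, 4 * bounds) - 2 * bounds)
    return params


# ---------------------------------------------------------------------------
# BOLD


def _bandlimited(
    rng: np.random.Generator, n: int, T: int, tr: float, band: tuple[float, float]
) -> np.ndarray:
    """n unit-variance time series with support restricted to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(rng.standard_normal((n, T)), axis=-1)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=T, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar1(rng: np.random.Generator, n: int, T: int, phi: float) -> np.ndarray:
    """n AR(1) series with unit marginal variance."""
    e = rng.standard_normal((n, T + 25))
    x = np.empty_like(e)
    x[:, 0] = e[:, 0]
    for t in range(1, e.shape[1]):
        x[:, t] = phi * x[:, t - 1] + np.sqrt(1 - phi**2) * e[:, t]
    return x[:, 25:]


def _channel_map(
    base: float,
    channel: Sequence[ChannelEffect],
    rois: Mapping[str, np.ndarray],
    mask: np.ndarray,
    dx: int,
    sex: int,
) -> np.ndarray:
    out = np.full(mask.shape, float(base))
    for eff in channel:
        roi = rois[eff.roi]
        if not np.all(mask[roi]):
            raise ValueError(f"ROI {eff.roi!r} extends outside the brain mask")
        out[roi] += eff.shift(dx, sex)
    return out


def generate_bold(
    subject: Mapping,
    spec: CohortSpec,
    effects: EffectSpec,
    site: SiteSpec,
    rng: np.random.Generator,
    motion: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> BoldImage:
    """Generate one subject's 4D BOLD volume from the latent-signal model.

    The in-band part of every voxel mixes the mirror-pair, regional, seed
    and hub latents according to the subject's coupling maps; the remaining
    variance is broadband AR(1) noise. A motion-locked global nuisance
    component (scaled FD trace) is added when a motion trace is supplied.
    """
    if mask is None:
        mask = default_mask(spec.grid_dims)
    T = spec.n_timepoints
    dx = 1 if subject["dx"] == "ASD" else 0
    sex = 1 if subject["sex"] == "F" else 0

    c_map = _channel_map(effects.base_coupling, effects.homotopic, effects.rois, mask, dx, sex)
    r_map = _channel_map(0.0, effects.regional, effects.rois, mask, dx, sex)
    a_map = _channel_map(0.0, effects.seed, effects.rois, mask, dx, sex)
    h_map = _channel_map(0.0, effects.hub, effects.rois, mask, dx, sex)
    f_map = _channel_map(effects.base_inband, effects.inband, effects.rois, mask, dx, sex)
    for name, m in (("coupling", c_map), ("regional", r_map), ("seed", a_map),
                    ("hub", h_map), ("in-band fraction", f_map)):
        vals = m[mask]
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError(f"{name} parameter leaves [0, 1] after effect injection")

    if effects.seed_roi is not None and effects.seed_roi in effects.rois:
        a_map[effects.rois[effects.seed_roi]] = effects.seed_self_share
    # the seed/hub/regional compartments claim their variance first; the
    # pair coupling yields where the budget would otherwise be exceeded
    c_map = np.minimum(c_map, 1.0 - a_map - r_map - h_map)

    # site batch + between-subject variation on the Fisher-z coupling scale;
    # the effective pair correlation may go negative (anti-correlated
    # homotopic pairs), carried by a signed loading on one hemisphere
    eta = rng.normal(0.0, effects.subject_sd)
    z = np.arctanh(np.clip(c_map, 0.0, 1.0 - 1e-12))
    c_eff = np.tanh(z + site.gamma + site.delta * eta)
    budget = 1.0 - a_map - r_map - h_map
    c_eff = np.clip(c_eff, -budget, budget)

    resid_share = np.clip(1.0 - np.abs(c_eff) - r_map - a_map - h_map, 0.0, None)

    nx = spec.grid_dims[0]
    vox = np.argwhere(mask)
    n_vox = len(vox)
    flat_index = np.full(mask.shape, -1, dtype=int)
    flat_index[mask] = np.arange(n_vox)
    mirror_ix = flat_index[nx - 1 - vox[:, 0], vox[:, 1], vox[:, 2]]
    if np.any(mirror_ix < 0):
        raise ValueError("mask is not mirror-symmetric")

    # one latent per unordered mirror pair
    pair_key = np.minimum(np.arange(n_vox), mirror_ix)
    _, pair_id = np.unique(pair_key, return_inverse=True)
    n_pairs = pair_id.max() + 1
    s_pair = _bandlimited(rng, n_pairs, T, spec.tr, effects.band)[pair_id]

    roi_names = sorted(effects.rois)
    s_region = {}
    for name in roi_names:
        s_region[name] = _bandlimited(rng, 2, T, spec.tr, effects.band)
    s_seed = _bandlimited(rng, 1, T, spec.tr, effects.band)[0]
    s_hub = _bandlimited(rng, 1, T, spec.tr, effects.band)[0]
    s_priv = _bandlimited(rng, n_vox, T, spec.tr, effects.band)
    noise = _ar1(rng, n_vox, T, effects.ar_coef)

    cm, rm, am, hm, fm, pm = (
        c_eff[mask][:, None],
        r_map[mask][:, None],
        a_map[mask][:, None],
        h_map[mask][:, None],
        f_map[mask][:, None],
        resid_share[mask][:, None],
    )
    # signed pair loading: the right-hemisphere member of each pair carries
    # the sign, so corr(x_L, x_R) equals the (possibly negative) coupling
    right = (vox[:, 0] >= nx // 2)[:, None]
    pair_load = np.sqrt(np.abs(cm)) * np.where(right & (cm < 0), -1.0, 1.0)
    u = (
        pair_load * s_pair
        + np.sqrt(am) * s_seed
        + np.sqrt(hm) * s_hub
        + np.sqrt(pm) * s_priv
    )
    if np.any(rm > 0):
        left = vox[:, 0] < nx // 2
        reg = np.zeros((n_vox, T))
        for name in roi_names:
            in_roi = effects.rois[name][mask]
            if not np.any(in_roi):
                continue
            hemi = np.where(left, 0, 1)
            reg[in_roi] = s_region[name][hemi[in_roi]]
        u = u + np.sqrt(rm) * reg
    series = np.sqrt(fm) * u + np.sqrt(1.0 - fm) * noise

    if motion is not None and effects.motion_amp > 0:
        from .qc import framewise_displacement

        fd = framewise_displacement(motion)
        fd_t = np.concatenate([[fd[0] if len(fd) else 0.0], fd])
        sd = fd_t.std()
        if sd > 0:
            series = series + effects.motion_amp * (fd_t - fd_t.mean()) / sd

    data = np.zeros(spec.grid_dims + (T,))
    data[mask] = series
    return BoldImage(data=data, mask=mask, voxel_size=spec.voxel_size, tr=spec.tr)


def simulate_cluster_means(
    table: pd.DataFrame,
    rng: np.random.Generator,
    beta_dx: float = 0.0,
    beta_sex: float = 0.0,
    beta_int: float = 0.0,
    baseline: float = 0.25,
    noise_sd: float = 0.1,
    age_slope: float = 0.005,
    mfd_slope: float = -0.3,
) -> np.ndarray:
    """Per-subject cluster-mean metric values from a linear ground truth.

    A light-weight stand-in for extracting cluster means from full volumes:
    the same diagnosis/sex/interaction parameterization as the BOLD
    generator, plus weak age and motion coupling, at the between-subject
    noise level the volumetric generator produces (subject coupling sd
    plus measurement noise). Used for replication-classifier and
    behaviour-model simulations where volumes would be gratuitous.
    """
    dx = (table["dx"].to_numpy() == "ASD").astype(float)
    sex = (table["sex"].to_numpy() == "F").astype(float)
    age = table["age"].to_numpy(dtype=float)
    mfd = table["mfd" if "mfd" in table else "target_mfd"].to_numpy(dtype=float)
    mu = (
        baseline
        + beta_dx * dx
        + beta_sex * sex
        + beta_int * dx * sex
        + age_slope * (age - age.mean())
        + mfd_slope * (mfd - mfd.mean())
    )
    return mu + rng.normal(0.0, noise_sd, len(table))


# ---------------------------------------------------------------------------
# behaviour


def generate_behavior(
    table: pd.DataFrame,
    roi_signal: np.ndarray,
    spec: BehaviorSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill ADOS-style scores for the clinical (ASD) rows only.

    The social-affect score is generated so that its within-sex correlation
    with ``roi_signal`` (one value per subject, e.g. a cluster-mean metric)
    matches the sex-specific targets; the total severity and RRB scores are
    noise within their instrument ranges. Scores are integer, range-clipped;
    neurotypical rows keep missing values.
    """
    table = table.copy()
    roi_signal = np.asarray(roi_signal, dtype=float)
    if len(roi_signal) != len(table):
        raise ValueError("roi_signal must align with the phenotype table")
    asd = table["dx"].to_numpy() == "ASD"
    modules = np.array(sorted(spec.module_probs))
    probs = np.array([spec.module_probs[m] for m in modules])
    for sex, r in (("M", spec.r_male), ("F", spec.r_female)):
        sel = asd & (table["sex"].to_numpy() == sex)
        n = int(sel.sum())
        if n == 0:
            if r != 0:
                raise ValueError(f"target correlation for empty stratum {sex!r}")
            continue
        sig = roi_signal[sel]
        sd = sig.std()
        zsig = (sig - sig.mean()) / sd if sd > 0 else np.zeros(n)
        latent = r * zsig + np.sqrt(1 - r**2) * rng.standard_normal(n)
        mu, ssd = spec.score_moments["ados_sa"]
        lo, hi = spec.score_ranges["ados_sa"]
        table.loc[sel, "ados_sa"] = np.clip(np.round(mu + ssd * latent), lo, hi)
    n_asd = int(asd.sum())
    for score in ("ados_css", "ados_rrb"):
        mu, ssd = spec.score_moments[score]
        lo, hi = spec.score_ranges[score]
        vals = np.clip(np.round(rng.normal(mu, ssd, n_asd)), lo, hi)
        table.loc[asd, score] = vals
    table.loc[asd, "ados_module"] = rng.choice(modules, size=n_asd, p=probs)
    return table
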