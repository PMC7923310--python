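"""The five voxel-wise intrinsic-brain-function metrics.

* ``seed_ifc`` -- Pearson correlation of every voxel with the mean series of
  a seed region (e.g. posterior cingulate), Fisher-z transformed.
* ``vmhc`` -- voxel-mirrored homotopic connectivity: correlation of each
  voxel with its left-right mirror on a symmetric grid, Fisher-z.
* ``reho`` -- regional homogeneity: Kendall's coefficient of concordance W
  of a voxel with its neighbourhood (27/19/7-connectivity).
* ``degree_centrality`` -- count (or sum) of whole-brain positive
  correlations above a threshold.
* ``falff`` -- fractional amplitude of low-frequency fluctuations: Fourier
  amplitude in 0.01-0.1 Hz over total amplitude, computed on series that
  were nuisance-regressed but NOT band-passed.

Correlation-based maps are reported as Fisher z (r clipped at 1 - 1e-7);
ReHo/DC/fALFF maps can be z-scored within the mask so the group model sees
scale-free inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import BoldImage

__all__ = [
    "MetricMap",
    "R_CLIP",
    "fisher_z",
    "seed_ifc",
    "vmhc",
    "kendall_w",
    "reho",
    "degree_centrality",
    "falff",
    "standardize_map",
    "compute_metric",
    "METRICS",
]

R_CLIP = 1.0 - 1e-7

NEIGHBORHOOD_OFFSETS = {
    7: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ],
}


@dataclass
class MetricMap:
    """One subject-level 3D metric map."""

    name: str
    data: np.ndarray
    mask: np.ndarray
    standardization: str = "raw"  # fisher_z | zscore | raw
    flags: np.ndarray | None = None  # voxels with degenerate input


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _standardized_series(bold: BoldImage) -> tuple[np.ndarray, np.ndarray]:
    """In-mask series demeaned and unit-normed; returns (X, zero_var flags)."""
    X = bold.in_mask().astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(X, axis=1)
    zero = norm == 0
    norm[zero] = 1.0
    return X / norm[:, None], zero


def seed_ifc(bold: BoldImage, seed_mask: np.ndarray) -> MetricMap:
    """Seed-based intrinsic functional connectivity map (Fisher z)."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if not np.all(bold.mask[seed_mask]):
        raise ValueError("seed mask extends outside the brain mask")
    seed = bold.data[seed_mask].mean(axis=0)
    seed = seed - seed.mean()
    norm = np.linalg.norm(seed)
    if norm == 0:
        raise ValueError("seed mean series has zero variance")
    seed /= norm
    X, zero = _standardized_series(bold)
    r = X @ seed
    r[zero] = 0.0
    data = np.zeros(bold.mask.shape)
    data[bold.mask] = fisher_z(r)
    flags = np.zeros_like(bold.mask)
    flags[bold.mask] = zero
    return MetricMap("pcc_ifc", data, bold.mask, "fisher_z", flags)


def vmhc(bold: BoldImage) -> MetricMap:
    """Voxel-mirrored homotopic connectivity (Fisher z), mirror about x.

    The map is exactly mirror-symmetric by construction. Voxels whose own
    or mirrored series has zero variance get 0 and are flagged.
    """
    nx = bold.mask.shape[0]
    if nx % 2 != 0:
        raise ValueError("grid must have an even first dimension")
    if not np.array_equal(bold.mask, bold.mask[::-1]):
        raise ValueError("mask is not mirror-symmetric")
    X, zero = _standardized_series(bold)
    vox = np.argwhere(bold.mask)
    flat = np.full(bold.mask.shape, -1, dtype=int)
    flat[bold.mask] = np.arange(len(vox))
    mirror = flat[nx - 1 - vox[:, 0], vox[:, 1], vox[:, 2]]
    r = np.einsum("ij,ij->i", X, X[mirror])
    bad = zero | zero[mirror]
    z = fisher_z(r)
    z[bad] = 0.0
    data = np.zeros(bold.mask.shape)
    data[bold.mask] = z
    flags = np.zeros_like(bold.mask)
    flags[bold.mask] = bad
    return MetricMap("vmhc", data, bold.mask, "fisher_z", flags)


def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series of length n.

    Ranks use midranks; the standard tie-correction term enters the
    denominator: W = 12*S / (K^2*(n^3 - n) - K*sum_j T_j) with
    T_j = sum_groups (t^3 - t) for each series' tied groups.
    """
    X = np.asarray(series_set, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a (K, n) array")
    K, n = X.shape
    if K < 2 or n < 3:
        raise ValueError("need K >= 2 series of length n >= 3")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    ties = 0.0
    for j in range(K):
        _, counts = np.unique(X[j], return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = K**2 * (n**3 - n) - K * ties
    if denom <= 0:
        raise ValueError("tie correction yields a zero denominator")
    return 12.0 * S / denom


def _rank_4d(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel temporal midranks for in-mask voxels (0 elsewhere)."""
    X = data[mask]
    order = np.argsort(X, axis=1, kind="stable")
    T = X.shape[1]
    ranks = np.empty_like(X)
    rng_idx = np.arange(1.0, T + 1.0)
    np.put_along_axis(ranks, order, np.broadcast_to(rng_idx, X.shape), axis=1)
    # midranks for ties
    has_ties = np.array([len(np.unique(row)) < T for row in X])
    for i in np.where(has_ties)[0]:
        ranks[i] = stats.rankdata(X[i])
    out = np.zeros(mask.shape + (T,))
    out[mask] = ranks
    return out


def reho(bold: BoldImage, neighborhood: int = 27, min_neighbors: int = 4) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    Edge voxels are computed over whatever in-mask neighbours exist
    (K = available + 1) and voxels with fewer than ``min_neighbors``
    neighbours are set to 0 and flagged.
    """
    if neighborhood not in NEIGHBORHOOD_OFFSETS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    mask = bold.mask
    T = bold.n_timepoints
    ranks = _rank_4d(bold.data, mask)
    # tie correction per voxel
    tie_term = np.zeros(mask.shape)
    for idx in np.argwhere(mask):
        _, counts = np.unique(bold.data[tuple(idx)], return_counts=True)
        if len(counts) < T:
            tie_term[tuple(idx)] = float((counts**3 - counts).sum())
    rank_sum = np.zeros(mask.shape + (T,))
    k_count = np.zeros(mask.shape)
    ties_sum = np.zeros(mask.shape)
    for dx, dy, dz in NEIGHBORHOOD_OFFSETS[neighborhood]:
        shifted = np.roll(ranks, (dx, dy, dz), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (dx, dy, dz), axis=(0, 1, 2)).astype(float)
        # rolled-in edges are masked out via the rolled mask of valid origins
        valid = _roll_valid(mask.shape, dx, dy, dz) & (shifted_mask > 0)
        rank_sum += shifted * valid[..., None]
        ties_sum += np.roll(tie_term, (dx, dy, dz), axis=(0, 1, 2)) * valid
        k_count += valid
    W = np.zeros(mask.shape)
    flags = np.zeros_like(mask)
    K = k_count
    with np.errstate(invalid="ignore", divide="ignore"):
        S = ((rank_sum - rank_sum.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
        denom = K**2 * (T**3 - T) - K * ties_sum
        W = np.where(denom > 0, 12.0 * S / denom, 0.0)
    W[~mask] = 0.0
    too_few = mask & (K < (min_neighbors + 1))
    W[too_few] = 0.0
    flags |= too_few
    return MetricMap("reho", W, mask, "raw", flags)


def _roll_valid(shape, dx, dy, dz) -> np.ndarray:
    """Mask of positions where np.roll by (dx,dy,dz) did not wrap around."""
    valid = np.ones(shape, dtype=bool)
    for axis, d in enumerate((dx, dy, dz)):
        idx = [slice(None)] * 3
        if d > 0:
            idx[axis] = slice(0, d)
            valid[tuple(idx)] = False
        elif d < 0:
            idx[axis] = slice(d, None)
            valid[tuple(idx)] = False
    return valid


def degree_centrality(
    bold: BoldImage,
    r_threshold: float = 0.25,
    binarize: bool = True,
    block: int = 1024,
) -> MetricMap:
    """Voxel degree: positive whole-brain correlations above ``r_threshold``.

    Binarized by default (count of connections); ``binarize=False`` sums
    the suprathreshold correlation weights. Self-connections are excluded.
    """
    if not (abs(r_threshold) < 1):
        raise ValueError("|r_threshold| must be < 1")
    X, zero = _standardized_series(bold)
    V = X.shape[0]
    if V < 2:
        raise ValueError("need at least 2 in-mask voxels")
    deg = np.zeros(V)
    for start in range(0, V, block):
        sub = X[start : start + block]
        r = sub @ X.T
        for i in range(sub.shape[0]):
            r[i, start + i] = 0.0  # exclude self
        above = (r > r_threshold) & (r > 0)
        deg[start : start + block] = (
            above.sum(axis=1) if binarize else np.where(above, r, 0.0).sum(axis=1)
        )
    deg[zero] = 0.0
    data = np.zeros(bold.mask.shape)
    data[bold.mask] = deg
    flags = np.zeros_like(bold.mask)
    flags[bold.mask] = zero
    return MetricMap("dc", data, bold.mask, "raw", flags)


def falff(bold: BoldImage, band: tuple[float, float] = (0.01, 0.1)) -> MetricMap:
    """Fractional ALFF: in-band Fourier amplitude over total amplitude.

    The input must be the nuisance-regressed but NOT band-passed series.
    The DC term is excluded from both sums; values lie in [0, 1].
    """
    low, high = band
    nyq = 1.0 / (2.0 * bold.tr)
    if not (0 < low < high <= nyq + 1e-12):
        raise ValueError("band must lie within (0, Nyquist]")
    X = bold.in_mask()
    X = X - X.mean(axis=1, keepdims=True)
    T = bold.n_timepoints
    freqs = np.fft.rfftfreq(T, d=bold.tr)
    amp = np.abs(np.fft.rfft(X, axis=-1))
    pos = freqs > 0
    in_band = pos & (freqs >= low) & (freqs <= high)
    total = amp[:, pos].sum(axis=1)
    zero = total == 0
    total[zero] = 1.0
    frac = amp[:, in_band].sum(axis=1) / total
    frac[zero] = 0.0
    data = np.zeros(bold.mask.shape)
    data[bold.mask] = frac
    flags = np.zeros_like(bold.mask)
    flags[bold.mask] = zero
    return MetricMap("falff", data, bold.mask, "raw", flags)


def standardize_map(metric: MetricMap) -> MetricMap:
    """Z-score ReHo/DC/fALFF maps within the mask; keep Fisher-z maps as-is."""
    if metric.standardization == "fisher_z":
        return metric
    vals = metric.data[metric.mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant map")
    data = np.zeros_like(metric.data)
    data[metric.mask] = (vals - vals.mean()) / sd
    return replace(metric, data=data, standardization="zscore")


def compute_metric(
    name: str,
    bold_filtered: BoldImage,
    bold_unfiltered: BoldImage | None = None,
    seed_mask: np.ndarray | None = None,
    standardize: bool = True,
    **kwargs,
) -> MetricMap:
    """Dispatch a metric by name on the appropriately filtered input."""
    if name == "pcc_ifc":
        if seed_mask is None:
            raise ValueError("pcc_ifc requires a seed mask")
        m = seed_ifc(bold_filtered, seed_mask)
    elif name == "vmhc":
        m = vmhc(bold_filtered)
    elif name == "reho":
        m = reho(bold_filtered, **kwargs)
    elif name == "dc":
        m = degree_centrality(bold_filtered, **kwargs)
    elif name == "falff":
        if bold_unfiltered is None:
            raise ValueError("falff requires the unfiltered series")
        m = falff(bold_unfiltered, **kwargs)
    else:
        raise ValueError(f"unknown metric {name!r}")
    return standardize_map(m) if standardize and m.standardization == "raw" else m


METRICS = ("pcc_ifc", "vmhc", "reho", "dc", "falff")
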