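"""Cluster-level effect sizes, robustness/replicability classification,
leave-one-site-out stability and cognitive-ontology overlap.

For every significant cluster, per-subject cluster means enter a full
regression model (diagnosis, sex, diagnosis-by-sex, age, mean FD). Each
term's partial eta squared is computed from type-III sums of squares
(effect coding, so main effects are well defined with unbalanced cells),
with a confidence interval from noncentral-F inversion. A discovery
finding counts as robust/replicable (R+) when the comparison analysis
shows the same covariate-adjusted contrast direction and a non-negligible
effect (partial eta squared >= 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectResult",
    "extract_cluster_means",
    "ClusterEffects",
    "full_model_effects",
    "eta_sq_from_f",
    "eta_sq_ci",
    "residualize",
    "classify_replication",
    "loso_stability",
    "ontology_overlap",
]

EFFECT_TERMS = ("dx", "sex", "dx_by_sex")


@dataclass
class EffectResult:
    """Effect size of one model term on one cluster's mean signal."""

    term: str
    eta_sq: float
    ci: tuple[float, float]
    f: float
    df: tuple[int, int]
    direction: int  # sign of the adjusted contrast
    contrast: float  # adjusted-mean contrast value
    cell_means: dict[str, float]  # covariate-adjusted means of the 4 cells
    cluster_id: int | None = None
    classification: str | None = None


def extract_cluster_means(maps: np.ndarray, cluster_cols: np.ndarray) -> np.ndarray:
    """Mean over cluster voxels per subject.

    ``maps`` is the (N, V) in-mask matrix; ``cluster_cols`` a boolean (V,)
    selector (or integer indices) of the cluster's voxels.
    """
    cluster_cols = np.asarray(cluster_cols)
    if cluster_cols.dtype == bool and not cluster_cols.any():
        raise ValueError("empty cluster mask")
    sub = np.asarray(maps, dtype=float)[:, cluster_cols]
    if sub.shape[1] == 0:
        raise ValueError("empty cluster mask")
    return sub.mean(axis=1)


def _effect_design(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Effect-coded full design: intercept, dx, sex, dx*sex, centred covs."""
    dx = np.where(table["dx"].to_numpy() == "ASD", 0.5, -0.5)
    sex = np.where(table["sex"].to_numpy() == "F", 0.5, -0.5)
    age = table["age"].to_numpy(dtype=float)
    mfd = table["mfd"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table)), dx, sex, dx * sex, age - age.mean(), mfd - mfd.mean()]
    )
    return X, ["intercept", "dx", "sex", "dx_by_sex", "age", "mfd"]


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def eta_sq_from_f(f: float, df1: int, df2: int) -> float:
    """Algebraic identity: eta_p^2 = F*df1 / (F*df1 + df2)."""
    return f * df1 / (f * df1 + df2)


def eta_sq_ci(
    f: float, df1: int, df2: int, level: float = 0.90
) -> tuple[float, float]:
    """Two-sided noncentral-F confidence interval for partial eta squared."""
    alpha = 1.0 - level
    if not np.isfinite(f) or f < 0:
        return (0.0, 1.0)

    def _lambda_for(prob: float) -> float:
        # find nc with ncf.cdf(f; df1, df2, nc) == prob
        if stats.ncf.cdf(f, df1, df2, 0.0) < prob:
            return 0.0
        hi = 10.0
        while stats.ncf.cdf(f, df1, df2, hi) > prob:
            hi *= 2.0
            if hi > 1e7:
                return hi
        return float(
            optimize.brentq(
                lambda nc: stats.ncf.cdf(f, df1, df2, nc) - prob, 0.0, hi
            )
        )

    lam_lo = _lambda_for(1.0 - alpha / 2.0)
    lam_hi = _lambda_for(alpha / 2.0)
    conv = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (conv(lam_lo), conv(lam_hi))


class ClusterEffects:
    """Full model for one cluster's per-subject means.

    ``ClusterEffects(means, table).fit()`` returns the per-term
    :class:`EffectResult` objects (type-III partial eta squared, CI,
    adjusted cell means and contrast direction).
    """

    def __init__(self, means, table: pd.DataFrame, ci_level: float = 0.90):
        self.y = np.asarray(means, dtype=float)
        if len(self.y) != len(table):
            raise ValueError("means must align with the table")
        self.table = table
        self.ci_level = ci_level
        self.X, self.names = _effect_design(table)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient effect design")
        if len(self.y) <= self.X.shape[1]:
            raise ValueError("need more subjects than parameters")

    def fit(self) -> dict[str, EffectResult]:
        X, y = self.X, self.y
        n, p = X.shape
        df2 = n - p
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse_full = _sse(X, y)
        b = dict(zip(self.names, beta))
        cell_means = {
            "NT_M": b["intercept"] - 0.5 * b["dx"] - 0.5 * b["sex"] + 0.25 * b["dx_by_sex"],
            "NT_F": b["intercept"] - 0.5 * b["dx"] + 0.5 * b["sex"] - 0.25 * b["dx_by_sex"],
            "ASD_M": b["intercept"] + 0.5 * b["dx"] - 0.5 * b["sex"] - 0.25 * b["dx_by_sex"],
            "ASD_F": b["intercept"] + 0.5 * b["dx"] + 0.5 * b["sex"] + 0.25 * b["dx_by_sex"],
        }
        contrasts = {
            "dx": (cell_means["ASD_M"] + cell_means["ASD_F"]) / 2
            - (cell_means["NT_M"] + cell_means["NT_F"]) / 2,
            "sex": (cell_means["NT_F"] + cell_means["ASD_F"]) / 2
            - (cell_means["NT_M"] + cell_means["ASD_M"]) / 2,
            "dx_by_sex": (cell_means["ASD_F"] - cell_means["NT_F"])
            - (cell_means["ASD_M"] - cell_means["NT_M"]),
        }
        out = {}
        for term in EFFECT_TERMS:
            j = self.names.index(term)
            sse_red = _sse(np.delete(X, j, axis=1), y)
            ss_term = max(sse_red - sse_full, 0.0)
            if sse_full <= 0:
                eta, fstat = 1.0, np.inf
                ci = (1.0, 1.0)
            else:
                eta = ss_term / (ss_term + sse_full)
                fstat = (ss_term / 1.0) / (sse_full / df2)
                ci = eta_sq_ci(fstat, 1, df2, self.ci_level)
            out[term] = EffectResult(
                term=term,
                eta_sq=float(eta),
                ci=ci,
                f=float(fstat),
                df=(1, df2),
                direction=int(np.sign(contrasts[term])) or 1,
                contrast=float(contrasts[term]),
                cell_means={k: float(v) for k, v in cell_means.items()},
            )
        return out


def full_model_effects(means, table: pd.DataFrame, **kwargs) -> dict[str, EffectResult]:
    """Functional wrapper over :class:`ClusterEffects`."""
    return ClusterEffects(means, table, **kwargs).fit()


def residualize(
    means,
    table: pd.DataFrame,
    terms: tuple[str, ...] = ("dx", "sex", "dx_by_sex", "age", "mfd"),
) -> np.ndarray:
    """OLS residuals of cluster means against the chosen terms (+intercept).

    The full-term set matches the robustness model; ``("age", "mfd")``
    reproduces the covariate-only residuals used for group-mean plots.
    """
    y = np.asarray(means, dtype=float)
    X_full, names = _effect_design(table)
    keep = [0] + [names.index(t) for t in terms]
    X = X_full[:, keep]
    if len(y) <= X.shape[1]:
        raise ValueError("need more subjects than parameters")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def classify_replication(
    discovery: EffectResult,
    replication: EffectResult,
    threshold: float = 0.01,
) -> str:
    """R+ iff same adjusted-contrast direction and eta_p^2 >= threshold."""
    if discovery.term != replication.term:
        raise ValueError("term mismatch between discovery and replication")
    same_dir = discovery.direction == replication.direction
    return "R+" if (same_dir and replication.eta_sq >= threshold) else "R-"


def loso_stability(means, table: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-site-out adjusted cell means and contrast-sign consistency.

    Returns one row per left-out site with the four adjusted cell means and
    per-term contrast signs, plus a ``sign_consistent`` summary row giving
    the fraction of leave-outs preserving the full-sample sign.
    """
    sites = sorted(table["site"].unique())
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    y = np.asarray(means, dtype=float)
    full = ClusterEffects(y, table).fit()
    rows = []
    for site in sites:
        keep = (table["site"] != site).to_numpy()
        sub = ClusterEffects(y[keep], table[keep].reset_index(drop=True)).fit()
        row = {"left_out": site}
        for cell, v in sub["dx"].cell_means.items():
            row[cell] = v
        for term in EFFECT_TERMS:
            row[f"sign_{term}"] = sub[term].direction
        rows.append(row)
    out = pd.DataFrame(rows)
    for term in EFFECT_TERMS:
        out.attrs[f"consistency_{term}"] = float(
            (out[f"sign_{term}"] == full[term].direction).mean()
        )
    return out


def plot_cell_means(
    effect: EffectResult,
    means=None,
    table: pd.DataFrame | None = None,
    ax=None,
):
    """Bar plot of the four covariate-adjusted cell means for one cluster.

    When ``means`` and ``table`` are given, covariate-residualized
    per-subject values are scattered over the bars.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    order = ["NT_M", "NT_F", "ASD_M", "ASD_F"]
    vals = [effect.cell_means[c] for c in order]
    ax.bar(range(4), vals, color=["#4878a8", "#a8486f", "#4878a8", "#a8486f"],
           alpha=0.7)
    if means is not None and table is not None:
        resid = residualize(means, table, terms=("age", "mfd"))
        cells = (
            table["dx"].astype(str) + "_" + table["sex"].astype(str)
        ).to_numpy()
        rng = np.random.default_rng(0)
        for i, c in enumerate(order):
            y = resid[cells == c] + np.mean(means) - np.mean(resid)
            ax.scatter(i + rng.uniform(-0.15, 0.15, len(y)), y, s=6,
                       color="0.3", alpha=0.5)
    ax.set_xticks(range(4), order)
    ax.set_ylabel("adjusted cluster mean")
    ax.set_title(f"{effect.term} (eta_p^2 = {effect.eta_sq:.3f})")
    return ax


def ontology_overlap(
    cluster_mask: np.ndarray,
    prob_maps: np.ndarray,
    p_thresh: float = 1e-5,
) -> np.ndarray:
    """Percent overlap of a cluster with thresholded probability maps.

    ``prob_maps`` has shape (n_maps, nx, ny, nz); each map is binarized at
    ``p_thresh`` and the percentage of cluster voxels inside the binary
    map is returned per map.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    n_clust = int(cluster_mask.sum())
    if n_clust == 0:
        raise ValueError("empty cluster")
    prob_maps = np.asarray(prob_maps, dtype=float)
    binary = prob_maps > p_thresh
    inter = binary[:, cluster_mask].sum(axis=1)
    return 100.0 * inter / n_clust
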