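"""Parametric empirical-Bayes ComBat harmonization of metric matrices.

Site (batch) effects on subjects x voxels metric matrices are modelled as
voxel-wise additive (gamma) and multiplicative (delta) terms on top of a
grand mean and protected covariate effects. Per-site, per-voxel estimates
are shrunk toward parametric priors -- normal for locations, inverse-gamma
for scales -- by iterated conditional modes, and the adjusted data restore
the covariate effects while removing the site location/scale.

The model is fitted and applied through a statsmodels-style pair:
``ComBat(data, sites, design).fit()`` returns :class:`ComBatResults`, whose
``transform`` method harmonizes the training data (or new data from the
same sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ComBat", "ComBatResults", "combat_fit", "combat_apply", "harmonize"]


@dataclass
class ComBatResults:
    """Fitted ComBat parameters (one row per site, one column per voxel)."""

    sites: list
    alpha_hat: np.ndarray          # (V,) grand effect
    beta_hat: np.ndarray           # (p, V) covariate effects
    gamma_star: np.ndarray         # (S, V) EB-shrunk site locations
    delta_star: np.ndarray         # (S, V) EB-shrunk site scales (sd units)
    pooled_var: np.ndarray         # (V,)
    gamma_bar: np.ndarray          # (S,) location prior means
    tau_sq: np.ndarray             # (S,) location prior variances
    a_prior: np.ndarray            # (S,) inverse-gamma shape
    b_prior: np.ndarray            # (S,) inverse-gamma rate
    kept: np.ndarray = field(repr=False, default=None)  # (V,) non-degenerate voxels
    n_iter: list[int] = field(default_factory=list)

    def transform(
        self, data: np.ndarray, sites: np.ndarray, design: np.ndarray | None = None
    ) -> np.ndarray:
        """Remove site location/scale; covariate effects are restored."""
        data = np.asarray(data, dtype=float)
        sites = np.asarray(sites)
        unknown = set(np.unique(sites)) - set(self.sites)
        if unknown:
            raise ValueError(f"unseen site labels: {sorted(map(str, unknown))}")
        stand_mean = self.alpha_hat[None, :].repeat(len(data), axis=0)
        if design is not None:
            design = np.asarray(design, dtype=float)
            stand_mean = stand_mean + design @ self.beta_hat
        sd = np.sqrt(self.pooled_var)[None, :]
        z = (data - stand_mean) / sd
        out = np.array(data, copy=True)
        for i, site in enumerate(self.sites):
            rows = sites == site
            if not rows.any():
                continue
            adj = (z[rows] - self.gamma_star[i]) / self.delta_star[i]
            out[np.ix_(rows, self.kept)] = (
                adj * sd + stand_mean[rows]
            )[:, self.kept]
        return out


class ComBat:
    """Location/scale batch-effect model for a subjects x voxels matrix.

    Parameters
    ----------
    data : (N, V) array
        Metric values, one row per subject.
    sites : (N,) array-like
        Batch labels.
    design : (N, p) array, optional
        Covariates to protect (no intercept, no site indicators) --
        typically diagnosis, sex, their interaction, age and mean FD.
    """

    def __init__(self, data, sites, design=None):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (subjects, voxels)")
        self.sites_labels = np.asarray(sites)
        if len(self.sites_labels) != len(self.data):
            raise ValueError("sites must align with data rows")
        self.site_list = sorted(set(self.sites_labels.tolist()))
        counts = pd.Series(self.sites_labels).value_counts()
        if (counts < 2).any():
            raise ValueError("every site needs at least 2 subjects")
        self.design = None if design is None else np.asarray(design, dtype=float)
        if self.design is not None:
            if len(self.design) != len(self.data):
                raise ValueError("design must align with data rows")
            if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
                raise ValueError("covariate design is rank deficient")

    def fit(self, conv: float = 1e-4, max_iter: int = 500) -> ComBatResults:
        Y = self.data
        N, V = Y.shape
        S = len(self.site_list)
        onehot = np.stack(
            [(self.sites_labels == s).astype(float) for s in self.site_list], axis=1
        )
        n_per = onehot.sum(axis=0)
        X = onehot if self.design is None else np.hstack([onehot, self.design])
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        site_int = B[:S]
        beta_hat = B[S:]
        alpha_hat = (n_per / N) @ site_int
        fitted = X @ B
        pooled_var = ((Y - fitted) ** 2).mean(axis=0)
        kept = pooled_var > 0
        safe_var = np.where(kept, pooled_var, 1.0)
        sd = np.sqrt(safe_var)

        stand_mean = alpha_hat[None, :] + (
            self.design @ beta_hat if self.design is not None else 0.0
        )
        Z = (Y - stand_mean) / sd

        if S == 1:
            # a single batch carries no identifiable site effect: identity
            return ComBatResults(
                sites=self.site_list,
                alpha_hat=alpha_hat,
                beta_hat=beta_hat,
                gamma_star=np.zeros((1, V)),
                delta_star=np.ones((1, V)),
                pooled_var=safe_var,
                gamma_bar=np.zeros(1),
                tau_sq=np.zeros(1),
                a_prior=np.full(1, np.inf),
                b_prior=np.full(1, np.inf),
                kept=kept,
                n_iter=[0],
            )

        gamma_hat = np.empty((S, V))
        delta_hat = np.empty((S, V))
        for i, s in enumerate(self.site_list):
            rows = self.sites_labels == s
            Zi = Z[rows]
            gamma_hat[i] = Zi.mean(axis=0)
            delta_hat[i] = Zi.var(axis=0, ddof=1)

        gamma_bar = gamma_hat[:, kept].mean(axis=1)
        tau_sq = gamma_hat[:, kept].var(axis=1, ddof=1)
        # inverse-gamma priors on delta^2 by method of moments
        d_bar = delta_hat[:, kept].mean(axis=1)
        d_var = delta_hat[:, kept].var(axis=1, ddof=1)
        a_prior = (2.0 * d_var + d_bar**2) / np.maximum(d_var, 1e-12)
        b_prior = (d_bar * d_var + d_bar**3) / np.maximum(d_var, 1e-12)

        gamma_star = np.zeros((S, V))
        delta_star = np.ones((S, V))
        n_iter = []
        for i, s in enumerate(self.site_list):
            rows = self.sites_labels == s
            Zi = Z[rows][:, kept]
            n_i = rows.sum()
            g = gamma_hat[i, kept].copy()
            d = delta_hat[i, kept].copy()
            it = 0
            while it < max_iter:
                g_new = (n_i * tau_sq[i] * gamma_hat[i, kept] + d * gamma_bar[i]) / (
                    n_i * tau_sq[i] + d
                )
                ssq = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (b_prior[i] + 0.5 * ssq) / (n_i / 2.0 + a_prior[i] - 1.0)
                change = max(
                    np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-8)),
                    np.max(np.abs(d_new - d) / np.maximum(np.abs(d), 1e-8)),
                )
                g, d = g_new, d_new
                it += 1
                if change < conv:
                    break
            gamma_star[i, kept] = g
            delta_star[i, kept] = np.sqrt(np.maximum(d, 1e-12))
            n_iter.append(it)

        return ComBatResults(
            sites=self.site_list,
            alpha_hat=alpha_hat,
            beta_hat=beta_hat,
            gamma_star=gamma_star,
            delta_star=delta_star,
            pooled_var=safe_var,
            gamma_bar=gamma_bar,
            tau_sq=tau_sq,
            a_prior=a_prior,
            b_prior=b_prior,
            kept=kept,
            n_iter=n_iter,
        )


def combat_fit(data, sites, design=None, **kwargs) -> ComBatResults:
    """Functional wrapper: fit the ComBat model."""
    return ComBat(data, sites, design).fit(**kwargs)


def combat_apply(
    data, fit: ComBatResults, sites, design=None
) -> np.ndarray:
    """Functional wrapper: apply a fitted ComBat adjustment."""
    return fit.transform(data, sites, design)


def harmonize(data, sites, design=None, **kwargs) -> np.ndarray:
    """Fit and apply in one step (the common pipeline call)."""
    fit = ComBat(data, sites, design).fit(**kwargs)
    return fit.transform(data, np.asarray(sites), design)
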