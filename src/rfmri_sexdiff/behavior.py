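"""Sex-differential brain-behaviour association within the clinical group.

A GLM on the ASD subjects relates the cluster-mean metric to sex, an ADOS
score, their interaction, and age/mean-FD covariates (optionally ADOS
module dummies). The interaction F tests whether the brain-behaviour
slope differs between sexes; within-sex Pearson correlations are reported
alongside, and a Bonferroni-adjusted alpha covers the three scores tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BehaviorResult", "SexByScoreGLM", "sex_by_score_glm", "bonferroni_alpha"]

SCORES = ("ados_css", "ados_sa", "ados_rrb")


@dataclass
class BehaviorResult:
    """Sex-by-score interaction test for one ADOS scale."""

    score: str
    f: float
    df: tuple[int, int]
    p: float
    r_male: float
    r_female: float
    n_male: int
    n_female: int
    covariates: tuple[str, ...]
    bonferroni_alpha: float
    n_excluded: int


class SexByScoreGLM:
    """Model: cluster mean ~ sex + score + sex:score + age + mfd (+ module)."""

    def __init__(
        self,
        means,
        table: pd.DataFrame,
        score: str = "ados_sa",
        covariates: tuple[str, ...] = ("age", "mfd"),
        include_module: bool = False,
        min_per_sex: int = 3,
    ):
        if score not in table.columns:
            raise ValueError(f"unknown score column {score!r}")
        means = np.asarray(means, dtype=float)
        if len(means) != len(table):
            raise ValueError("means must align with the table")
        asd = table["dx"].to_numpy() == "ASD"
        scored = asd & np.isfinite(table[score].to_numpy(dtype=float))
        if include_module:
            scored &= np.isfinite(table["ados_module"].to_numpy(dtype=float))
        self.n_excluded = int(asd.sum() - scored.sum())
        tab = table.loc[scored].reset_index(drop=True)
        self.y = means[scored]
        sex = (tab["sex"].to_numpy() == "F").astype(float)
        n_f, n_m = int(sex.sum()), int((1 - sex).sum())
        if n_f < min_per_sex or n_m < min_per_sex:
            raise ValueError(
                "single-sex/insufficient: need at least "
                f"{min_per_sex} scored subjects per sex"
            )
        self.score_name = score
        self.covariates = tuple(covariates) + (
            ("ados_module",) if include_module else ()
        )
        s = tab[score].to_numpy(dtype=float)
        cols = [np.ones(len(tab)), sex, s - s.mean(), sex * (s - s.mean())]
        names = ["intercept", "sex", "score", "sex_by_score"]
        for c in covariates:
            v = tab[c].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(c)
        if include_module:
            mods = tab["ados_module"].astype(int)
            ref = mods.value_counts().idxmax()  # most frequent module = reference
            for level in sorted(set(mods) - {ref}):
                cols.append((mods == level).astype(float).to_numpy())
                names.append(f"module_{level}")
        self.X = np.column_stack(cols)
        self.names = names
        self.sex = sex
        self.scores = s
        self.n_male, self.n_female = n_m, n_f
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient behaviour design")
        if len(self.y) <= self.X.shape[1]:
            raise ValueError("not enough scored subjects for the model")

    def fit(self, n_tests: int = 3, alpha: float = 0.05) -> BehaviorResult:
        X, y = self.X, self.y
        n, p = X.shape
        df2 = n - p
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse_full = float(np.sum((y - X @ beta) ** 2))
        j = self.names.index("sex_by_score")
        Xr = np.delete(X, j, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        sse_red = float(np.sum((y - Xr @ br) ** 2))
        fstat = max(sse_red - sse_full, 0.0) / (sse_full / df2)
        pval = float(stats.f.sf(fstat, 1, df2))
        male = self.sex == 0
        r_m = _pearson(self.y[male], self.scores[male])
        r_f = _pearson(self.y[~male], self.scores[~male])
        return BehaviorResult(
            score=self.score_name,
            f=float(fstat),
            df=(1, df2),
            p=pval,
            r_male=r_m,
            r_female=r_f,
            n_male=self.n_male,
            n_female=self.n_female,
            covariates=self.covariates,
            bonferroni_alpha=bonferroni_alpha(n_tests, alpha),
            n_excluded=self.n_excluded,
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def sex_by_score_glm(
    means,
    table: pd.DataFrame,
    score: str = "ados_sa",
    covariates: tuple[str, ...] = ("age", "mfd"),
    include_module: bool = False,
) -> BehaviorResult:
    """Functional wrapper over :class:`SexByScoreGLM`."""
    return SexByScoreGLM(
        means, table, score, covariates, include_module
    ).fit()


def bonferroni_alpha(n_tests: int = 3, alpha: float = 0.05) -> float:
    """Exact Bonferroni-adjusted alpha (0.05/3 = 0.0167, unrounded)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
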