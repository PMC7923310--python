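"""Head-motion quantification and sample-eligibility filtering.

Framewise displacement follows the Power convention: backward differences
of the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere, summed in absolute value. Eligibility mirrors the selection
rules of large multi-site pediatric case-control cohorts: school-age
range, FIQ within broad normal limits, a sample-adaptive motion cutoff at
Q3 + 3*IQR of mean FD, and a minimum of three subjects per
diagnosis-by-sex cell at every retained site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HEAD_RADIUS_MM",
    "EligibilityReport",
    "framewise_displacement",
    "mean_fd",
    "eligibility_filter",
    "site_cell_filter",
    "cohort_summary",
]

HEAD_RADIUS_MM = 50.0

REASON_CODES = ("age", "fiq", "mfd", "site_cell")


@dataclass
class EligibilityReport:
    """Outcome of the eligibility filter."""

    retained: list[str]
    excluded: dict[str, list[str]]  # subject_id -> reason codes
    mfd_threshold: float
    table: pd.DataFrame = field(repr=False, default=None)


def framewise_displacement(
    motion: np.ndarray, radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """FD series (mm) from a (T, 6) motion trace (3 translations, 3 rotations).

    FD_t = sum |delta translation| + radius * sum |delta rotation|, length T-1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters must be finite")
    d = np.diff(motion, axis=0)
    return np.abs(d[:, :3]).sum(axis=1) + radius * np.abs(d[:, 3:]).sum(axis=1)


def mean_fd(motion: np.ndarray, radius: float = HEAD_RADIUS_MM) -> float:
    return float(framewise_displacement(motion, radius).mean())


def eligibility_filter(
    table: pd.DataFrame,
    age_range: tuple[float, float] = (7.0, 18.0),
    fiq_range: tuple[float, float] = (70.0, 148.0),
    mfd_threshold: float | None = None,
) -> EligibilityReport:
    """Apply the age / FIQ / motion eligibility criteria (inclusive bounds).

    The motion cutoff defaults to Q3 + 3*IQR of the input sample's mean FD
    (type-7 linear-interpolation quantiles); pass ``mfd_threshold`` to
    freeze it, e.g. to re-apply a first pass's threshold.
    """
    required = {"subject_id", "age", "fiq", "mfd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    mfd = table["mfd"].to_numpy(dtype=float)
    if mfd_threshold is None:
        q1, q3 = np.quantile(mfd, [0.25, 0.75])
        mfd_threshold = float(q3 + 3.0 * (q3 - q1))
    reasons: dict[str, list[str]] = {}
    keep = np.ones(len(table), dtype=bool)
    checks = (
        ("age", (table["age"] < age_range[0]) | (table["age"] > age_range[1])),
        ("fiq", (table["fiq"] < fiq_range[0]) | (table["fiq"] > fiq_range[1])),
        ("mfd", table["mfd"] > mfd_threshold),
    )
    for code, bad in checks:
        bad = bad.to_numpy()
        keep &= ~bad
        for sid in table.loc[bad, "subject_id"]:
            reasons.setdefault(sid, []).append(code)
    return EligibilityReport(
        retained=list(table.loc[keep, "subject_id"]),
        excluded=reasons,
        mfd_threshold=mfd_threshold,
        table=table.loc[keep].reset_index(drop=True),
    )


def site_cell_filter(
    table: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Drop sites with fewer than ``min_n`` subjects in any dx-by-sex cell."""
    for col in ("site", "dx", "sex"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    counts = table.groupby(["site", "dx", "sex"]).size().unstack(["dx", "sex"])
    counts = counts.reindex(
        columns=pd.MultiIndex.from_product([["ASD", "NT"], ["M", "F"]]), fill_value=0
    ).fillna(0)
    bad_sites = sorted(counts.index[(counts < min_n).any(axis=1)])
    kept = table[~table["site"].isin(bad_sites)].reset_index(drop=True)
    return kept, bad_sites


def _group_stats(values: pd.Series, groups: pd.Series) -> dict:
    out = {}
    for g, v in values.groupby(groups, observed=True):
        v = v.dropna()
        out[g] = {
            "n": int(len(v)),
            "mean": float(v.mean()) if len(v) else np.nan,
            "sd": float(v.std()) if len(v) > 1 else np.nan,
            "min": float(v.min()) if len(v) else np.nan,
            "max": float(v.max()) if len(v) else np.nan,
        }
    return out


def cohort_summary(table: pd.DataFrame) -> dict:
    """Per-cell descriptives and omnibus group tests (cohort-table style).

    Age and FIQ are compared across the four dx-by-sex cells with one-way
    ANOVA, mean FD with Kruskal-Wallis (its distribution is skewed),
    categorical columns with chi-square (no continuity correction), and
    ADOS scores between male and female ASD subjects with two-sample t
    tests. Degenerate variables (zero variance everywhere) are flagged.
    """
    cells = table["dx"].astype(str) + "_" + table["sex"].astype(str)
    sizes = cells.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two groups with at least two rows")
    summary: dict = {"cells": {}, "tests": {}}
    for var in ("age", "fiq", "mfd"):
        if var not in table.columns:
            continue
        summary["cells"][var] = _group_stats(table[var], cells)
        samples = [
            v.dropna().to_numpy()
            for _, v in table[var].groupby(cells, observed=True)
        ]
        samples = [s for s in samples if len(s) >= 2]
        if all(np.ptp(s) == 0 for s in samples):
            summary["tests"][var] = {"flag": "degenerate (zero variance)"}
            continue
        if var == "mfd":
            h, p = stats.kruskal(*samples)
            summary["tests"][var] = {"H": float(h), "p": float(p)}
        else:
            f, p = stats.f_oneway(*samples)
            summary["tests"][var] = {"F": float(f), "p": float(p)}
    # categorical composition: sex by diagnosis
    ct = pd.crosstab(table["dx"], table["sex"])
    if ct.shape == (2, 2):
        chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
        summary["tests"]["sex_by_dx"] = {"chi2": float(chi2), "p": float(p)}
    asd = table[table["dx"] == "ASD"]
    for score in ("ados_css", "ados_sa", "ados_rrb"):
        if score not in table.columns:
            continue
        m = asd.loc[asd["sex"] == "M", score].dropna()
        f = asd.loc[asd["sex"] == "F", score].dropna()
        if len(m) >= 2 and len(f) >= 2:
            t, p = stats.ttest_ind(m, f)
            summary["tests"][score] = {"t": float(t), "p": float(p)}
    return summary


def chi_square_counts(counts: np.ndarray) -> tuple[float, float]:
    """Chi-square test on a contingency table without continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(counts), correction=False)
    return float(chi2), float(p)
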