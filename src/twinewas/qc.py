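"""Bin-level QC and longitudinal-stability screening.

The screen mirrors the two-step design of a stability-first EWAS:

1. drop bins with zero methylation in too many samples (default: >= 20%);
2. among individuals measured twice at least ``min_gap_years`` apart,
   compute the per-bin test–retest Pearson correlation (R_repeat); bins with
   a significantly positive correlation (two-sided P < 0.05 and r > 0) are
   "longitudinally stable bins" (lsBINs) and carry forward;
3. profile the genetic architecture of lsBINs via twin correlations
   (R_MZ, R_DZ) and their dependence on R_repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "FilterReport",
    "zero_fraction_filter",
    "paired_visits",
    "repeat_correlation",
    "twin_correlations",
    "stability_dependence",
    "pearson_columns",
]


@dataclass(frozen=True)
class FilterReport:
    """Counts from the zero-methylation bin filter."""

    n_input: int
    n_removed: int
    n_retained: int
    max_zero_fraction: float

    @property
    def retained_pct(self) -> float:
        return 100.0 * self.n_retained / self.n_input


def zero_fraction_filter(
    matrix: pd.DataFrame, max_zero_fraction: float = 0.20
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove bins whose fraction of exactly-zero samples is >= the threshold.

    Follows the stricter ">=" reading of the cut-off; the threshold is a
    parameter so the ">" variant is one call away.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputError("empty methylation matrix")
    zero_frac = (matrix.to_numpy() == 0.0).mean(axis=0)
    keep = zero_frac < max_zero_fraction
    report = FilterReport(
        n_input=matrix.shape[1],
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        max_zero_fraction=max_zero_fraction,
    )
    return matrix.loc[:, keep], report


def pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson correlation of two aligned (n, p) arrays.

    NaNs are handled pairwise-complete per column. Returns (r, n_used);
    zero-variance columns yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("arrays must be aligned")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = ok.sum(axis=0).astype(float)
    xs = np.where(ok, x, 0.0)
    ys = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        dx = np.where(ok, x - mx, 0.0)
        dy = np.where(ok, y - my, 0.0)
        cov = (dx * dy).sum(axis=0)
        vx = (dx * dx).sum(axis=0)
        vy = (dy * dy).sum(axis=0)
        r = cov / np.sqrt(vx * vy)
    r[(vx <= 0) | (vy <= 0) | (n < 3)] = np.nan
    return r, n


def paired_visits(
    matrix: pd.DataFrame, cohort: pd.DataFrame, min_gap_years: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the two-visit sample: one row per individual measured twice
    with a between-visit gap of at least ``min_gap_years``.

    Returns (visit-1 matrix, visit-2 matrix) with aligned individual rows.
    """
    v1 = cohort[cohort["visit"] == 1].set_index("individual_id")
    v2 = cohort[cohort["visit"] == 2].set_index("individual_id")
    common = v1.index.intersection(v2.index)
    gap = v2.loc[common, "visit_year"] - v1.loc[common, "visit_year"]
    common = common[(gap >= min_gap_years).to_numpy()]
    if len(common) < 3:
        raise InputError("need at least 3 individuals with qualifying repeat visits")
    m1 = matrix.loc[v1.loc[common, "sample_id"]]
    m2 = matrix.loc[v2.loc[common, "sample_id"]]
    m1.index = common
    m2.index = common
    return m1, m2


def repeat_correlation(visit1: pd.DataFrame, visit2: pd.DataFrame) -> pd.DataFrame:
    """Per-bin test–retest Pearson correlation and lsBIN call.

    P-values use the exact t transform t = r sqrt(n-2)/sqrt(1-r^2) on n-2
    degrees of freedom (two-sided). A bin is an lsBIN when P < 0.05 and
    r > 0 — negative "stability" is not meaningful.
    """
    if visit1.shape[0] < 3:
        raise InputError("need at least 3 paired individuals")
    if not visit1.index.equals(visit2.index):
        raise InputError("visit matrices must be paired by individual")
    r, n = pearson_columns(visit1.to_numpy(), visit2.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(r)] = np.nan
    is_ls = (p < 0.05) & (r > 0)
    is_ls[np.isnan(r)] = False
    return pd.DataFrame(
        {"r_repeat": r, "p_repeat": p, "n_repeat": n.astype(int), "is_lsbin": is_ls},
        index=visit1.columns,
    )


def _complete_pairs(cohort_v1: pd.DataFrame, zygosity: str) -> pd.DataFrame:
    sub = cohort_v1[cohort_v1["zygosity"] == zygosity]
    counts = sub.groupby("family_id")["sample_id"].count()
    fams = counts.index[counts == 2]
    return sub[sub["family_id"].isin(fams)].sort_values(["family_id", "individual_id"])


def twin_correlations(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    bins=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin Pearson correlation across MZ pairs and across DZ pairs.

    Twin-1/twin-2 assignment within each pair is randomized once per call
    (seeded) so that arbitrary file ordering cannot induce artifacts.
    """
    cols = matrix.columns if bins is None else pd.Index(bins)
    v1 = cohort[cohort["visit"] == 1]
    rng = np.random.default_rng(seed)
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = _complete_pairs(v1, zyg)
        n_pairs = len(sub) // 2
        if n_pairs < 3:
            raise InputError(f"need at least 3 complete {zyg} pairs")
        vals = matrix.loc[sub["sample_id"], cols].to_numpy()
        first = vals[0::2]
        second = vals[1::2]
        flip = rng.random(n_pairs) < 0.5
        t1 = np.where(flip[:, None], second, first)
        t2 = np.where(flip[:, None], first, second)
        r, n = pearson_columns(t1, t2)
        out[f"r_{zyg.lower()}"] = r
        out[f"n_{zyg.lower()}"] = n.astype(int)
    return pd.DataFrame(out, index=cols)[["r_mz", "n_mz", "r_dz", "n_dz"]]


def stability_dependence(
    twin: pd.DataFrame,
    stability: pd.DataFrame,
    ratio_min_rdz: float = 0.05,
) -> dict:
    """Correlate twin correlations (and their MZ/DZ ratio) with R_repeat.

    The ratio R_MZ/R_DZ is computed only where R_DZ >= ``ratio_min_rdz``
    (division-blow-up guard); the number of excluded bins is reported.
    """
    common = twin.index.intersection(stability.index)
    rep = stability.loc[common, "r_repeat"].to_numpy()
    rmz = twin.loc[common, "r_mz"].to_numpy()
    rdz = twin.loc[common, "r_dz"].to_numpy()
    ok = ~(np.isnan(rep) | np.isnan(rmz) | np.isnan(rdz))
    rep, rmz, rdz = rep[ok], rmz[ok], rdz[ok]
    if len(rep) < 3 or np.ptp(rep) == 0:
        raise InputError("R_repeat constant or too few bins: dependence undefined")

    def corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise InputError("constant input: correlation undefined")
        r, p = stats.pearsonr(a, b)
        return {"r": float(r), "p": float(p), "n": int(len(a))}

    result = {
        "r_mz_vs_r_repeat": corr(rmz, rep),
        "r_dz_vs_r_repeat": corr(rdz, rep),
    }
    use = rdz >= ratio_min_rdz
    result["n_ratio_excluded"] = int((~use).sum())
    if use.sum() >= 3 and np.ptp(rep[use]) > 0:
        result["ratio_vs_r_repeat"] = corr(rmz[use] / rdz[use], rep[use])
    else:
        result["ratio_vs_r_repeat"] = None
    return result
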