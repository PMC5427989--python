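"""Discovery / replication association testing with Fisher combination.

Discovery uses CWP-discordant MZ twin pairs — the within-pair methylation
difference cancels genetic background and shared environment, so a paired t
test on (affected − unaffected) differences isolates the disease signal.
Replication uses a Welch two-sample t test (affected vs unaffected) in the
remaining, disjoint sample after adjusting methylation for age and age^2
(the methylation–age relationship is nonlinear). Nominally significant
results (P < 0.05 in both stages) with the same direction of effect are
combined by Fisher's method on 4 degrees of freedom.

Sign convention throughout: positive t means higher methylation in affected
individuals, in both stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InputError

__all__ = [
    "select_discordant_pairs",
    "discover_discordant",
    "adjust_age",
    "replicate",
    "fisher_combine",
    "build_assoc_table",
    "rank_top",
]


def select_discordant_pairs(
    cohort: pd.DataFrame, n_pairs: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Deterministically (seeded) choose CWP-discordant MZ pairs.

    Returns a DataFrame with one row per chosen pair and columns
    ``affected_sample`` / ``unaffected_sample`` (visit-1 sample ids).
    """
    v1 = cohort[(cohort["visit"] == 1) & (cohort["zygosity"] == "MZ")]
    rows = []
    for fam, grp in v1.groupby("family_id", sort=True):
        if len(grp) == 2 and grp["cwp"].sum() == 1:
            aff = grp.loc[grp["cwp"] == 1, "sample_id"].iloc[0]
            unaff = grp.loc[grp["cwp"] == 0, "sample_id"].iloc[0]
            rows.append((fam, aff, unaff))
    if len(rows) < 2:
        raise InputError("need at least 2 CWP-discordant MZ pairs")
    pairs = pd.DataFrame(rows, columns=["family_id", "affected_sample", "unaffected_sample"])
    if len(pairs) > n_pairs:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(pairs), size=n_pairs, replace=False))
        pairs = pairs.iloc[keep].reset_index(drop=True)
    return pairs


def discover_discordant(matrix: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Paired t test of methylation within discordant MZ pairs, per bin.

    d = affected − unaffected; t = mean(d) / (sd(d)/sqrt(k)) on k−1 df,
    two-sided. Bins with zero difference variance get NaN statistics and are
    flagged (``valid_disc`` False).
    """
    k = len(pairs)
    if k < 2:
        raise InputError("need at least 2 discordant pairs")
    aff = matrix.loc[pairs["affected_sample"]].to_numpy()
    unaff = matrix.loc[pairs["unaffected_sample"]].to_numpy()
    d = aff - unaff
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(k))
        p = 2.0 * stats.t.sf(np.abs(t), k - 1)
    bad = sd == 0
    t[bad & (mean == 0)] = 0.0
    p[bad & (mean == 0)] = 1.0
    t[bad & (mean != 0)] = np.nan
    p[bad & (mean != 0)] = np.nan
    return pd.DataFrame(
        {"t_disc": t, "p_disc": p, "n_disc_pairs": k, "valid_disc": ~(bad & (mean != 0))},
        index=matrix.columns,
    )


def adjust_age(matrix: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Residualize each bin on intercept, age and age^2 by least squares."""
    sub = cohort.set_index("sample_id").loc[matrix.index]
    age = sub["age"].to_numpy(dtype=float)
    if np.isnan(age).any():
        raise InputError("ages must be present for all samples")
    if np.ptp(age) == 0:
        raise CollinearityError("age is constant: quadratic age adjustment undefined")
    x = np.column_stack([np.ones_like(age), age, age**2])
    m = matrix.to_numpy()
    beta, *_ = np.linalg.lstsq(x, m, rcond=None)
    resid = m - x @ beta
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def replicate(adjusted: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t test of (age-adjusted) methylation, affected vs
    unaffected, per bin. Positive t = higher methylation in affected."""
    sub = cohort.set_index("sample_id").loc[adjusted.index]
    aff = adjusted.loc[sub["cwp"] == 1].to_numpy()
    unaff = adjusted.loc[sub["cwp"] == 0].to_numpy()
    if len(aff) < 2 or len(unaff) < 2:
        raise InputError("both affected and unaffected groups need >= 2 members")
    t, p = stats.ttest_ind(aff, unaff, axis=0, equal_var=False)
    return pd.DataFrame(
        {"t_rep": t, "p_rep": p, "n_rep": len(aff) + len(unaff)}, index=adjusted.columns
    )


def fisher_combine(
    p_disc, p_rep, sign_disc, sign_rep, *, nominal_alpha: float = 0.05, gate: bool = True
):
    """Direction-concordant Fisher combination of two p-values (vectorized).

    chi2 = −2(ln p_disc + ln p_rep) referred to the chi-square upper tail on
    4 df. With ``gate`` (default), combination requires both p-values below
    ``nominal_alpha`` and concordant signs; non-qualifying entries yield NaN
    and ``combined`` False.
    """
    p1 = np.asarray(p_disc, dtype=float)
    p2 = np.asarray(p_rep, dtype=float)
    if np.any(p1[~np.isnan(p1)] <= 0) or np.any(p2[~np.isnan(p2)] <= 0):
        raise InputError("p-values must lie in (0, 1]")
    if np.any(p1[~np.isnan(p1)] > 1) or np.any(p2[~np.isnan(p2)] > 1):
        raise InputError("p-values must lie in (0, 1]")
    s1 = np.sign(np.asarray(sign_disc, dtype=float))
    s2 = np.sign(np.asarray(sign_rep, dtype=float))
    concordant = s1 == s2
    ok = ~(np.isnan(p1) | np.isnan(p2))
    if gate:
        ok &= (p1 < nominal_alpha) & (p2 < nominal_alpha) & concordant
    with np.errstate(divide="ignore"):
        chi2 = np.where(ok, -2.0 * (np.log(p1) + np.log(p2)), np.nan)
    p_fisher = np.where(ok, stats.chi2.sf(chi2, 4), np.nan)
    return chi2, p_fisher, concordant, ok


def build_assoc_table(
    disc: pd.DataFrame, rep: pd.DataFrame, *, nominal_alpha: float = 0.05
) -> pd.DataFrame:
    """Merge discovery and replication results and apply the gated Fisher
    combination. Bins failing the gate keep their component statistics."""
    tab = disc.join(rep, how="inner")
    chi2, p_fisher, concordant, combined = fisher_combine(
        tab["p_disc"], tab["p_rep"], tab["t_disc"], tab["t_rep"],
        nominal_alpha=nominal_alpha,
    )
    tab["direction_concordant"] = concordant
    tab["chi2_fisher"] = chi2
    tab["p_fisher"] = p_fisher
    tab["combined"] = combined
    tab["sign"] = np.sign(tab["t_disc"]).astype("Int64")
    return tab


def rank_top(records: pd.DataFrame, k: int = 24) -> pd.DataFrame:
    """Top-k combined records by ascending Fisher p, ties by larger |chi2|
    then genomic coordinate (bin id). Deterministic across runs."""
    comb = records[records["combined"].fillna(False)].copy()
    comb["_abschi2"] = comb["chi2_fisher"].abs()
    comb["_id"] = comb.index
    comb = comb.sort_values(
        ["p_fisher", "_abschi2", "_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns=["_abschi2", "_id"])
    return comb.head(k)
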