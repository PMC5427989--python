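"""Synthetic twin-cohort generator.

Produces bin-level methylation matrices and a phenotype table with the
statistical structure the downstream analysis assumes:

* per-bin ACE structure — an additive-genetic component shared with
  correlation 1 within MZ pairs and 0.5 within DZ pairs, a common-environment
  component shared within pair, and unique environment;
* longitudinal stability — for "stable" bins a persistent component (genetic
  + shared + persistent unique environment) carries over to a second visit,
  so the expected test–retest correlation equals ``test_retest_r``; unstable
  bins are regenerated per visit;
* zero inflation — a fraction of entries per bin is set to exactly 0,
  mimicking bins with no MeDIP coverage;
* a liability-threshold disease model — chronic-widespread-pain status is 1
  when a latent Gaussian liability (additive-genetic twin component, age and
  BMI effects, and per-SD effects of designated causal methylation bins)
  exceeds the threshold implied by the target prevalence.

The default cohort mirrors the study design this pipeline targets: 565 MZ
pairs, 244 DZ pairs and 90 singletons (1708 measured women), a subset with a
repeat methylation visit at least three years later, smoking known for ~76%
of individuals (45% ever-smokers among those), and white-blood-cell counts
for ~26%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "visit1"]

N_CHROMS = 22
BIN_WIDTH = 500
BIN_STEP = 250

# Per-SD liability effect giving four causal bins a combined 6% share.
_DEFAULT_GAMMA = float(np.sqrt(0.06 / 4.0))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic twin cohort.

    Variance-share parameters (``bin_h2``, ``bin_c2``, ``test_retest_r``)
    may be scalars or per-bin arrays of length ``n_bins``; for stable bins
    ``test_retest_r >= bin_h2 + bin_c2`` must hold, because genetic and
    shared-environment components persist across visits by construction.
    """

    n_mz_pairs: int = 565
    n_dz_pairs: int = 244
    n_singletons: int = 90
    n_bins: int = 5000
    frac_stable_bins: float = 0.10
    bin_h2: float | Sequence[float] = 0.15
    bin_c2: float | Sequence[float] = 0.10
    test_retest_r: float | Sequence[float] = 0.30
    zero_inflation: float = 0.01
    causal_bin_effects: tuple[tuple[int, float], ...] = (
        (0, _DEFAULT_GAMMA),
        (1, _DEFAULT_GAMMA),
        (2, _DEFAULT_GAMMA),
        (3, _DEFAULT_GAMMA),
    )
    liability_h2: float = 0.636
    beta_age: float = 0.01
    beta_bmi: float = 0.02
    prevalence: float = 0.15
    repeat_fraction: float = 0.17
    repeat_gap_years: float = 7.0
    age_range: tuple[float, float] = (17.0, 82.0)
    bmi_mean: float = 25.6
    bmi_sd: float = 4.5
    smoking_known_fraction: float = 1307.0 / 1708.0
    smoking_rates: tuple[float, float] = (489.0 / 1307.0, 99.0 / 1307.0)  # ex, current
    wbc_fraction: float = 441.0 / 1708.0
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    stable_bin_flags: np.ndarray
    causal_bin_ids: list[str]
    true_h2: float
    true_bin_effects: dict[str, float]
    liability_threshold: float

    def to_json(self, path) -> None:
        payload = {
            "stable_bin_flags": [bool(x) for x in self.stable_bin_flags],
            "causal_bin_ids": list(self.causal_bin_ids),
            "true_h2": self.true_h2,
            "true_bin_effects": self.true_bin_effects,
            "liability_threshold": self.liability_threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_bin_array(value, n_bins: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_bins,)).copy()
    if np.any(arr < 0) or np.any(arr > 1):
        raise ConfigError(f"{name} must lie in [0, 1]")
    return arr


def _validate(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if min(cfg.n_mz_pairs, cfg.n_dz_pairs, cfg.n_singletons) < 0 or cfg.n_bins < 1:
        raise ConfigError("cohort sizes must be non-negative and n_bins >= 1")
    if not (0.0 < cfg.prevalence < 1.0):
        raise ConfigError("prevalence must lie in (0, 1)")
    if not (0.0 <= cfg.zero_inflation <= 1.0):
        raise ConfigError("zero_inflation must lie in [0, 1]")
    if not (0.0 <= cfg.frac_stable_bins <= 1.0):
        raise ConfigError("frac_stable_bins must lie in [0, 1]")
    h2 = _as_bin_array(cfg.bin_h2, cfg.n_bins, "bin_h2")
    c2 = _as_bin_array(cfg.bin_c2, cfg.n_bins, "bin_c2")
    rr = _as_bin_array(cfg.test_retest_r, cfg.n_bins, "test_retest_r")
    if np.any(h2 + c2 > 1.0 + 1e-12):
        raise ConfigError("bin_h2 + bin_c2 must not exceed 1")
    n_stable = int(round(cfg.frac_stable_bins * cfg.n_bins))
    if np.any(rr[:n_stable] + 1e-12 < (h2 + c2)[:n_stable]):
        raise ConfigError(
            "test_retest_r must be >= bin_h2 + bin_c2 for stable bins "
            "(genetic and shared components persist across visits)"
        )
    gam2 = sum(g * g for _, g in cfg.causal_bin_effects)
    if cfg.liability_h2 < 0 or cfg.liability_h2 + gam2 > 1.0 + 1e-12:
        raise ConfigError("liability_h2 + sum of squared bin effects must not exceed 1")
    for j, _ in cfg.causal_bin_effects:
        if not (0 <= j < cfg.n_bins):
            raise ConfigError(f"causal bin index {j} out of range for n_bins={cfg.n_bins}")
    if len({j for j, _ in cfg.causal_bin_effects}) < len(cfg.causal_bin_effects):
        raise ConfigError("causal bin indices must be distinct")
    return h2, c2, rr


def make_bin_grid(n_bins: int) -> pd.DataFrame:
    """Overlapping 500 bp bins at 250 bp step, spread over 22 chromosomes."""
    per_chrom = int(np.ceil(n_bins / N_CHROMS))
    chroms, starts = [], []
    for c in range(1, N_CHROMS + 1):
        k = min(per_chrom, n_bins - len(chroms))
        if k <= 0:
            break
        chroms.extend([f"chr{c}"] * k)
        starts.extend(BIN_STEP * np.arange(k))
    bins = pd.DataFrame({"chrom": chroms, "start": np.asarray(starts, dtype=int)})
    bins["end"] = bins["start"] + BIN_WIDTH
    bins.index = bins["chrom"] + "_" + bins["start"].astype(str)
    bins.index.name = "bin_id"
    return bins


def _shared_component(rng, r_fam: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-individual standard-normal component with within-pair correlation
    r_fam (one value per family); returns (2 * n_fam, n_bins)."""
    n_fam = r_fam.shape[0]
    common = rng.standard_normal((n_fam, n_bins))
    unique = rng.standard_normal((2 * n_fam, n_bins))
    w_c = np.sqrt(r_fam)[:, None]
    w_u = np.sqrt(1.0 - r_fam)[:, None]
    out = np.repeat(common * w_c, 2, axis=0)
    out += unique * np.repeat(w_u, 2, axis=0)
    return out


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a twin cohort.

    Returns
    -------
    matrix : DataFrame
        Methylation matrix, rows = sample ids (``individual_v1``/``_v2``),
        columns = bin ids (``chrom_start``). FPKM-like non-negative values.
    cohort : DataFrame
        One row per sample: twin structure, CWP status, covariates, visit.
    truth : SimTruth
        Stable-bin flags, causal bins with effects, heritability, threshold.
    """
    h2, c2, rr = _validate(config)
    rng = np.random.default_rng(config.seed)
    cfg = config

    n_fam = cfg.n_mz_pairs + cfg.n_dz_pairs + cfg.n_singletons
    n_ind = 2 * n_fam  # phantom cotwins of singletons included, dropped later
    zyg = np.array(
        ["MZ"] * cfg.n_mz_pairs + ["DZ"] * cfg.n_dz_pairs + ["SGL"] * cfg.n_singletons
    )
    # Genetic correlation of the pair: singletons alternate MZ/DZ-like
    # (their unmeasured cotwin is a real twin of unknown recorded zygosity).
    r_gen = np.where(zyg == "MZ", 1.0, 0.5)
    sgl = np.where(zyg == "SGL")[0]
    r_gen[sgl[::2]] = 1.0
    r_gen[sgl[1::2]] = 0.5

    family_id = np.repeat([f"fam{i:04d}" for i in range(n_fam)], 2)
    member = np.tile(["a", "b"], n_fam)
    individual_id = np.char.add(np.char.add(family_id.astype(str), "_"), member)
    zyg_ind = np.repeat(zyg, 2)

    # --- covariates -------------------------------------------------------
    age_fam = rng.uniform(*cfg.age_range, size=n_fam)  # twins share birth date
    age = np.repeat(age_fam, 2)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n_ind), 14.0, 55.0)

    # --- bin grid and variance shares ------------------------------------
    bins = make_bin_grid(cfg.n_bins)
    n_stable = int(round(cfg.frac_stable_bins * cfg.n_bins))
    stable = np.zeros(cfg.n_bins, dtype=bool)
    stable[:n_stable] = True
    a2 = np.where(stable, h2, 0.0)
    cc2 = np.where(stable, c2, 0.0)
    u2 = np.where(stable, rr - h2 - c2, 0.0)  # persistent unique environment
    e2 = np.clip(1.0 - a2 - cc2 - u2, 0.0, None)  # per-visit noise

    # FPKM-like scale with a fixed mean/SD ratio of 5: exact zeros then sit
    # 5 SD below the mean for every bin, so low-rate zero inflation
    # attenuates correlations uniformly and mildly instead of wrecking
    # high-expression bins.
    mu = rng.uniform(5.0, 10.0, size=cfg.n_bins)
    sd = mu / 5.0

    # --- methylation components ------------------------------------------
    A = _shared_component(rng, r_gen, cfg.n_bins)
    C = np.repeat(rng.standard_normal((n_fam, cfg.n_bins)), 2, axis=0)
    U = rng.standard_normal((n_ind, cfg.n_bins))
    persistent = np.sqrt(a2) * A + np.sqrt(cc2) * C + np.sqrt(u2) * U
    del A, C, U

    def visit_values(noise):
        std = persistent + np.sqrt(e2) * noise
        vals = mu + sd * std
        mask = rng.random(vals.shape) < cfg.zero_inflation
        vals[mask] = 0.0
        return np.clip(vals, 0.0, None)

    m1 = visit_values(rng.standard_normal((n_ind, cfg.n_bins)))

    # --- liability and CWP status ----------------------------------------
    gam2 = sum(g * g for _, g in cfg.causal_bin_effects)
    AL = _shared_component(rng, r_gen, 1)[:, 0] * np.sqrt(cfg.liability_h2)
    EL = rng.standard_normal(n_ind) * np.sqrt(max(1.0 - cfg.liability_h2 - gam2, 0.0))
    L = AL + EL
    L += cfg.beta_age * (age - np.mean(cfg.age_range))
    L += cfg.beta_bmi * (bmi - cfg.bmi_mean)
    for j, g in cfg.causal_bin_effects:
        col = m1[:, j]
        s = col.std()
        if s > 0:
            L += g * (col - col.mean()) / s
    var_l = (
        cfg.beta_age**2 * (cfg.age_range[1] - cfg.age_range[0]) ** 2 / 12.0
        + cfg.beta_bmi**2 * cfg.bmi_sd**2
        + cfg.liability_h2
        + gam2
        + max(1.0 - cfg.liability_h2 - gam2, 0.0)
    )
    tau = stats.norm.ppf(1.0 - cfg.prevalence) * np.sqrt(var_l)
    cwp = (L > tau).astype(int)
    cotwin_cwp = cwp.reshape(-1, 2)[:, ::-1].reshape(-1)

    # --- smoking and white-blood-cell counts ------------------------------
    p_ex, p_cur = cfg.smoking_rates
    smoking = np.where(
        rng.random(n_ind) < cfg.smoking_known_fraction,
        rng.choice(["ex", "current", "never"], size=n_ind,
                   p=[p_ex, p_cur, 1.0 - p_ex - p_cur]),
        "NA",
    )
    has_wbc = rng.random(n_ind) < cfg.wbc_fraction
    wbc = {
        "neut": np.clip(rng.normal(3.9, 1.1, n_ind), 0.2, None),
        "eos": np.clip(rng.normal(0.17, 0.10, n_ind), 0.0, None),
        "mono": np.clip(rng.normal(0.42, 0.12, n_ind), 0.02, None),
        "lymph": np.clip(rng.normal(1.85, 0.50, n_ind), 0.2, None),
    }
    for key in wbc:
        wbc[key] = np.where(has_wbc, np.round(wbc[key], 3), np.nan)

    # --- repeat visits -----------------------------------------------------
    measured = np.ones(n_ind, dtype=bool)
    measured[2 * (cfg.n_mz_pairs + cfg.n_dz_pairs) + 1 :: 2] = False  # phantoms
    measured_idx = np.where(measured)[0]
    n_repeat = int(round(cfg.repeat_fraction * measured_idx.size))
    repeat_idx = rng.choice(measured_idx, size=n_repeat, replace=False)
    repeat_idx.sort()
    gaps = stats.truncnorm.rvs(
        (3.0 - cfg.repeat_gap_years) / 1.2, np.inf,
        loc=cfg.repeat_gap_years, scale=1.2, size=n_repeat, random_state=rng,
    )
    year1 = rng.uniform(1996.0, 2000.0, size=n_ind)

    m2_rows = None
    if n_repeat:
        noise2 = rng.standard_normal((n_repeat, cfg.n_bins))
        std2 = persistent[repeat_idx] + np.sqrt(e2) * noise2
        vals2 = mu + sd * std2
        mask2 = rng.random(vals2.shape) < cfg.zero_inflation
        vals2[mask2] = 0.0
        m2_rows = np.clip(vals2, 0.0, None)

    # --- assemble outputs (phantom cotwins dropped) ------------------------
    def cohort_rows(idx, visit, ages, years):
        return pd.DataFrame(
            {
                "sample_id": [f"{individual_id[i]}_v{visit}" for i in idx],
                "individual_id": individual_id[idx],
                "family_id": family_id[idx],
                "zygosity": zyg_ind[idx],
                "cwp": cwp[idx],
                "cotwin_cwp": cotwin_cwp[idx],
                "age": np.round(ages, 2),
                "bmi": np.round(bmi[idx], 2),
                "smoking": smoking[idx],
                "neut": wbc["neut"][idx],
                "eos": wbc["eos"][idx],
                "mono": wbc["mono"][idx],
                "lymph": wbc["lymph"][idx],
                "visit": visit,
                "visit_year": np.round(years, 2),
            }
        )

    cohort = cohort_rows(measured_idx, 1, age[measured_idx], year1[measured_idx])
    frames = [cohort]
    if n_repeat:
        frames.append(
            cohort_rows(repeat_idx, 2, age[repeat_idx] + gaps, year1[repeat_idx] + gaps)
        )
    cohort = pd.concat(frames, ignore_index=True)

    rows = [m1[measured_idx]]
    if m2_rows is not None:
        rows.append(m2_rows)
    matrix = pd.DataFrame(
        np.vstack(rows), index=cohort["sample_id"].to_numpy(), columns=bins.index
    )
    matrix.index.name = "sample_id"

    truth = SimTruth(
        stable_bin_flags=stable,
        causal_bin_ids=[bins.index[j] for j, _ in cfg.causal_bin_effects],
        true_h2=cfg.liability_h2,
        true_bin_effects={bins.index[j]: g for j, g in cfg.causal_bin_effects},
        liability_threshold=float(tau / np.sqrt(var_l)),
    )
    return matrix, cohort, truth


def visit1(matrix: pd.DataFrame, cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict matrix and cohort to first-visit samples (the cross-sectional
    analysis set; repeat visits serve only the stability screen)."""
    sub = cohort[cohort["visit"] == 1]
    return matrix.loc[sub["sample_id"]], sub.reset_index(drop=True)
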