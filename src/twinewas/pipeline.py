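"""End-to-end orchestration of the twin EWAS pipeline.

Stage order mirrors the study design: zero-methylation QC -> longitudinal
stability screen (lsBINs) -> twin-correlation profiling -> discordant-MZ
discovery -> age-adjusted replication -> direction-concordant Fisher
combination -> effective-number-of-tests threshold and FDR -> top-bin
logistic models -> liability-threshold variance decomposition. Every stage
writes a plain-text artifact plus counts into a machine-readable summary;
identical config + seed give byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, io, liability, models, multiple_testing, qc
from .errors import InputError, TwinEwasError
from .simulate import SimConfig, make_bin_grid, simulate_cohort, visit1

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("twinewas")

STAGES = ("qc", "stability", "twincorr", "ewas", "correct", "models", "liability")


@dataclass
class PipelineConfig:
    """Thresholds, sizes and paths for a pipeline run."""

    bed_path: str | None = None
    matrix_path: str | None = None
    cohort_path: str | None = None
    max_zero_fraction: float = 0.20
    lsbin_p: float = 0.05
    lsbin_require_positive: bool = True
    nominal_p: float = 0.05
    alpha: float = 0.05
    min_gap_years: float = 3.0
    n_discovery_pairs: int = 50
    meff_block_size: int = 5000
    top_k: int = 24
    n_joint_bins: int = 4
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self):
        for name in ("max_zero_fraction", "lsbin_p", "nominal_p", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise InputError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.matrix_path:
        bins, matrix = io.read_bin_matrix(config.bed_path, config.matrix_path)
        cohort = io.read_cohort(config.cohort_path)
        return matrix, cohort, bins
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    matrix, cohort, _ = simulate_cohort(SimConfig(**sim_kwargs))
    return matrix, cohort, make_bin_grid(matrix.shape[1])


def _bin_table(df: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    out = bins.loc[df.index, ["chrom", "start", "end"]].join(df)
    out.index.name = "bin_id"
    return out


def run_pipeline(config: PipelineConfig, outdir, until: str | None = None) -> dict:
    """Run the pipeline, writing artifacts into ``outdir``.

    ``until`` stops after the named stage (one of ``STAGES``). Any stage
    error is re-raised carrying the stage name. Returns the in-memory stage
    results plus the run summary.
    """
    if until is not None and until not in STAGES:
        raise InputError(f"unknown stage {until!r}; expected one of {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    results: dict = {"summary": summary}
    current = "input"

    def record(stage: str, counts: dict, *files: Path):
        summary["stages"][stage] = counts
        for f in files:
            summary["artifacts"][f.name] = _sha256(f)
        log.info("stage %s: %s", stage, counts)

    def finish():
        io.write_json(summary, outdir / "summary.json")
        return results

    try:
        matrix, cohort, bins = _load_inputs(config)
        record("input", {"n_samples": matrix.shape[0], "n_bins": matrix.shape[1],
                         "n_individuals": int(cohort["individual_id"].nunique())})

        current = "qc"
        matrix_qc, filt = qc.zero_fraction_filter(matrix, config.max_zero_fraction)
        record("qc", {"n_input": filt.n_input, "n_removed": filt.n_removed,
                      "n_retained": filt.n_retained,
                      "retained_pct": round(filt.retained_pct, 4)})
        results.update(matrix_qc=matrix_qc, filter=filt)
        if until == "qc":
            return finish()

        current = "stability"
        v1m, v2m = qc.paired_visits(matrix_qc, cohort, config.min_gap_years)
        stab = qc.repeat_correlation(v1m, v2m)
        stab["is_lsbin"] = stab["p_repeat"] < config.lsbin_p
        if config.lsbin_require_positive:
            stab["is_lsbin"] &= stab["r_repeat"] > 0
        stab_path = outdir / "stability.tsv"
        _bin_table(stab, bins).to_csv(stab_path, sep="\t", float_format=io.FLOAT_FMT)
        lsbins = stab.index[stab["is_lsbin"].fillna(False)]
        record("stability",
               {"n_tested": len(stab), "n_repeat_individuals": len(v1m),
                "n_lsbins": len(lsbins),
                "lsbin_pct_of_input": round(100.0 * len(lsbins) / matrix.shape[1], 4)},
               stab_path)
        results.update(stability=stab, lsbins=lsbins)
        if until == "stability":
            return finish()
        if len(lsbins) == 0:
            raise InputError("no longitudinally stable bins: cannot continue")
        matrix_ls = matrix_qc.loc[:, lsbins]

        current = "twincorr"
        twin = qc.twin_correlations(matrix_ls, cohort, seed=config.seed)
        twin_path = outdir / "twincorr.tsv"
        _bin_table(twin, bins).to_csv(twin_path, sep="\t", float_format=io.FLOAT_FMT)
        try:
            dependence = qc.stability_dependence(twin, stab.loc[lsbins])
        except InputError as exc:
            dependence = {"error": str(exc)}
        dep_path = outdir / "dependence.json"
        io.write_json(dependence, dep_path)
        record("twincorr", {"n_bins": len(twin),
                            "mean_r_mz": round(float(np.nanmean(twin["r_mz"])), 4),
                            "mean_r_dz": round(float(np.nanmean(twin["r_dz"])), 4)},
               twin_path, dep_path)
        results.update(twin=twin, dependence=dependence)
        if until == "twincorr":
            return finish()

        current = "ewas"
        m1, coh1 = visit1(matrix_ls, cohort)
        pairs = association.select_discordant_pairs(
            coh1, config.n_discovery_pairs, seed=config.seed)
        disc = association.discover_discordant(m1, pairs)
        disc_samples = set(pairs["affected_sample"]) | set(pairs["unaffected_sample"])
        rep_mask = ~m1.index.isin(disc_samples)
        assert rep_mask.sum() + len(disc_samples) == len(m1)
        adj = association.adjust_age(m1.loc[rep_mask], coh1)
        rep = association.replicate(adj, coh1)
        assoc = association.build_assoc_table(disc, rep, nominal_alpha=config.nominal_p)
        record("ewas", {
            "n_discovery_pairs": len(pairs),
            "n_replication_samples": int(rep_mask.sum()),
            "n_disc_nominal": int((assoc["p_disc"] < config.nominal_p).sum()),
            "n_rep_nominal": int((assoc["p_rep"] < config.nominal_p).sum()),
            "n_both_nominal_ungated": int(((assoc["p_disc"] < config.nominal_p)
                                           & (assoc["p_rep"] < config.nominal_p)).sum()),
            "n_combined_concordant": int(assoc["combined"].sum()),
        })
        results.update(assoc=assoc, pairs=pairs)
        if until == "ewas":
            ewas_path = outdir / "ewas.tsv"
            _bin_table(assoc, bins).to_csv(ewas_path, sep="\t", float_format=io.FLOAT_FMT)
            summary["artifacts"][ewas_path.name] = _sha256(ewas_path)
            return finish()

        current = "correct"
        meff = multiple_testing.effective_tests(
            m1, bins, block_size=config.meff_block_size, alpha=config.alpha)
        q = np.full(len(assoc), np.nan)
        comb = assoc["combined"].to_numpy()
        if comb.any():
            q[comb] = multiple_testing.fdr_dependency(assoc.loc[comb, "p_fisher"])
        assoc["q_by"] = q
        ewas_path = outdir / "ewas.tsv"
        _bin_table(assoc, bins).to_csv(ewas_path, sep="\t", float_format=io.FLOAT_FMT)
        meff_path = outdir / "meff.json"
        io.write_json(
            {"alpha": meff.alpha, "block_size": meff.block_size, "n_bins": meff.n_bins,
             "meff_total": meff.total_meff, "threshold": meff.threshold,
             "per_chrom": meff.per_chrom}, meff_path)
        top = association.rank_top(assoc, config.top_k)
        top_path = outdir / "top_bins.tsv"
        _bin_table(top, bins).to_csv(top_path, sep="\t", float_format=io.FLOAT_FMT)
        record("correct",
               {"meff_total": round(meff.total_meff, 2), "threshold": meff.threshold,
                "n_epigenomewide": int((assoc["p_fisher"] < meff.threshold).sum()),
                "n_top": len(top)},
               ewas_path, meff_path, top_path)
        results.update(meff=meff, top=top)
        if until == "correct":
            return finish()

        current = "models"
        top_bins = list(top.index[: config.n_joint_bins])
        model_rows = []

        def add_fit(label, fit):
            for term, row in fit.terms.iterrows():
                model_rows.append({
                    "model": label, "term": term, "estimate": row["estimate"],
                    "se": row["se"], "z": row["z"], "p": row["p"],
                    "n": fit.n_used, "converged": fit.converged,
                })

        for b in top_bins:
            try:
                add_fit(f"single:{b}", models.logistic_cwp(m1[b], coh1))
            except TwinEwasError:
                model_rows.append({"model": f"single:{b}", "term": "error",
                                   "estimate": np.nan, "se": np.nan, "z": np.nan,
                                   "p": np.nan, "n": 0, "converged": False})
        joint_ok = False
        if len(top_bins) >= 2:
            try:
                add_fit("joint", models.joint_logistic(m1[top_bins], coh1))
                joint_ok = True
            except TwinEwasError:
                pass
        cwp1 = coh1.set_index("sample_id").loc[m1.index, "cwp"].to_numpy()
        eta = {b: models.anova_variance_explained(m1[b].to_numpy(), cwp1)
               for b in top_bins}
        models_df = pd.DataFrame(model_rows)
        models_path = outdir / "models.tsv"
        models_df.to_csv(models_path, sep="\t", index=False, float_format=io.FLOAT_FMT)
        eta_path = outdir / "anova_eta2.json"
        io.write_json({"eta2": eta}, eta_path)
        record("models", {"n_single_models": len(top_bins), "joint_fitted": joint_ok},
               models_path, eta_path)
        results.update(models=models_df, eta2=eta)
        if until == "models":
            return finish()

        current = "liability"
        full = liability.fit_liability(cohort, ("age", "bmi"), matrix=m1, bins=top_bins)
        reduced = liability.fit_liability(cohort, ("age", "bmi"), matrix=m1,
                                          bins=top_bins, fix_a2=0.0, compute_se=False)
        lam, p_lrt = liability.lrt_vad(full, reduced)
        liab = {
            "a2": full.a2, "se_a2": full.se_a2, "tau": full.tau,
            "beta": full.beta, "gamma": full.gamma,
            "fractions": {"AGF": full.fractions["AGF"],
                          "EGF": full.fractions["EGF"],
                          "RES": full.fractions["RES"]},
            "egf_total": float(sum(full.fractions["EGF"].values())),
            "loglik": full.loglik, "loglik_reduced": reduced.loglik,
            "lrt": {"stat": lam, "p": p_lrt},
            "n_mz_pairs": full.n_mz_pairs, "n_dz_pairs": full.n_dz_pairs,
            "n_singletons": full.n_singletons,
            "converged": full.converged, "boundary": full.boundary,
        }
        liab_path = outdir / "liability.json"
        io.write_json(liab, liab_path)
        record("liability", {"a2": round(full.a2, 4), "lrt_p": round(p_lrt, 6),
                             "egf_total": round(liab["egf_total"], 4)}, liab_path)
        results.update(liability=liab, liability_fit=full)
    except TwinEwasError as exc:
        raise type(exc)(f"stage '{current}': {exc}") from exc
    return finish()
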