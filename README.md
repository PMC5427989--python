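# twinewas

A twin-design epigenome-wide association (EWAS) pipeline for chronic
widespread pain (CWP), built for bin-level MeDIP-seq methylation data from
MZ/DZ twin cohorts. It implements, end to end:

1. **QC** — exclusion of bins with zero methylation in ≥ 20% of samples.
2. **Longitudinal stability screen** — per-bin Pearson correlation
   *R*<sub>repeat</sub> between measurements taken ≥ 3 years apart;
   bins with significantly positive *R*<sub>repeat</sub> (*P* < 0.05) are
   longitudinally stable bins (**lsBINs**).
3. **Twin-correlation profiling** — *R*<sub>MZ</sub>, *R*<sub>DZ</sub> per
   lsBIN and the dependence of both (and their ratio) on *R*<sub>repeat</sub>.
4. **Discovery** — paired *t* test of methylation within CWP-discordant MZ
   pairs (genetic background cancels within pair).
5. **Replication** — Welch *t* test, affected vs unaffected, in the disjoint
   remaining sample after residualizing methylation on age and age².
6. **Combination** — Fisher's method (χ² on 4 df) restricted to bins nominally
   significant in *both* stages with the *same direction* of effect.
7. **Multiple testing** — effective number of independent tests
   *M*<sub>eff</sub> from eigenvalues of the bin correlation matrix
   (Li & Ji counting, blockwise per chromosome), epigenome-wide threshold
   α/*M*<sub>eff</sub>, and Benjamini–Yekutieli FDR under dependency.
8. **Covariate models** — per-bin and joint logistic regressions of CWP on
   standardized methylation with age, BMI, cotwin affection status, smoking
   and white-blood-cell counts; one-way-ANOVA η² per bin.
9. **Liability-threshold decomposition** — maximum-likelihood AE twin model
   of the latent CWP liability with methylation bins as fixed epigenetic
   covariates: additive-genetic fraction (AGF = *a*², the narrow-sense
   heritability of liability), per-bin epigenetic fractions
   (EGF<sub>j</sub> = γ<sub>j</sub>²), residual (RES), and a
   boundary-corrected likelihood-ratio test of *V*<sub>AD</sub> > 0.

Because no real cohort ships with the package, a first-class synthetic twin
cohort generator (`twinewas.simulate`) produces methylation matrices and
phenotype tables with the full assumed structure — per-bin ACE variance
components (MZ genetic correlation 1, DZ ½), longitudinal persistence,
zero inflation, and a liability-threshold disease model — together with a
ground-truth record for parameter-recovery testing. Its defaults mirror the
motivating study design: 565 MZ pairs + 244 DZ pairs + 90 singletons
(1708 women), ~17% with a repeat visit ≥ 3 years later, 45% ever-smokers
among the ~76% with smoking data, liability heritability 0.636, and four
causal bins jointly explaining 6% of liability variance.

## The core model

For individual *i* the liability is

```
L_i = β' x_i + Σ_j γ_j z_ij + A_i + E_i ,     CWP_i = 1  iff  L_i > τ
```

with x standardized covariates (age, BMI), z standardized bin methylation,
Var(A) = a², Var(E) = 1 − a² − Σγ², corr(A) = 1 within MZ and ½ within DZ
pairs. Each complete pair contributes the bivariate-normal orthant
probability of its observed status combination (computed by Drezner–
Wesolowsky/Genz quadrature to ~1e-14); singletons contribute univariate
tails. AGF + Σ EGF + RES = 1 by construction.

## Worked example

```bash
twinewas simulate --outdir demo/inputs --seed 1 --n-bins 2000
twinewas run-all --bed demo/inputs/bins.bed --matrix demo/inputs/matrix.tsv \
    --cohort demo/inputs/cohort.csv --outdir demo/run --seed 1
twinewas report --rundir demo/run
```

prints (abridged):

```
run seed 1
  qc         n_input=2000, n_removed=0, n_retained=2000, retained_pct=100.0
  stability  lsbin_pct_of_input=11.9, n_lsbins=238, n_repeat_individuals=290, n_tested=2000
  twincorr   mean_r_dz=0.1126, mean_r_mz=0.1639, n_bins=238
  ewas       n_combined_concordant=3, n_disc_nominal=15, n_discovery_pairs=50,
             n_rep_nominal=18, n_replication_samples=1608
  correct    meff_total=238.0, n_top=3, threshold=0.00021
  liability  a2=0.6547, egf_total=0.0748, lrt_p=0.0
heritability a2 = 0.655 +/- 0.053, epigenetic total = 7.48%, LRT p = 3.371e-21
```

Reading this: 290 individuals had a qualifying repeat visit; 238/2000 bins
(11.9%) passed the stability screen, with mean twin correlations
*R*<sub>MZ</sub> ≈ 0.16 > *R*<sub>DZ</sub> ≈ 0.11 as an additive-genetic
component predicts. Three bins survived the two-stage direction-concordant
gate — all three are true causal bins of the generator (the fourth missed
the stability screen at this seed). The liability fit recovers the simulated
heritability (truth 0.636, estimate 0.655 ± 0.053) and attributes 7.5% of
liability variance to the top bins (truth 6% over four bins), with the
additive-genetic component decisively supported by the LRT.

The same pipeline is available as a library (`twinewas.run_pipeline`,
`twinewas.fit_liability`, ...) and per-stage subcommands
(`qc`, `stability`, `twincorr`, `ewas`, `correct`, `models`, `liability`).

## Layout

```
src/twinewas/
  simulate.py          synthetic twin-cohort generator (+ ground truth)
  qc.py                zero filter, stability screen, twin correlations
  association.py       discovery / replication / Fisher combination
  multiple_testing.py  Li–Ji effective tests, BY FDR
  models.py            logistic covariate models, ANOVA eta^2
  liability.py         liability-threshold AE decomposition (core model)
  pipeline.py          stage orchestration, artifacts, summaries
  io.py                BED3 / TSV / CSV / JSON round-trip I/O
  cli.py               `twinewas` command-line interface
docs/methods.md        modelling assumptions, defaults, limitations
```
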