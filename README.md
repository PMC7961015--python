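# dcisprofiler

Single-cell phenotyping and breast-cancer-event risk scoring for
multiplexed-immunofluorescence (MxIF) cohorts of ductal carcinoma in situ
(DCIS).

## The problem

DCIS is a non-obligate precursor of invasive breast cancer; most patients
are treated aggressively although only a minority would ever progress.
Iterative MxIF staining quantifies dozens of protein markers in every
segmented cell of a tissue-microarray core, which makes it possible to ask
whether the *cellular composition* of a lesion — rather than bulk marker
levels — predicts a later breast cancer event (BCE).

`dcisprofiler` implements that analysis as a tested, reusable pipeline:

1. **QC filtering** of segmented cell tables: epithelial cells with 1–2
   nuclei, every sub-cellular compartment area strictly between 10 and
   1500 px, and perfect round-to-round registration (per-cell QC score =
   Pearson correlation of baseline vs round DAPI patches; the summary is
   the minimum over rounds).  Fields of view need
   %DCIS/(%DCIS + %Normal) ≥ 0.5; patients need ≥ 100 cells, non-BCE
   follow-up ≥ 3 years, and BCE events < 10 years.  Every stage emits an
   audit with conserved counts.
2. **Preprocessing**: exposure-time correction, log2(x+1), per-slide
   median centring, nuclear-median (ER, PR, p21, Ki67) vs whole-cell-median
   summarisation, then 1%-tail capping and z-standardisation.
3. **Univariate screen**: per-patient mean of cell medians, Welch t-tests,
   Benjamini–Hochberg FDR at q = 0.2.
4. **Consensus k-means phenotyping** of ER/HER2/cMET/SLC7A5 for
   k = 2..15 with PAC (proportion of ambiguously clustered pairs) model
   selection, and canonical relabelling of the six phenotype archetypes.
5. **Escore**: each patient's cluster profile (fraction of cells per
   cluster) feeds a logistic regression of BCE on the percentage
   covariates x₁ = %C5&6 and x₂ = %C2&4.  The linear risk score is

       Escore = b₁·(%Clus5&6) + b₂·(%Clus2&4),   high risk ⇔ Escore > τ

   with τ tied to the cohort base rate: P(BCE) > base rate ⇔
   Escore > logit(base rate) − intercept.  The published model
   (b₁ = 1.77, b₂ = −2.78, τ = 13 at base rate 0.255) ships as a frozen
   constant.  Leave-one-out cross-validation and duplicate-core
   concordance support the fit.
6. **Survival**: Kaplan–Meier disease-free-interval curves of the binary
   Escore groups and the two-group log-rank test.

Because no per-patient data were deposited for the original cohort, the
package includes a first-class **synthetic cohort generator** that
reproduces the study's statistical structure (51 patients, 13 BCE; ~75k
epithelial cells after QC; six cluster archetypes; group-conditional
Dirichlet cluster profiles; slide batch effects; exposure jitter; QC
artifacts) by *inverting the preprocessing chain*, so every downstream
stage is testable against known ground truth.

## Worked example

```python
import dcisprofiler as dp
from dcisprofiler.pipeline import RunConfig, run_pipeline

cfg = RunConfig(outdir="example_run", seed=11, cluster_k=6,
                simulation=dp.SimulationConfig(seed=11))
result = run_pipeline(cfg)
print(f"cells analysed : {result.report['n_cells_analyzed']}")
print(f"patients       : {result.report['n_patients_analyzed']}")
print(f"Escore slopes  : {result.escore_model.slope_c56:+.3f} (%C5&6), "
      f"{result.escore_model.slope_c24:+.3f} (%C2&4)")
print(f"high risk      : {int(result.predictions['high_risk'].sum())} patients")
print(f"AUC {result.metrics.auc:.3f}  LOOCV AUC {result.loocv.auc:.3f}  "
      f"log-rank p {result.logrank.p:.2e}")
```

prints (seed 11):

```
cells analysed : 74086
patients       : 51
Escore slopes  : +0.044 (%C5&6), -0.001 (%C2&4)
high risk      : 14 patients
AUC 0.913  LOOCV AUC 0.816  log-rank p 9.29e-05
```

i.e. ~74k epithelial cells survive QC for the 51 simulated patients, a
higher %C5&6 (HER2-high phenotypes) raises the fitted risk of a second
event, 14 patients land above the base-rate threshold, and the binary
score splits the disease-free-interval curves (log-rank p ≈ 1e-4).
Fitted slope magnitudes depend on the cohort's profile dispersion — on a
widely dispersed simulated cohort they are much smaller than the published
coefficients, which were fitted to the real cohort; the frozen published
model is available as `dp.PUBLISHED_ESCORE` for scoring without
refitting.

The same pipeline is available from the shell:

```bash
dcisprofiler run-all --seed 11 --k 6 --outdir example_run
dcisprofiler simulate --seed 1 --outdir cohort/
dcisprofiler qc --cells cohort/cells.csv --fovs cohort/fovs.csv \
    --patients cohort/patients.csv --outdir qc/
```

## Layout

| module | contents |
| --- | --- |
| `synthetic_cohort` | archetypes, `SimulationConfig`, `generate_cohort`, nuclear patch synthesis |
| `cell_qc` | registration scoring, cell/FOV/patient filters, `FilterAudit` |
| `preprocess` | `MarkerPanel`, exposure/log2/slide normalisation, capping + standardisation |
| `univariate` | patient aggregation, Welch tests, BH-FDR |
| `clustering` | k-means, consensus matrices, PAC, `select_k`, canonical labels |
| `escore_model` | profiles, logistic fit, classification, LOOCV, core concordance |
| `survival` | Kaplan–Meier and log-rank on Escore groups |
| `pipeline` / `cli` | end-to-end orchestration and the `dcisprofiler` command |

See `docs/methods.md` for the modelling assumptions and numerical
conventions.
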