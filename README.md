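# lipidyn

Longitudinal plasma lipidomics analysis: from raw targeted-MRM transition
intensities to biological associations.

Deeply sampled human cohorts now profile hundreds of plasma lipid species
per participant over years, through health, respiratory viral infections
and ageing. `lipidyn` implements the full analysis path such a study needs,
as a tested, reusable Python library:

* **Extraction** — each scheduled MRM transition is acquired 20 times;
  transitions with more than two zero recordings are treated as not
  available, the rest summarized by the mean of the nonzero recordings and
  matched to lipid species on (method, polarity, Q1, Q3, scan index).
* **Quantification** — concentrations (nmol/ml) from deuterated spike-in
  standards: `conc = (analyte / spike) × spike_conc`, with the analyte
  signal halved for complex lipids with two identical fatty acyls (their
  fragment ions report at 2× intensity). Poorly detected standards
  (missingness > 5%) are substituted within class; classes without a
  matched standard are normalized against a surrogate chosen by a
  correlation hierarchy on QC samples and scaled by a pooled
  log-log regression.
* **QC filtering and imputation** — technical/biological CVs, the sample
  (>25% missing) and species (<10% valid, QC CV > 20%, QC CV above the
  biosample CV) filters, class exclusions, and a left-censoring-aware
  truncated-normal KNN imputation bounded by per-class detection limits.
* **Analysis layers** — participant variance decomposition (ICC) and
  personalized-lipid selection; co-abundance modules (soft threshold →
  topological overlap → average-linkage modules → eigengenes → merge) with
  covariate-adjusted clinical correlations; SSPG (insulin resistance),
  infection-phase, cytokine–lipid and ageing (Δage) regressions;
  IR-vs-IS differential correlations; infection trajectory clustering with
  elbow-selected k-means; direction-split Fisher enrichment of
  physicochemical annotations (saturation, omega class, chain parity,
  small/large TAG, constituent FA).
* **Synthetic cohort generator** — a first-class module that emulates the
  study's statistical structure (class-structured abundances over 4 orders
  of magnitude, class-specific ICC, low technical CV, left-censored
  missingness, planted ageing/SSPG/infection/cytokine effects) and writes a
  ground-truth ledger, so every layer is testable offline.

The core quantitative conventions: CV = 100·sd/mean on untransformed
concentrations; ICC = σ²ᵦ/(σ²ᵦ+σ²ₑ) from the one-way unbalanced ANOVA
estimator; TOMᵢⱼ = (Σᵤaᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ); the ageing model
regresses baseline-subtracted ln concentrations on Δyears with a 5-year
percent change of 100·(e^{5β}−1); IR means SSPG > 150 mg/dl.

See `docs/methods.md` for the full model descriptions, defaults and
limitations.

## Worked example

Run the whole pipeline on a synthetic study:

```python
import lipidyn as L
from lipidyn.pipeline import run_pipeline

data = L.simulate_study(L.SimulationConfig(seed=1))
res = run_pipeline(data, seed=1)
print(res.intensity.shape)
print(len(res.filter_report.robust_species))
print(dict(zip(res.filter_report.dropped_species["species"],
               res.filter_report.dropped_species["reason"])))
```

prints

```
(320, 152)
147
{'LPE(15:0)': 'low_validity', 'TAG51:1-FA20:5': 'low_validity',
 'DAG(14:0/15:0)': 'high_qc_cv', 'DAG(16:1/22:4)': 'qc_cv_exceeds_bio_cv',
 'PI(16:0/18:3)': 'excluded_species'}
```

— 320 samples (280 biosamples + 40 QC) by 152 analysed species; 147
species survive filtering, and every dropped sample/species is exactly one
of the generator's planted QC violations (plus the platform's excluded
species). The concentrations recovered for spike-quantified species match
the planted truth with a median relative error of ~2.4%.

Association layers read a concentration matrix plus metadata. At a
power-reasonable design (70 participants, one SSPG visit each, half of 30
species carrying a planted standardized effect of 0.5):

```python
res = lipidyn.models.sspg_regression(conc, metadata)
res[res["significant"]].head(3)[["species", "beta", "p", "fdr"]]
```

```
      species     beta            p      fdr
PC(15:0/15:0) 0.615602 1.953182e-07 0.000006
PC(16:0/20:4) 0.422452 5.006118e-04 0.001502
PC(16:1/17:0) 0.371601 2.827774e-03 0.007069
```

All 15 significant species (BH FDR < 5%) are exactly the 15 planted ones,
with a median recovered |β| of 0.465 — the planted 0.5 attenuated slightly
by the z-scaling of the response.

A thin CLI wraps the same functions:

```sh
lipidyn simulate --seed 5 --out bundle/
lipidyn analyze sspg conc.csv bundle/metadata.csv --out sspg_results.csv
lipidyn analyze ageing conc.csv bundle/metadata.csv --level class --out ageing.csv
```

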