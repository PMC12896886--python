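# csctargets

Discovery and characterization of cancer-stem-cell (CSC) surface antigens
as antibody targets, packaged as a tested, reusable pipeline.

Tumors such as colorectal carcinoma harbor a resilient stem-like
subpopulation that survives conventional therapy and seeds relapse.  A
practical route to drugging these cells is transcriptomic: compare
stem-phenotype CSCs (sCSC, spheroid-grown) against their serum-
differentiated counterparts (dCSC) and against normal colon, tumor tissue
and conventional cancer cell lines; keep genes encoding membrane-accessible
proteins; and validate the shortlist by qPCR and antibody binding assays.
This package implements every computational step of that workflow and a
synthetic-data module that generates multi-platform studies with known
ground truth, so the whole pipeline is testable without access to
proprietary array data.

## What's inside

| module | contents |
|---|---|
| `csctargets.simulate` | multi-platform expression studies with planted targets/decoys, Ct tables, dose-response curves, sensorgrams |
| `csctargets.normalize` | quantile normalization; global rank-invariant set normalization (GRSN) |
| `csctargets.integrate` | best-match probe mapping across array platforms; parametric empirical-Bayes batch adjustment (ComBat-style, with exposed γ/δ² estimates); medoid/MAD sample pruning; PCA diagnostics |
| `csctargets.rankprod` | rank-product differential expression, permutation pfp, per-class fold changes |
| `csctargets.funnel` | the five-stage membrane-target prioritization funnel with YES/MAYBE/NO ratings and target/biomarker categories |
| `csctargets.qpcr` | 2^-ΔΔCt relative quantification and the 3-fold CSC-specificity call |
| `csctargets.assays` | one-site binding (Bmax, KD), 4PL competition (IC50), 1:1 SPR kinetics (ka, kd, KD = kd/ka), µg/mL ↔ nM conversion |

The statistic at the core of the discovery step is the rank product: for
classes A and B, each pairwise sample comparison ranks genes by fold
change, and

&nbsp;&nbsp;&nbsp;&nbsp;RP(g) = (∏ₖ rank_k(g))^(1/K)

over the K comparisons; small RP means consistent up-regulation.
Significance is controlled by the false positive prediction
pfp(g) = E_perm[#{RP ≤ RP(g)}] / rank(g), an FDR-like quantity estimated
by within-gene permutation, with the funnel's first cut at pfp ≤ 0.1.

## Worked example

```python
import csctargets as ct

# a two-platform study: 2,000 genes, 25 planted membrane targets,
# 25 tumor-shared membrane decoys, platform batch effects
cfg = ct.StudyConfig(seed=0, n_planted_targets=25, n_planted_decoys=25)
study, annotation, truth = ct.gen_expression_study(cfg)

adjusted, est = ct.combat_adjust(study, ct.BatchDesign.from_study(study))
report = ct.run_funnel(adjusted, annotation, ct.FunnelConfig(seed=0))
print(report.counts)
final = set(report.final_ranked)
print(len(final & set(truth.planted_target_ids)),
      len(final & set(truth.planted_decoy_ids)))
```

prints

```
{'deg_up_csc': 49, 'membrane': 49, 'consistency': 24, 'scored': 24, 'final': 24}
24 0
```

— 49 genes pass the sCSC-vs-dCSC rank-product cut (the 25 targets, the 25
decoys minus one borderline gene, all membrane-annotated so stage 2 keeps
them); the consistency stage against normal and tumor classes removes the
tumor-shared decoys; and the final ranked list recovers 24 of the 25
planted targets with zero decoys.

The same pipeline as a narrative analysis lives in `analysis/`
(`01_simulate_study.py` … `06_assay_characterization.py`); each script
prints what it found and writes its tables under `results/`.  A `csctargets`
command-line interface wraps the individual steps
(`csctargets simulate|normalize|integrate|de|funnel|qpcr|assay --help`).

On the assay side:

```python
dr = ct.gen_dose_response("one_site", {"bmax": 5.0, "kd": 0.2},
                          [0.06, 0.12, 3.0, 15.0], noise_sd=0.0)
fit = ct.fit_one_site(dr, mw_kda=150.0)
print(fit.params["kd"], fit.params_nm["kd"])   # 0.2 µg/mL, 1.33 nM
```

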