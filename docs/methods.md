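# Methods

This package re-implements, as a tested pipeline over synthetic data with
known ground truth, the computational workflow used to discover and
characterize antibody-accessible surface targets on colorectal cancer stem
cells (CSCs): cross-platform microarray integration, rank-product
differential expression with permutation-based false-positive-prediction
(pfp) control, a staged membrane-target prioritization funnel, 2^-ΔΔCt qPCR
validation, and the nonlinear binding-assay models used on the resulting
antibody candidates.

## The synthetic study

Real discovery studies of this kind combine a proprietary CSC microarray
dataset with public colon expression datasets measured on two array
architectures.  Because such data cannot be redistributed, every analysis
here runs on data from `csctargets.simulate`, which emulates the study
design with explicit ground truth:

* **Expression model.**  Gene-wise log2 baselines are Normal(8, 1.5) —
  the typical post-summarization intensity scale of expression arrays —
  with additive class effects in log2 space and Gaussian residual noise
  (default SD 0.5 log2).
* **Tissue classes.**  Samples are drawn from a fixed vocabulary
  (sCSC, dCSC, normal, normal_lcm, normal_crypt, tumor, tumor_lcm,
  tumor_crypt, cell_line, stem_ref).  Defaults: 8 sCSC, 8 dCSC (matching
  the eight patient-derived CSC lines such studies start from, each grown
  as stem spheroids and as serum-differentiated counterparts), 10 normal,
  4 LCM normal, 10 tumor, 4 LCM tumor, 8 cell lines.  Class sizes beyond
  the CSC lines are not dictated by any published design and are exposed
  in `StudyConfig`.
* **Planted truth.**  `n_planted_targets` genes (default 25) gain
  `planted_log2fc` (default 1.5) in sCSC samples only and are annotated as
  clean membrane targets; `n_planted_decoys` genes gain the same effect in
  sCSC *and* in tumor-like classes (tumor, LCM tumor, tumor crypt, cell
  lines), so they imitate tumor-shared antigens that the consistency stage
  must reject.
* **Batch effects.**  Each platform contributes a gene-wise additive shift
  (Normal(0, 1.5) log2 by default) and a gene-wise multiplicative variance
  factor (Uniform(0.8, 1.25)) applied to the residual noise.  The batch
  model deliberately mirrors the correction model so that parameter
  recovery is well-posed and measurable.
* **Platform assignment.**  By default every tissue class alternates
  between two datasets on different platforms, keeping the batch/covariate
  model identifiable.  Designs in which a class sits entirely on one
  platform (the realistic worst case) can be built with
  `dataset_of_class`; the adjustment then raises an explicit confounding
  error rather than silently absorbing biology into the batch term.
* **Outliers.**  A configurable fraction of samples is displaced by a
  constant 4 log2 units on a random 25% of genes, producing unambiguous
  medoid-distance outliers for the pruning step.
* **What is not modeled:** probe-level effects (the pipeline starts at
  probe-set matrices), scanner artifacts, RNA degradation, correlated
  gene–gene structure, and platform-specific probe sensitivity beyond the
  location/scale batch model.  Passing tests therefore demonstrate
  correctness of the algorithms under the stated generative model, not
  performance on any particular real dataset.

All generators are deterministic given one integer seed, with one
generator stream per artifact.

## Normalization

`quantile_normalize` maps every sample onto the mean of the sorted
intensity vectors (average ranks for ties); it is idempotent and leaves
identical arrays unchanged.

`grsn_normalize` implements global rank-invariant set normalization:
probes with the largest cross-sample rank variance are discarded over 10
sweeps on a geometric schedule until 25% of probes remain, and each array
is corrected against the approximated common reference (the per-probe mean
of the quantile-normalized samples) through a nondecreasing curve fitted on
the invariant set.  The correction curve is an interpolating polyline
through the invariant points whose reference ordinates are
monotone-adjusted by isotonic regression (PAVA).  This choice replaces a
fixed-span running-line smoother that was evaluated first: with a span
fraction of the points, the smoother's bandwidth in intensity units
explodes in the sparse distribution tails, leaving ~0.8 log2 residual on a
pure monotone distortion (v → v + 0.5·sin v).  The PAVA polyline has no
bandwidth: where noise breaks monotonicity, pool-adjacent-violators
averages neighboring points (acting as a local smoother — it halves a
distorted array's median residual in a six-array noise check), while
already-monotone data pass through exactly, so undistorted arrays are
preserved to machine precision.  Ranks on the invariant set are preserved
weakly (ties may be introduced by pooling).

## Batch-effect adjustment

`combat_adjust` is the standard parametric empirical-Bayes location/scale
model.  Per gene, expression is standardized by a covariate-adjusted mean
(intercept + one-hot tissue classes, first class as reference) and pooled
variance; per-batch additive effects γ and variance factors δ² are
estimated and shrunk toward a normal and an inverse-gamma prior
respectively, hyperparameters by method of moments, with the usual
iterative conditional update (tolerance 1e-6).  Batches default to the
array platform; `batch_by="dataset"` combines platform and dataset id.
Covariate levels confined to one batch raise `ConfoundingError`.
The implementation agrees with scanpy's ComBat to ~1e-5 per entry in the
covariate-free case (scanpy's categorical-covariate path mis-centers its
output in this environment, so the cross-check is run without covariates).

One property worth stating precisely: parametric ComBat is **not**
idempotent at tight tolerance.  On a second pass the raw batch effects are
statistically null, but the EB shrinkage re-contracts the residual sampling
spread of the per-gene variance factors, moving values by ~0.1 log2 at
desk scale (the reference implementation behaves identically).  The test
suite therefore asserts what is true: a second pass is a strong contraction
(<10% of the first pass's largest change) and leaves the additive batch
separation removed.

## Sample pruning

`medoid_mad_prune` restricts heterogeneous groups to samples "within one
MAD of the medoid".  Distances are Euclidean over the 1,000 most variable
genes, z-scored.  The medoid (sample minimizing total pairwise distance)
is always retained.  The retention threshold is median + 1·MAD of the
group's nonzero pairwise distances (`strict=True` uses the bare MAD, a
much harsher cut that empties typical groups).  A sample's deviation is
measured as its distance to the medoid's **denoised profile** — the
gene-wise group median — rather than to the raw medoid sample: at array
dimensionality the medoid's own measurement noise enters every distance,
pairwise and to-medoid distances then concentrate at the same radius, and
the one-MAD margin is only ~2 SD of the tight-sample spread, so a clean
group of ten loses a sample by chance in roughly one run in five.  Against
the denoised center the inlier radius drops by ~√2 while the threshold
(derived from pairwise distances) does not, giving a wide, stable margin.
The literal single-sample reading remains available via
`center="medoid"`.

## Rank-product differential expression

For classes A and B, every pairwise (a, b) sample comparison yields
per-gene log2 fold changes, ranked across genes within the comparison
(rank 1 = strongest change in the analyzed direction, average ranks for
ties).  The rank product is the geometric mean of a gene's ranks over the
K comparisons, computed in log space.  K is capped at 200 pairs by seeded
subsampling.  Both directions are reported, along with the mean log2 fold
change.

The pfp (false positive prediction) of gene g is the permutation-expected
count of genes with RP ≤ RP(g), divided by g's position in the observed RP
ordering — an FDR-like quantity.  The null shuffles each gene's values
across the pooled samples independently, B = 100 permutations by default.
pfp is reported raw (not monotonized) so that it matches exhaustive
enumeration exactly; `monotonize=True` applies a cumulative-minimum
step-down.  An `exhaustive` mode enumerates the full product of per-gene
sample permutations for oracle-level verification at toy sizes.

Under the exchangeable null, the pfp at observed rank r estimates
(expected false positives at that threshold)/r ≈ 1; the acceptance suite
verifies this calibration at ranks 20/100/400 over 50 simulations and
checks the pfp ≤ 0.1 acceptance set against its expected-false-positive
budget.

## The prioritization funnel

Five nested stages reduce the gene universe to a ranked shortlist:

1. **deg_up_csc** — genes up-regulated in sCSC vs dCSC at pfp ≤ 0.1;
2. **membrane** — transmembrane or GPI-anchored annotation;
3. **consistency** — pfp ≤ 0.1 *and* positive fold change in the
   CSC-versus-class comparison for every configured class (default:
   normal and tumor);
4. **scored** — the YES/MAYBE/NO rating: NO if any criterion fails
   outright (linear fold change < 2 vs tumor or cell lines, any vital
   organ at high expression, extensive shedding, unfavorable knowledge);
   YES if all four criteria are favorable (fold change ≥ 2, all vital
   organs low, limited shedding, favorable knowledge); MAYBE otherwise.
   Genes whose only shortfall is vital-tissue expression are categorized
   B (biomarker — useful diagnostically even if not safely druggable);
   all others T (therapeutic target).  The threshold is applied
   inclusively (≥ 2.0);
5. **final** — NO-rated genes are dropped (unless listed in the per-gene
   `overrides`, which exists because published shortlists keep a few
   genes on judgment calls no rule expresses), genes failing the
   immunogenicity / ectopic-expression / paralog-similarity screens are
   dropped, and the rest are ranked YES-first, then by ascending rank
   product vs dCSC.

Annotation fields (`membrane_status`, per-organ expression levels,
shedding, knowledge score, screen flags) are categorical inputs supplied
with the study, not computed from external atlases; the rating rubric is a
faithful reconstruction of the described semantics, encoded as explicit,
testable rules.  Membrane status is settled once at stage 2; stage 4 is
pure scoring.

Under the default benchmark conditions (2,000 genes, 25 planted targets at
1.5 log2, 25 tumor-shared decoys, batch effects corrected first) the final
list recovers ≥ 88% of targets on average with ≤ 3 decoys per run across
ten seeds.

## qPCR validation

`ddct_quantify` implements 2^-ΔΔCt: per line, ΔCt = mean Ct(gene) − mean
Ct(housekeeping); ΔΔCt references a designated CSC line; RQ = 2^-ΔΔCt,
also expressed as percent of the reference.  Amplification efficiency is
fixed at 2.0 per cycle; no standard-curve correction.  Replicates are
averaged on the Ct scale by default (`per_replicate` switches to
per-replicate RQ combined by geometric mean — identical for balanced
designs since the geometric mean of 2^-x is 2^-mean(x)).

`specificity_call` renders the validation rubric as a two-part AND:
(1) ≥ 3 CSC lines at ≥ 3-fold the normal-colon control, and (2) the median
CSC RQ at ≥ 3-fold the RQ of ≥ 4 cancer cell lines; `acceptable` needs
both, `partial` exactly one, `rejected` neither.  The prose this rubric
comes from is grammatically ambiguous; the single-criterion reading is
obtained with `min_cancer_lines=0`.  The median-over-CSC-lines aggregate
in part (2) was chosen to make the call monotone in CSC expression.

## Binding-assay models

* **One-site saturation** Y = Bmax·X/(KD + X); EC50 ≡ KD.  Bmax is
  profiled in closed form over a log-spaced KD grid, then both parameters
  are polished by Levenberg–Marquardt.  A flat response is flagged
  (`flat-response`) with parameters withheld — KD is unidentifiable.
* **4PL competition** Y = bottom + (top − bottom)/(1 + (X/IC50)^hill),
  multi-start over an IC50 log-grid × hill set, hill unconstrained in
  sign, top/bottom bounded by the data range ± 20%.
* **SPR 1:1 kinetics** with closed-form association
  R(t) = C·ka·Rmax/(C·ka + kd)·(1 − e^−(C·ka+kd)t) and exponential
  dissociation; global least squares across concentrations in log10(ka),
  log10(kd), Rmax from a fixed multi-start grid.  KD = kd/ka by
  construction.  A kd estimate pinned at its lower bound (default 1e-6/s)
  is flagged `dissociation below detection`, mirroring how very slow
  off-rates exceed instrument limits.
* **Units.**  `mass_to_molar` converts µg/mL to nM as c/MW·1000 with a
  150 kDa IgG default.  Published EC50 tables for such antibodies print a
  mass column labeled mg/mL beside an nM column; the paired values are
  mutually consistent only under µg/mL at 150 kDa (0.18 ↔ 1.2 nM), so the
  package treats that header as an erratum and works in µg/mL.  The
  competition-assay nM column of the same source is *not* consistent with
  any single MW and is not used as a reference anywhere.

All optimizers are deterministic (seedless multi-start from fixed grids).
Noiseless round trips recover generating parameters to 1e-6 relative;
under 5% multiplicative noise the median relative error of KD/IC50 stays
below 15% over 100 seeds at the published concentration grids
(4-point titration 0.06–15 µg/mL; 8-point 1:3 dilutions 0.014–30 µg/mL;
five SPR concentrations, 180 s association / 800 s dissociation).

## Problem sizes

Simulations run at desk scale by choice: 2,000 genes, ~50 samples, 100
permutations, 10–50 seeds per property.  These sizes are large enough for
every calibration band used in the tests while keeping the whole suite and
the acceptance script each inside a few minutes on one CPU.

## Known limitations

* The pfp permutation null treats genes independently; correlated genes
  would make pfp anticonservative, as with the original method.
* GRSN's invariant-fraction (0.25) and sweep count (10) are defaults in
  the spirit of the cited approach; the original publication's exact
  parameters are not recoverable from the source describing the workflow.
* The funnel's qualitative criteria are only as good as the annotation
  table; no attempt is made to score immunogenicity or shedding from
  sequence.
* The SPR model is pure 1:1 Langmuir: no mass-transport limitation,
  bivalent analyte, or avidity effects (dimeric ligands are fit as if
  monovalent, which is exactly why slow apparent off-rates get flagged
  rather than interpreted).
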