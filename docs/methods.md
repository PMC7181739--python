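# Methods

## Model and procedure

`methcorr` treats a gene's expression as predictable from the methylation
state of CpG sites that co-vary with it across tumors — whether the
coupling is a functional regulatory interaction or an indirect consequence
of cell-type composition (cell-type-specific expression co-varying with
cell-type-specific methylation through the mixture of cell types in the
sample). The procedure is:

1. split the cohort into discovery set 1 (40 %), discovery set 2 (40 %) and
   a validation set (20 %);
2. in each discovery set independently, compute the Spearman correlation ρ
   (average-rank tie handling) between each gene's log2(FPKM+1) expression
   and each CpG's β-value, with a two-sided p-value from the large-sample
   t approximation on n−2 degrees of freedom;
3. keep (gene, CpG) pairs with p < 0.01 and sign-concordant ρ in both sets;
   per gene and sign, rank pairs by |ρ| within each set, order by rank sum,
   truncate to 100; genes lacking either sign are dropped;
4. compress each gene's CpGs into the MethCORR score
   MCS = mean of β over positive CpGs and (1 − β) over negative CpGs;
5. regress expression on MCS (polynomial degree 1–4, OLS on raw powers),
   selecting the degree by mean held-out RMSE over 10 repeats of 10-fold
   cross-validation with a ≥ 5 % relative-improvement requirement for any
   polynomial over the linear model; refit the selected degree on the full
   discovery set; accept the gene when R² > 0.16 in both discovery and
   validation;
6. infer expression in new samples by evaluating the accepted polynomial at
   the sample's MCS;
7. build the gene map: edge (i, j) iff
   0.5·Overlap + 0.5·Jaccard of the two negative CpG sets is ≥ 0.126.

## Assumptions

- Expression–methylation coupling is monotone enough for rank correlation,
  and stable between the two discovery halves; requiring dual-set
  significance *and* sign concordance replaces any multiple-testing
  correction (raw p < 0.01 with replication).
- Discovery and application samples share the coupling structure (same
  tissue/disease context); applying a matrix across array platforms only
  needs tolerant probe dropping, not re-discovery.
- The β-value scale is comparable across samples (normalization is assumed
  done upstream; array preprocessing is out of scope).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | per-set Spearman significance cutoff (two-sided p) |
| `max_per_sign` | 100 | CpGs kept per gene per correlation sign |
| `fractions` | 0.4/0.4/0.2 | discovery-1 / discovery-2 / validation split |
| `cv_repeats × cv_folds` | 10 × 10 | cross-validation scheme for model selection |
| `rmse_improvement` | 0.05 | relative RMSE gain a polynomial must give |
| `r2_min` | 0.16 | acceptance gate on discovery and validation R² |
| `map_cutoff` | 0.126 | inclusive combined-similarity threshold for edges |
| `impute_k` | 10 | neighbours for KNN β imputation |

## Numerical and design choices

- **R² definition.** R² is the squared Pearson correlation between predicted
  and observed expression (matching correlation-style reporting), not
  1 − SS_res/SS_tot; for a refit linear model the two coincide on the
  training set but differ on held-out data. Configurability was not needed
  because every consumer in the package uses the same definition.
- **Ranking metric.** Within a discovery set, CpGs are ranked by |ρ|
  (positive and negative lists are ranked separately by strength). Rank-sum
  ties break by larger mean |ρ|, then lexicographic probe ID, making
  selection a total order independent of input order and platform.
- **Sign concordance between discovery sets is required** (configurable):
  a sign flip between halves contradicts a reproducible association.
- **p-values at |ρ| = 1** are clamped to the smallest positive double to
  respect the (0, 1] contract of the t approximation.
- **Cross-validation folds** depend only on (seed, repeat, n, folds) and are
  shared across genes, so one global seed reproduces every gene's fold
  assignment. Per-fold OLS solves the normal equations with a pseudoinverse
  (batched across genes); degree ≤ 4 on MCS ∈ [0, 1] keeps conditioning
  acceptable without orthogonalization. Final coefficients come from
  refitting the selected degree on the full discovery set — CV is used only
  for selection.
- **Degenerate inputs.** Constant-MCS genes are rank-deficient and rejected
  with NaN metrics; constant observed expression yields undefined R² and
  rejection; zero-variance genes/probes in the Spearman scan produce NaN ρ
  records that are excluded from selection; constant genes get NaN
  z-scores and are listed as flagged.
- **Imputation.** Missing β-values are filled by row-wise KNN over probes
  (Euclidean distance on mutually observed samples, donors restricted to
  probes observed at the target sample, k = 10, mean of donors, clipped to
  [0, 1]), written in-package because the scikit-learn imputer's
  column-oriented convention does not match this row-wise behaviour.
- **Percentile/IQR convention** is linear interpolation between closest
  order statistics everywhere (NumPy default); stated explicitly so users
  can match other conventions. The segment CIN score interprets "mean IQR"
  as the mean of per-chromosome IQRs over chromosomes with ≥ 4 qualifying
  segments; a whole-sample single-IQR mode is available.
- **QMSP risk directions.** The assays amplify unmethylated template, so
  high ΔCT means high methylation. CRC1 is called high-risk at
  ΔCT_CD3E ≥ 19.5 (T-cell depletion); CRC2 at ΔCT_ACTA2 < 15.55 or
  ΔCT_PDPN < 13.5 (CAF/EMT abundance). The directions are fixed by the
  primer chemistry but remain configurable through the cutoff mapping.
- **Storage.** All artifacts are plain TSV with a mandatory header, floats
  at 10 significant digits (bitwise round-trips at that precision), missing
  β as empty/NA, and a `# config_hash=` stamp on pipeline outputs. No
  binary container is provided; TSV is the canonical interchange format and
  the matrices at this package's scale do not warrant one.

## Synthetic data: what it emulates and what it does not

The generator produces cohorts with the two coupling mechanisms the method
relies on, plus nulls:

- **direct** genes: a latent promoter activity u ~ Uniform(0.1, 0.9) drives
  expression (RNA = B0 + B1·u, B0 ~ U(0.5, 2), B1 = 4) and is written into
  two driver CpGs, β = 1 − u (negative driver) and β = u (positive driver);
- **celltype** genes: samples are Dirichlet(1) mixtures of cell types; each
  type hypomethylates its marker CpGs (β 0.1 vs. 0.8, a forced Δβ ≥ 0.3)
  and expresses its own genes (~8 vs. ~1–3 log2 units), so expression and
  marker methylation co-vary only through the mixture;
- **null** genes: N(3, 1) expression independent of methylation.

β noise is Gaussian truncated (clipped) to [0, 1] (sd 0.05 by default),
chosen over a logit-normal model for transparency of the ground truth;
expression noise sd defaults to 0.28, about 0.3× the direct-gene signal sd
(|B1|·sd(u) ≈ 0.92). A fraction of β entries (≤ 5 %) can be masked missing
to emulate failed probes.

Not emulated: realistic probe-manifest genomic coordinates, batch and
fixation artifacts beyond i.i.d. noise, copy-number–methylation coupling,
and the long-tailed count structure of real RNA-seq. Passing tests on these
cohorts therefore demonstrate the correctness and calibration of the
machinery (recovery of planted couplings, null rejection rates), not
expected performance on any real tumor cohort.

## Problem sizes used in the test and acceptance runs

The end-to-end runs use 240 samples × 2,000 probes × 300 genes (100 direct,
100 cell-type, 100 null) — the package's chosen study conditions for a
fully self-contained cohort. Statistical calibration uses 200 replicates at
n = 300 for parameter recovery and discovery/validation sizes 316/78
(mirroring a 394-sample cohort's 80/20 split) for the acceptance gate, with
500 informative and 1,000 null genes.

## Known limitations

- Genome-scale inputs (4×10⁵ probes × 2×10⁴ genes) need a chunked Spearman
  scan; the current implementation materializes the full gene × probe
  correlation matrix per discovery set, which is fine up to a few thousand
  probes × thousands of genes in memory.
- The KNN imputer is quadratic in probes with missing data; acceptable for
  the supported matrix sizes, slow at full array scale.
- Detection p-value QC requires the caller to supply per-cohort p-value
  tables; the package does not compute detection p-values from raw IDATs
  (array preprocessing is out of scope).
- The β-value-based risk thresholds on "normalized" β scales are exposed
  only as generic threshold rules; the package does not reconstruct any
  particular normalization.
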