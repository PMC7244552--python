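# Methods notes

## Load model and anchoring

A sample's total microbial load is reconstructed from the dPCR reading of
the extraction eluate:

    load = c · V_elution · (V_dead / V_loaded) / m        [16S copies / g]

where `c` is the eluate concentration in copies/µL, `V_dead / V_loaded ≥ 1`
corrects for loading only part of the lysate on the extraction column
("lysate produced / lysate loaded"), and `m` is the input mass in grams.
The semantics of the dead-volume ratio are deliberately user-facing: whether
it is measured before or after bead-beating losses is a property of the
protocol, not of this package, so it is carried as a plain ratio.

Anchoring multiplies each taxon's relative read abundance by the total
load. Relative abundances come from the **raw** counts — rarefaction is
reserved for beta-diversity distances, where unequal depths would otherwise
bias zero probabilities. Row sums of the anchored table equal the dPCR
totals by construction (this is asserted in tests at 1e-9 relative
tolerance). Per-taxon accuracy offsets against taxon-specific truth (e.g. a
consistent 2.5× amplification difference for a mucin-degrading genus) are
*reported* by `error_analysis` as the mean log2 error, never auto-corrected:
a constant offset cancels in group comparisons made under one protocol, and
silently "fixing" it would hide a real property of the assay.

Measurement precision is summarised as `fold_precision = 2^(1.959964·s)`
where `s` is the sample sd (ddof = 1) of mean-centered log2 errors; an sd of
0.48 gives 1.92 ≈ 2×, i.e. individual measurements are trustworthy to about
a factor of two at 95% confidence. Normality of the centered errors is
screened with Shapiro–Wilk.

## Quantitative limits

* **Replicate %CV.** For ≥2 technical replicates of one specimen, each
  taxon contributes (mean relative abundance, %CV) with sd at ddof = 1.
  With n = 4 replicates the %CV saturates at 200% when a taxon appears in a
  single replicate — a useful sanity bound on the curve's left edge.
* **Power-law threshold.** `%CV = a·x⁻ᵇ` is fit by ordinary least squares
  in log–log space (closed-form testable; zero-CV and zero-mean points
  cannot enter a log fit and are excluded, as optionally are flagged
  contaminants). The quantitation threshold at CV level `L` is
  `(a/L)^(1/b)` percent. On noiseless power-law input the fit recovers
  (a, b) to 1e-6 in log space.
* **Poisson floor.** With expected count λ = N·p the counting CV is
  100/√λ percent, giving the closed-form threshold `p = (100/L)²/N` — at
  L = 30% and N = 28,000 reads, 0.04% relative abundance, i.e. ~11 reads.
  The bootstrap band (`poisson_ci_band`) draws, per grid abundance, 10,000
  sets of 4 Poisson variates and reports the middle 95% of their %CV.
* **Depth scaling.** `threshold_vs_depth` rarefies the replicates to each
  depth (multivariate hypergeometric, seeded), refits, and regresses
  log threshold on log depth to estimate γ in `threshold ∝ depth^(−γ)`.
  Under the generator's pure counting noise the 30%-CV crossing sits at a
  fixed expected read count, so the threshold falls essentially as
  1/depth (γ ≈ 1.0 measured). Real replicate data often decay more slowly
  (nearer √depth), which is what extra, depth-independent technical noise
  in library preparation produces; a pure multinomial replicate model
  cannot reproduce that slower decay, and this is a known limit of what the
  simulator demonstrates about real data.
* **LLOQ per gram** divides the smallest reliably-extractable copy input by
  the largest extractable mass; reporting uses round-half-up
  significant-figure rounding (values are canonicalised to 12 significant
  digits first so binary float residue cannot flip a half-up boundary —
  8.3e4/0.2 must round at 2 s.f. to 4.2e5, not 4.1e5).
* **Detection bookkeeping.** "Detected" means ≥1 read. Dropouts are taxa
  present only in a high-DNA-input library; contaminants only in the
  low-input one; blank-derived flags rank taxa by blank prevalence, then
  blank reads, then lexical id (fully deterministic).

## Differential analysis and classes

Taxa present in ≥4 samples of at least one group (or a fraction, for
unequal groups) are tested by Kruskal–Wallis with tie correction. The
default p-value uses the chi-square approximation (df = groups − 1), the
standard backend; `method="exact"` enumerates all two-group assignments
(feasible to 16 pooled samples) for tiny cohorts where the chi-square tail
is unreliable — at n = 3 + 3 the approximate and exact p differ by up to
~0.05 in the tail, which matters at conventional cutoffs. Constant features
get p = 1 by convention and a flag. BH step-up q-values are computed across
exactly the taxa tested in one call, so per-site analyses correct within
site. Fold changes are log2 ratios of *arithmetic* group means of copies/g
(the quantity of interest is the average load, not the average log load);
one-sided zeros route to the presence/absence class instead of a number.

Null calibration: with both groups drawn from one lognormal load
distribution (n = 6 + 6, 1,000 features), 3.9–4.7% of features fall below
p = 0.05 — the chi-square approximation is slightly conservative for
discrete rank statistics at this n, which is the safe direction.

Quantification classes compare two groups' detection and quantification
status: detection requires prevalence ≥ 2/3 (mirroring the 4-of-6
prevalence filter; the group-detection rule is otherwise a free choice and
is exposed as a parameter), and quantification additionally requires the
group *mean* relative abundance to clear the CV threshold at the analysis
depth. Per-group means were chosen over per-sample tests because the class
is a statement about the group-level estimate; per-sample variants can be
built from `group_summary` directly. The class map is total over the valid
detection/quantification lattice and monotone: raising the LOQ threshold
can only demote quant → semi-quant → no-quant.

## Ordination

CLR uses natural logs and a pseudocount of 1 read added to counts. For
absolute tables the scale-consistent pseudocount is one read's worth of
load, `total_load/read_depth` per sample; with that choice CLR of the
anchored table is identical to CLR of the counts, so Aitchison distances
agree between the relative and absolute branches exactly (tested to 1e-8).
This is the compositional fact that anchoring cannot change CLR-based
ordination; absolute information enters ordination through the plain log
transform instead, which preserves between-sample scale.

PCA is an eigendecomposition of the sample covariance; feature loadings are
eigenvectors scaled by √eigenvalue, so the loadings matrix reconstructs the
covariance in the full-rank case (tested at 1e-8). Eigenvector signs are
fixed by making each vector's largest-magnitude entry positive. Taxon
impact on the PC1/PC2 plane is the Euclidean norm of the loading pair
(interpreting "sum of the loading vectors" as the vector sum's magnitude);
an absolute-sum variant is exposed as `method="abs_sum"`. Bray–Curtis +
PCoA (classical MDS via scikit-bio) are provided for comparison on rarefied
relative data. Spearman networks take the top-30 taxa by mean load plus
the total load, BH-correct across all pairs, and emit edges at q < 0.1;
ties use average ranks and constant features stay NaN.

## Simulator

The generator is the package's ground-truth instrument, emulating the
measurement chain, not read-level artifacts:

| parameter | default | rationale |
|---|---|---|
| depth | 28,000 reads | typical per-sample amplicon depth |
| replicates | 1 (4 for %CV studies) | matches technical-replicate designs |
| group size | 6 | common small-cohort animal study |
| taxa (two-group study) | 20, loads 1e6–1e10 copies/g | desk-scale genus-level span of gut contents |
| taxa (%CV study) | 50, abundances spanning 4.5 decades | populates the CV curve down past the detection limit |
| biological scatter | lognormal, σ(ln) = 0.35 | ~1.4× subject-to-subject geometric spread |
| dPCR noise | Poisson on aliquot copies | pure counting statistics; ~10% CV at 100 copies |
| library input | 1.2e7 copies | high-input regime where contaminants are invisible |
| contaminants | 40 copies × 3 taxa per prep | calibration default that surfaces contaminants below ~1e4 input copies (≈0.4% share), not a measured value |
| amplification bias | off | optional per-taxon multiplier to emulate primer-coverage offsets |

Contaminants are *fixed absolute copies per library prep* — the single
assumption that makes contaminant share rise as sample input falls, and
blank libraries consist of them alone. Noise-free mode replaces Poisson and
multinomial draws with (rounded) expectations, giving exact identity
pipelines for oracles. All randomness flows from the one config seed; equal
configs produce bit-identical studies.

What the simulator does **not** model — and therefore what green tests do
not establish about real data: amplification-cycle kinetics and chimeras,
taxonomic misassignment, overdispersed (beyond-Poisson) library-prep noise
(hence the γ ≈ 1 depth scaling above), partition-volume variance in dPCR,
and extraction-efficiency chemistry.

Statistical power note: with n = 6 + 6 the smallest attainable two-group
Kruskal–Wallis chi-square p is ≈0.0039 (full rank separation), so a single
true positive among m tested taxa can reach q < 0.1 only when m ≲ 25. The
default 20-taxon community keeps the benchmark power-analysis-consistent;
an 8× shift is recovered at q < 0.1 in ~100% of runs.

## Numerical and interface choices

* Rarefaction is sampling **without** replacement (multivariate
  hypergeometric via numpy), a single seeded draw per sample; seeds are
  mandatory wherever randomness exists because none of the procedures are
  deterministic otherwise.
* %CV and error sds use ddof = 1 throughout; the 95% z is fixed at
  1.959964.
* TSV layout: taxa as rows, samples as columns, first header `taxon_id`;
  BIOM input is accepted behind the same reader when the optional `biom`
  package is installed. All-zero taxa are retained by default (they carry
  presence/absence information against blanks and replicate sets).
* The p-value scatter comparing relative vs absolute analyses uses raw
  Kruskal–Wallis p on both axes with q-values reserved for significance
  calls; the discordance flag triggers at |log10 p-ratio| > 2.5.
* Degenerate inputs: zero-depth samples are an error at anchoring;
  all-zero samples CLR-transform to zero rows with a warning; λ = 0 grid
  points in the bootstrap band are skipped with a warning; both-zero group
  means make a fold change an error rather than a NaN that could silently
  propagate.

## Problem sizes

The test suite and the acceptance script run simulations at desk scale by
design: 100-seed power sweeps of 12-sample studies, 1,000-feature null
panels, 10⁵ dPCR draws, and single %CV studies of 4 × 28,000-read
replicates. These sizes give stable estimates (binomial se of a 100-seed
recovery rate ≈ 4 points; se of the null rate at 1,000 features ≈ 0.7
points) while keeping a full run in seconds.
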