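# Methods

## The analysis rules

### Counting and species abundance

A read assigned to *k* genes contributes 1/*k* to each, so total counts are
conserved exactly per sample. Species abundance is a per-sample fraction
after a layer-specific density normalisation: genome length (bp) for the
metagenome; coding bases excluding rRNA regions for the metatranscriptome
(rRNA is depleted experimentally and removed computationally upstream, so
including those bases would deflate rRNA-rich genomes); nothing for 16S
(one count = one read — deliberately no 16S copy-number or amplicon-length
correction, and the simulator draws 16S reads proportional to abundance so
the estimator is unbiased under its own observation model); summed filtered
protein intensity over the per-sample total for the metaproteome, with
species lacking any detected protein reported as 0 and flagged not-detected
rather than silently merged with true zeros.

### Taxon-specific scaling

The goal of this normalisation is to decouple within-species functional
composition from taxon abundance before differential analysis. We define it
as the feature's relative abundance divided by its species' relative
abundance in the same sample. With the default species profile — the
species' share of the same count table — this reduces algebraically to the
feature's within-species fraction and is exactly invariant to rescaling one
species' abundance while holding its composition fixed; that invariance is
asserted as a test. A different profile (e.g. the genome-normalised one) may
be supplied, at the cost of exact invariance. Features of species undetected
in a sample are masked NaN, never zero, and stay masked through correlation
(pairwise deletion).

### Protein quantification

Species-level uniqueness is the filter: a peptide matching proteins of two
or more species is discarded; a peptide shared among proteins of a single
species counts for each of them. Within a protein, peptides are ordered by
the number of samples with a positive intensity, with ties broken by higher
mean intensity, then lexicographic peptide sequence — a total order, so the
result is invariant to input row order (tested). The per-sample abundance is
the mean over the top three peptides with missing values excluded per sample
rather than imputed as zero, matching intensity-based DIA reporting; a
protein with fewer than three eligible peptides is discarded.

### Metabolite annotation

The matching tolerance is interpolated linearly in m/z between the two
instrument anchors (1 mDa at m/z 50, 5 mDa at m/z 1000, clamped outside);
only the range endpoints are physically anchored, and a linear profile is
the simplest monotone interpolation. Adducts: [M−H] and [M−2H] in negative
mode (we read [M−2H] as doubly charged, hence (M − 2·1.007276)/2), and
[M+] (= M − m_e), [M+H], [M+Na] (+22.989218), [M+K] (+38.963158) in positive
mode; each candidate is replicated with 0–2 ¹³C substitutions at +1.003355 Da
on the neutral mass. Annotation is deliberately many-to-many — MS1-only
acquisition cannot resolve isomers, so one ion may match many metabolites
and vice versa.

Filtering keeps annotated ions, removes ions whose *every* annotation
carries a ¹³C substitution, and retains one representative ion per
metabolite. The representative rule is made deterministic: Spearman
correlation with the total ion current (robust to the heavy-tailed intensity
scale) when computable for at least one candidate, otherwise largest mean
intensity; remaining ties break by smaller |Δm| then lower m/z.

Quantile normalisation is performed separately per polarity (the two modes
are acquired as separate runs with different electrospray behaviour). Tied
values within a sample receive the mean of the reference values they would
have occupied; as a consequence the "all columns share one multiset"
property holds exactly only for tie-free columns.

### Concordance statistics

Cross-layer agreement pools all (species, sample) pairs present in both
layers into one Spearman ρ; an optional floor keeps pairs where both
abundances reach it. Sample distances are 1 − Spearman between samples over
feature vectors, after dropping features with mean abundance below a
per-layer floor (1e−7 for gene- and transcript-level features, 1e−5 for
proteins, 0 for species-level profiles). The Mantel statistic is the Pearson
correlation of the upper triangles; the one-sided p-value jointly permutes
rows/columns of the second matrix with a seeded generator and uses the
add-one estimator (1 + hits)/(1 + n_perm), with 999 permutations as the
default. Logistic growth fitting uses least squares on
L/(1 + exp(−k(t − t₀))) with deterministic initialisation (L = max OD, t₀ at
half-max, k from the finite-difference slope at t₀, using slope = Lk/4 at
the midpoint); degenerate series return a failure flag with a message
instead of raising.

### Differential selection and enrichment

Fold changes are computed on raw values, log2((treated + ε)/(control + ε)),
averaged over matched replicate pairs (same run, timepoint, replicate
index); ε defaults to half the smallest nonzero value of the table so
zero-vs-zero gives 0. Selection takes, per feature, the single measurement
with maximum |log2FC| over the time course, then applies the layer cuts
(transcripts |log2FC| > 2 at pFDR < 0.001; proteins and metabolites
|log2FC| > log2(1.5) at pFDR < 0.05) and splits by sign. Enrichment is a
two-sided Fisher exact test per set over a universe defined as all features
passing the layer's abundance floor (detected at least once by default),
BH-adjusted across sets, run once per direction; for metabolomics the sets
are keyed by ion id so an ion annotated to several metabolites of one
pathway counts once.

The permutation feature test is plumbing: the original analysis used
external differential machinery (negative-binomial Wald tests for
transcripts, repeated-measures models for proteins/metabolites), which this
package deliberately does not reimplement. To let the pipeline run
end-to-end it substitutes a paired sign-flip test on matched-pair log1p
differences, two-sided, add-one estimator, BH across features. Adjusted
p-values from any external tool can be passed in instead. Because the test
is discrete (minimum p = 1/(1 + n_perm)), the transcript cut at pFDR < 0.001
needs a large permutation count; the pipeline uses 19,999 sign-flip draws
(vectorised, so this is cheap) while hypothesis-testing calibration uses the
conventional 199.

## The simulator

### What it emulates

The study design: a stabilised 32-species community (6 labelled
Bacteroidota, the drug-susceptible phylum; the real community had six
depleted Bacteroidota members), drug added in exponential phase, sampling at
0/15/30 min and 1/3/43/91 h after addition, two full experimental runs (A/B)
in duplicate — 56 samples. Ground truth consists of species abundance
fractions, within-species expression fractions for transcripts and (lagged)
proteins, and metabolite concentrations.

Key generator defaults, chosen once to emulate the study conditions:

| parameter | default | rationale |
|---|---|---|
| baseline abundance | log-normal, σ = 2, renormalised | reproduces the few-dominant-species structure (4 species > 10%) |
| depletion | 0.25 per 24 h reference time, as depletion^(t/t_ref) | multiplicative per unit time is the simplest mechanism giving a progressive, strong depletion by the 43/91 h samples |
| induced KO set | one 10-KO pathway | stands in for the stress-response regulon |
| induction fold | 8 | comfortably above the 4-fold transcript selection cut |
| induction profile | per-gene, per-timepoint exponent in fold^U, U ~ Uniform(0.5, 1.5) from the first post-treatment timepoint | a response whose shape varies over time; makes the lag identifiable, since a constant step would leave all post-lag timepoints statistically indistinguishable |
| transcript→protein lag | 1 timepoint | the protein induction profile is exactly the transcript profile shifted by one timepoint |
| proteome detection | top 30% of proteins per species by mean expression | emulates low metaproteomic depth (about 9% of predicted proteins detected community-wide in the study; ≤ 30% for the best-covered species) |
| shared peptides | 10% of peptides attached to a second species | exercises the species-uniqueness filter |
| multi-mapped reads | 5%, partner gene from the same species | exercises count splitting without biasing species-level sums |
| mass error | Gaussian, σ = tol(mz)/3 | keeps essentially all ions within tolerance while exercising the matching window |
| peptide ionisation factors | log-normal, σ = 0.5 | per-peptide response spread; part of the noise model, so the noise-free regime recovers protein abundance exactly |

All randomness flows from a single seed through named, independent
`SeedSequence` streams per layer, so outputs are bit-identical across runs
and adding one layer never perturbs another.

Reference metabolite masses are rejection-sampled so that all enumerated
candidate m/z values of distinct metabolites stay ≥ 20 mDa apart (≥ 4× the
maximum tolerance). This makes noise-free annotation unambiguous and gives
the generator a clean recall oracle; real references (HMDB-scale) are far
denser, which is precisely why real annotation is only tentative.

### What it does not emulate

Control compositions are constant over time within a run (no community
growth dynamics, no run-to-run exponential-phase divergence); there is no
strain-level variation, no read-level sequence simulation (no FASTQ), no
chromatography or retention time, no medium-background ions, and species
never protect each other from the drug. Passing tests therefore demonstrate
the correctness and calibration of the analysis rules under the stated
observation models — not performance on real data, where reference
incompleteness, compositional artefacts and batch effects dominate.

## Numerical choices and degenerate inputs

Fractions are renormalised per sample and asserted to sum to 1 within 1e−9.
Division by an undetected species yields NaN masks, never zeros. Spearman
uses average ranks for ties throughout; correlations over constant vectors
are undefined and masked. The Mantel test refuses < 4 samples; pooled
Spearman refuses < 3 shared pairs; the lagged correlation refuses < 10
shared features. The sigmoid fit flags non-increasing series and
non-physical parameter signs rather than raising. Problem sizes in the test
suite are chosen deliberately: 8-species communities for unit tests, the
full 32-species experiment at depth 1e6 (noise-free) for ground-truth
recovery, 200 replicates × 199 permutations for null calibration, matching a
3σ binomial band around α = 0.05.

## Known limitations

- The taxon-specific scaling formula is this package's own minimal
  definition satisfying the stated invariance; published scalings built on
  relative expression differ in detail.
- The lag is recovered from the argmax of the lagged correlation at the
  early, closely spaced timepoints (15 min–1 h). At the late timepoints
  (43/91 h) fold changes are dominated by species depletion rather than
  induction, and the argmax is not informative about the lag there.
- Fisher enrichment assumes feature exchangeability within the universe;
  with correlated features (peptides of one protein, ions of one metabolite)
  the dedup rules reduce but do not remove dependence.
- `[M+]` vs `[M+H]` and the charge state of `[M−2H]` are conventions, fixed
  here as M − m_e and z = 2 respectively.
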