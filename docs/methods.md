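# Methods

This note documents the models, parameter choices and numerical decisions
behind `ampliclone`, and what the simulator does and does not emulate.

## Genotype calling model

A cell's observation at one amplicon is a pair (ref_reads, alt_reads);
coverage is their sum and scVAF = alt / coverage, kept as an exact ratio.
Because the first PCR cycles can favor one allele, heterozygous scVAFs are
not concentrated at 0.5 but spread over roughly 0.01–0.99; and polymerase/
sequencing error gives WT cells a small nonzero scVAF. The calling scheme
therefore measures the per-locus error empirically from WT spike-in control
cells co-processed on every plate and sets:

* `wt_threshold = mean + k·SD` of the control scVAFs (k = 3 by default,
  SD with n−1 denominator — the source describes only "SD");
* `mutant_threshold = wt_threshold + margin` (margin = 0.01 scVAF);
* `hom_mutant_threshold = 1 − mutant_threshold`.

Coverage floors are 50 reads for gDNA and 30 for cDNA amplicons; a mutant
call additionally needs ≥ 10 mutant reads. Decision order: low coverage →
UNDETECTED; scVAF **strictly** below the WT cutoff → WT; at or above the
mutant cutoff with enough mutant reads → MUT (HOM_MUT when the hom cutoff
is also reached at a diploid locus); everything else → UNDETERMINED. The
strict WT comparison is a deliberate boundary convention: the source of the
rule is ambiguous at the exact cutoff, and pushing the boundary case into
UNDETERMINED is the conservative direction. Hemizygous loci (e.g. an
X-linked BCORL1-style target) never receive the het/hom distinction.

gDNA and cDNA calls are combined by a fixed rule table: mutant in either
analyte → MUT; both WT → WT; gDNA WT with an uninformative cDNA → WT; cDNA
WT with an uninformative gDNA → UNDETERMINED (cDNA amplicons have a much
higher dropout rate, so a lone cDNA WT is weak evidence); nothing
informative → UNDETERMINED. UNDETERMINED cells are excluded from
genotype-stratified analyses rather than imputed.

Threshold derivation requires ≥ 30 control cells per locus (the assay
co-sorts roughly 10% of wells as controls but states no floor; 30 gives a
usable SD estimate).

### False-positive validation

The mutant cutoff is validated by bootstrap-resampling the control scVAFs
(1000 replicates by default, seeded), fitting each resample to a beta
distribution by the method of moments, and recording the upper-tail
probability beyond the mutant cutoff. Beta support is open, so zero scVAFs
are nudged to half the smallest positive value for the locus; an all-zero
(noise-free) control distribution has false-positive probability 0 by
definition and the fit is skipped. Degenerate moment configurations
(variance ≥ m(1−m)) also skip the fit.

### Minima-based alternative

For loci with a well-populated trimodal all-cell scVAF distribution
(reference-only, biallelic, variant-only), cutoffs can instead be placed at
the two interior minima of a Gaussian KDE (Silverman bandwidth, 1001-point
grid on [0, 1], which caps cutoff resolution at 0.001). When a
control-derived WT cutoff is supplied it is kept, so the minima strategy
only moves the mutant cutoff: cells between the WT cutoff and the lower
minimum become undetermined, never WT. Distributions without a three-peak
structure raise an error directing users back to the control strategy.

## Allelic dropout

ADO is modeled (and simulated) as pre-amplification whole-allele loss,
independent per allele. Two estimators:

* **SNP method.** A germline heterozygous SNP on the same gDNA amplicon is
  called Hom Ref / Het / Hom Alt with cutoffs derived from WT-control
  (Hom Ref) cells exactly as for mutations
  (`alt_detection = mean + 3·SD + 0.01`, mirrored for Hom Alt). The SNP is
  phased against the mutation by the sign of the Pearson correlation of
  their scVAFs over cells with both amplicons detected (both readouts share
  the cell's amplification skew). Significance is a two-sided test at
  α = 0.05 with ≥ 20 paired cells; non-significant loci are "ambiguous" and
  excluded from rescue rather than guessed. Per-allele rates are the
  fractions of genotyped cells called Hom Ref (Alt-allele dropout) and
  Hom Alt (Ref-allele dropout). Apparently-WT cells whose SNP call shows
  loss of the mutant-bearing haplotype are reassigned to UNDETERMINED with
  a `mutant_allele_ADO` flag; mutant calls are never touched.
* **Hom-frequency method.** Assuming the mutation heterozygous, homozygous
  calls arise only from WT-allele loss:
  `WT ADO rate = n_hom / (n_het + 2·n_hom)`. For dual-analyte loci a cell
  counts as homozygous only when every detected analyte looks homozygous.

Both estimators converge to a/(1+a) for per-allele rate a (cells losing the
counted allele of interest versus all genotyped cells), i.e. they slightly
understate a for large a; at the rates seen in practice (≤ 0.15) the bias
is below 0.02 and the two methods agree, which is itself a property test.
Per-allele symmetry is a simulator default, not a runtime constraint.

## Clonal hierarchies

The genotype matrix (cells × mutations; MUT/WT/MISSING) is scored against
every rooted labeled mutation tree — enumerated via Prüfer sequences,
(m+1)^(m−1) trees for m mutations, m ≤ 6 — under a per-entry error model
with false-positive rate fd = 0.01 and dropout rate ad = 0.02 by default
(matching common single-cell tree-inference settings). Each cell's
likelihood is the uniform average over attachment nodes of the product of
per-entry probabilities; MISSING contributes 1. This exhaustive search
replaces MCMC, which is only needed for many mutations; within the
exhaustive regime the maximum is exact. Ties are broken toward fewer branch
points (linear over branching), then lexicographic parent vector.

Cells are assigned to the unique clone consistent with their detected
mutant set. An extra clone mutation may be UNDETERMINED (missing data) or
WT-called **if ancestral to a detected mutation** — the latter is an
inferred ancestral dropout, capped at `max_ancestral_ado` (default 1) and
tagged `ado_rescued`. WT-called extras below the deepest detected mutation
are never allowed (dropout of a detected descendant is impossible), which
is what makes the deepest consistent clone the right target for rescue.
Cells with several consistent clones (undetermined data at a
tree-discriminating locus) or none (e.g. mutant calls on two branches) are
unassignable and excluded downstream.

## Clone abundance

At cluster level the relative likelihood of being mutant is the mutant:WT
odds — the discrete analogue of a smoothed density ratio; graph-diffusion
smoothers and Bayesian composition tests are deliberately out of scope, as
they are generic external methods rather than part of this analysis. The
normalized likelihood divides each cluster's odds by the reference
(HSC/MPP) odds, so the reference is 1 by construction; cells of descendant
clones carry the parent clone's mutations and count as mutant for it.
Computation is per sample first, then averaged across samples. Uncertainty
comes from a percentile bootstrap over cells resampled within sample
(default 1000 replicates, seeded); clusters whose CI excludes 1 are
flagged. The bulk utility converts VAF to clone fraction as 2·VAF for
autosomal heterozygous loci (capped at 1 with a warning above VAF 0.5) and
VAF unchanged for hemizygous loci.

## Driver rules

Variant post-processing is a pure rule engine over annotated input columns
(COSMIC counts, population AF, InterPro membership are inputs, not live
lookups, keeping runs offline and reproducible). VarDict calls need 5
variant reads for SNVs (≥ 2 per strand; 10 and ≥ 4 per strand for indels),
base quality ≥ 30, mapping quality ≥ 40 (waived for U2AF1/U2AF1L5, which
are multi-mapped in hg38 due to the gene duplication), strand-bias Fisher
p ≥ 1e-4 and no position bias; Mutect2 calls must pass all default filters
except possibly `clustered_events`, plus the same read-support rule.
Germline/artefact flags: population AF > 0.001 (max across the three
population databases — the conservative combination), the VAF bands
0.4–0.6 and > 0.9, panel-of-normals membership, and cohort recurrence
(≥ 3 samples by default; the source states no number) — each with
somatic-evidence rescues as encoded in `flag_germline_or_artefact`.
Surviving variants are drivers if any of eight rules fires; all rule IDs
are recorded so every classification replays from its trace. Across
callers, union-keep is the default (the flags, not caller agreement,
remove artefacts); intersection is available. CALR "exon 9" is
operationalized as truncating variants at protein residues 352–417. The
compiled CH-mutation list referenced by the flag rules ships as an empty
user-supplied table. Sample CH status = ≥ 1 driver at VAF ≥ cutoff
(default 0.02), with counts also reported at the 0.01 and 0.02 bands.

## Simulator

Per cell: cluster ~ configured fractions; clone ~ per-cluster clone
probabilities (remainder WT); per amplicon: coverage ~ negative binomial
(gDNA mean 500, cDNA mean 150, dispersion 2 — chosen so the default
coverage filters retain roughly 95% of wells), an allele-sampling fraction
~ Beta(1.2, 1.2) reproducing the 0.01–0.99 heterozygous scVAF spread,
independent per-allele dropout (gDNA 0.05, cDNA 0.25 — cDNA amplicons drop
out far more often; both-allele loss leaves the amplicon empty), and WT
noise drawn from a beta with mean `error_rate` (default 7.2e-4, shape 2.3,
matched to the worked-example control moments at high coverage) feeding a
binomial read draw. A linked SNP shares the gDNA amplicon's skew and
dropout events, so phase correlations arise mechanistically. WT-control
cells (10% of wells, spread over plates) are WT at somatic loci and
Hom Ref at SNPs. Empty wells (2% of wells by default) emit at most 2 reads
per amplicon. A `deterministic` locus mode (no skew, exact read split,
even coverage) provides the noise-free limit for exact tests. Outputs are
bit-reproducible from (config, seed).

Not emulated: transcriptome counts and embeddings, doublets, index-sorting
structure, plate position effects, correlated dropout between loci, and
coverage–genotype dependence. Passing tests therefore demonstrate correct
recovery under this generative model, not robustness to every failure mode
of real plates — thresholds on real data should still be inspected per
locus (the threshold table and FP validation exist for exactly that).

The label-perturbation utility relabels a seeded simple random sample
(default 10%) of mutant cells as WT, emulating the genotyping-error
sensitivity analysis; on simulated data this attenuates cluster-level
enrichment at most mildly and preserves the ranking of enriched clusters.

## Problem sizes used in the checks

The bundled tests and acceptance script run entirely on synthetic or
printed-value inputs: simulations of 200–10,000 cells, 100-replicate tree
recovery at 500 cells and 3 mutations, bootstrap validations at 200–1000
replicates, and a 10⁶-draw Monte-Carlo tail check — sizes chosen to make
the statistical assertions sharp while keeping the whole suite fast on one
CPU.
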