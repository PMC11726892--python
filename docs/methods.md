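# Methods

## Signal model

Each sequenced molecule carries, at every CpG (indexed by the
plus-strand C; minus-strand calls collapse onto the same site by CpG
palindromic symmetry), a latent state drawn independently as 5mC with
probability `p_m`, 5hmC with probability `p_h`, otherwise unmodified
(`p_m + p_h ≤ 1`). Protection from deamination depends on the
chemistry: RREM protects 5mC and 5hmC; RREhM protects 5hmC only. A
protected base is read as C with probability `1 − e_over` (`e_over`:
spurious deamination of a protected base), an unprotected base as C
with probability `e_fail` (conversion failure), and a base-call flip
with probability `e_seq` is applied last. The expected observed-C
fraction at a site is therefore

    E[level] = q_prot · π + q_unprot · (1 − π),
    q_prot   = (1 − e_over)(1 − e_seq) + e_over · e_seq,
    q_unprot = e_fail (1 − e_seq) + (1 − e_fail) e_seq,

with `π = p_m + p_h` (RREM) or `π = p_h` (RREhM). Defaults
`e_fail = e_over = 0.005`, `e_seq = 0.001` are plausible
enzymatic-conversion magnitudes; the spike-ins exist precisely because
such rates must be estimated per run, and QC reports them without
correcting the levels (deliberately — the analysis consumes raw
levels, and the limitation is stated here rather than hidden behind an
implicit correction).

## Synthetic study

`generate_genome` builds uppercase DNA at ~42% GC with 80% of
background CG dinucleotides disrupted, reproducing the CpG depletion
of mammalian genomes so that reduced representation is meaningful;
CCGG sites are planted on average every 500 bp (the invariant is ≥ 1
per 5 kb); CpG islands are CG-rich rewritten segments exempt from
depletion. Gene models (3–6 exons of 150–300 bp separated by 0.5–3 kb
introns) provide promoter (1 kb upstream of the first exon), exon and
intron intervals; LINE (~3 kb), SINE (~200 bp) and LTR (~500 bp)
intervals are placed at a configurable total density (default 10% of
the genome, split evenly). Raw intervals may overlap; flattening is
the annotation module's job. Two spike-in contigs, `lambda_spike`
(3 kb, fully unmodified) and `pUC19_spike` (2.7 kb, fully
CpG-methylated), are fixed sequences independent of the study seed,
CpG-dense, with MspI sites every 250 bp so they survive size
selection.

`generate_truth` draws baseline `p_m` from a two-component beta
mixture — 75% of sites from Beta(0.4, 15), 25% from Beta(5, 5) — so
that most sites sit below 10% modification while a minority are
"dynamic" (20–80%); baseline `p_h` is Beta(0.5, 24.5) (mean 0.02).
Group effects shift `p_m` or `p_h` additively at a seeded random
subset of main-genome CpGs (default: +0.20 on `p_h` in DKO at 2% of
sites, +0.15 in WT-AOX, +0.25 plus a +0.15 `p_m` effect in DKO-AOX —
the hyper-hydroxymethylation pattern the study design is meant to
expose, with magnitudes that clear the differential delta of 0.1 at
depth ~30). Every applied shift is recorded in a ledger
(site, group, target, requested and realized delta) for recovery
tests; clipping keeps `p_m + p_h ≤ 1`.

MspI digestion cuts at `C^CGG` (one cut coordinate per occurrence);
pre-selection fragments tile each contig exactly, including the two
contig-end fragments, and size selection retains lengths in
[40, 400] bp inclusive. Depth is Poisson per site (default mean 30;
spike-ins ×10) rather than derived from fragment-end placement — the
analysis consumes per-site counts only, so fragment-level placement
would add cost without testable content. Reads are emitted as
site-call records (read id, contig, CpG position, C/T) at true
coordinates; alignment is bypassed by design.

The lesion track emulates a binned (100 bp) log2 enrichment ratio of
oxidative-lesion (8-OHdG) sequencing between two conditions: bin
values are Normal(0, `noise_sd`) with an additive `effect` on bins
overlapping designated regions; the default run leaves it independent
of the methylation truth, which is exactly the null the co-enrichment
verdict must not reject.

## Calling and filters

Levels are `n_modified / depth` per site. The depth window (10–100×)
and the dynamic window (20–80%) are both inclusive at both ends — the
source conventions say "between" without stating inclusivity, and
inclusive bounds make boundary behaviour testable. The 5mC-only
estimator is the clipped subtraction `max(0, level_RREM −
level_RREhM)` at sites covered in both assays; no variance is
propagated and no formal deconvolution is attempted, so individual
site estimates are noisy and slightly biased upward near zero (the
clip); the estimator is unbiased in the mean at moderate levels, which
is what the tests assert. Sites covered in only one assay are counted
and reported, never imputed. Level histograms use bins
[0, 0.1), …, [0.9, 1.0] with the last bin closed.

Spike-in QC pools counts per spike contig (sites with depth ≥ the
lower depth bound; at least 20 sites required) and reports apparent
modification with Wilson 95% intervals. For RREM, pUC19 measures
protection efficiency (ideal `1 − e_over`); for RREhM, pUC19's 5mC is
unprotected, so its apparent modification should match `e_fail` — a
built-in specificity control. Lambda above 2% apparent modification
raises a warning flag.

## Differential testing

Group levels are pooled over replicates, `mu_g = Σ n_i / Σ d_i`. The
variance uses the beta-binomial form

    Var_g = Σ_i d_i · p̃(1 − p̃) · (1 + (d_i − 1)φ) / (Σ_i d_i)²

with `p̃ = mu_g` clamped to `[1/(D+1), D/(D+1)]` (`D` = group total
depth), which keeps the variance positive at boundary proportions.
The Wald statistic `(mu1 − mu2)/√(Var1 + Var2)` is referred to the
standard normal, two-sided.

Dispersion φ is estimated per site by method of moments across
replicates within each group (equating the sample variance of
replicate proportions to its beta-binomial expectation), combined
across groups weighted by degrees of freedom `m = Σ_g (r_g − 1)`,
floored at 0, and shrunk toward the genome-wide 10%-trimmed mean φ̄:
`φ_shrunk = (m·φ_site + k·φ̄)/(m + k)`, default `k = 10`. With three
replicates per group the raw per-site estimate has ~4 degrees of
freedom and is essentially noise; the shrinkage weight was chosen so
that the stabilized estimate tracks φ̄ while still letting strongly
dispersed sites stand out. This explicit moment/shrinkage scheme
replaces the Bayesian shrinkage of the reference differential-
methylation package, and the delta criterion is a hard effect-size
filter `|diff| ≥ 0.1` (inclusive) combined with BH-adjusted `p ≤
0.05` (inclusive), rather than a posterior-probability criterion: the
stated analysis parameters are "no smoothing, delta 0.1, FDR ≤ 0.05",
and the replacement is fully specified and testable. Null calibration
(type-I error within [0.03, 0.07] at nominal 0.05) and power (≥ 70%
recovery of Δ = 0.3 at depth 30, 3v3, φ = 0.01) are asserted by the
acceptance tests.

DMR merging is a greedy scan: chain consecutive same-direction
significant loci with inter-locus gaps ≤ 100 bp; accept a chain when
its span is ≥ 50 bp, it has ≥ 3 members, and members are ≥ 50% of all
tested loci inside the span. These defaults mirror the reference
package's documented region defaults. The scan is verified against an
exhaustive maximal-run enumerator on randomized inputs.

## Annotation enrichment

Precedence (promoter > CpG island > exon > intron > LINE > SINE > LTR
> intergenic) is a configurable stand-in for an external annotator's
undocumented internal priority; intergenic is the complement, so the
flattened labeling is a partition of every contig. Enrichment is
log2(observed/expected) where expected fractions come from the
replicate's own depth-filtered assayed background — reduced
representation makes the assayed background very different from the
genome, so using genomic base composition would manufacture spurious
enrichment. Zero observed (or expected) categories get a
pseudo-fraction of half a site, flagged in the output.

Group comparisons use an exact two-sided Mann–Whitney permutation test
(mid-ranks, full enumeration up to combined n = 12; tie-corrected
normal approximation above). With 3 vs 3 replicates the smallest
attainable exact p is 2/C(6,3) = 0.1; the module reports this floor
alongside every comparison because any significance claim below it at
that replication cannot come from this test — a real discrepancy with
published asterisks down to p < 0.001 at n = 3, which the package
makes explicit rather than reproducing.

## Co-enrichment

Window scores are length-weighted means of track bins over
[pos − 50, pos + 50), clipped at contig ends and divided by the
clipped length; bins absent from a sparse bedGraph count as zero.
Bins overlapping the window contribute by overlap length (whether a
bin must instead be fully contained is unstated in the source
conventions; overlap weighting is the continuous choice and is linear
in the track, a property the tests exploit). The null set is a
seeded uniform draw, equal in size to the DML set, from the assayed
5hmC pool excluding DML. The verdict is "no co-enrichment" iff the
DML-score median is within τ = 0.1 of zero (τ operationalizes "score
close to zero" and is configurable) and the Mann–Whitney p against
the random set is ≥ 0.05. Per-chromosome summaries use only bins with
value ≠ 0, with Tukey whiskers capped at the data range.

## Pipeline and determinism

One flat key-value YAML config covers the whole run; unknown keys are
rejected and all range errors are reported together. Per-stage seeds
derive from CRC32 of "stage-name/global-seed" (kept below 2³¹), so
stages are independently rerunnable and a full rerun is byte-identical
(all floats are written with a fixed `%.6g` format). Coordinates are
0-based half-open in memory and in BED/bedGraph; coverage tables on
disk are a Bismark-coverage-compatible dialect (header line; contig,
1-based position, strand `+`, n_modified, n_unmodified).

## Problem sizes and what the tests show

Default study: 2 chromosomes × 1 Mb, 4 groups × 3 replicates × 2
assays at mean depth 30 — about 11 M site calls, a deliberate
desk-scale stand-in for the >1.5 M-CpG scale of a real
reduced-representation study. Simulated data share the analysis's
statistical structure (beta-binomial replicate variability, the
two-assay protection arithmetic, feature-structured backgrounds) but
not real-genome sequence composition, mappability, strand biases, or
fragment-level coverage correlation; passing tests therefore validate
the statistical machinery and its calibration, not alignment-era
artifacts. The acceptance studies use 5 000 sites for calibration and
power, 600 sites for the 5mC-only estimator, 200 randomized inputs
for the DMR enumerator check, and 300 loci for co-enrichment.

## Known limitations

- No FASTQ/quality/adapter/PCR-duplication modeling; no chemical
  (bisulfite) mode.
- The 5mC-only subtraction ignores sampling correlation between the
  paired assays and clips at zero.
- The Wald test assumes per-site independence; no covariates or
  paired designs.
- The per-site moment dispersion estimate is only informative through
  its shrinkage prior at three replicates.
- The co-enrichment verdict threshold τ = 0.1 is a pragmatic
  operationalization, not an estimated quantity.
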