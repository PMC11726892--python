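# rremtools

Simulation and analysis of paired **RREM-seq / RREhM-seq** experiments —
reduced-representation enzymatic methyl and hydroxymethyl sequencing of
CpG methylation (5mC) and hydroxymethylation (5hmC), as used to study
oxidative-stress-driven epigenetic change in sperm DNA.

In enzymatic-conversion libraries, protected cytosines read as **C** and
unprotected cytosines are deaminated and read as **T**. The two paired
chemistries differ in what they protect:

* **RREM-seq** protects both 5mC and 5hmC — its signal at a CpG is
  `p_m + p_h`;
* **RREhM-seq** protects 5hmC only — its signal is `p_h`.

Both libraries are reduced-representation: the genome is digested with
MspI (`C^CGG`) and 40–400 bp fragments are retained. Unmethylated lambda
DNA and CpG-methylated pUC19 are spiked in so conversion error rates can
be estimated from sequence of known modification state.

The package covers, as a tested library plus CLI:

* **`rremtools.simulate`** — a fully synthetic desk-scale study:
  annotated multi-chromosome genome (promoters, exons, introns, CpG
  islands, LINE/SINE/LTR repeats), per-CpG `(p_m, p_h)` truth with
  group effects and a recovery ledger, in-silico MspI digestion and
  size selection, conversion-aware read simulation for both assays
  with spike-ins, and a binned (100 bp) log2-ratio oxidative-lesion
  (8-OHdG) track.
* **`rremtools.calling`** — per-CpG C/T counting, depth filtering
  (10–100×, inclusive), spike-in QC with Wilson confidence intervals,
  dynamic-CpG selection (levels in 20–80%), level histograms, and a
  clipped-subtraction 5mC-only estimate `max(0, level_RREM − level_RREhM)`.
* **`rremtools.differential`** — per-site beta-binomial Wald tests
  without smoothing. A locus is a DML when the Benjamini–Hochberg
  adjusted p ≤ 0.05 **and** |Δ| ≥ 0.1; significant same-direction loci
  are merged into DMRs (span ≥ 50 bp, ≥ 3 member CpGs, inter-locus gap
  ≤ 100 bp, ≥ 50% of tested CpGs in the span significant).
* **`rremtools.annotation`** — one genomic-feature category per CpG by
  precedence (promoter > CpG island > exon > intron > LINE > SINE >
  LTR > intergenic), per-category percentage distributions, log2
  observed/expected enrichment against the assayed background, and an
  exact Mann–Whitney test (with the explicit p-floor of 0.1 at three
  replicates per group).
* **`rremtools.coenrich`** — lesion signal around candidate loci:
  length-weighted mean of track bins over ±50 bp windows, a random
  non-DML null drawn from the assayed 5hmC pool, Mann–Whitney
  comparison and a co-enrichment verdict, plus per-chromosome boxplot
  summaries over non-zero bins.
* **`rremtools.pipeline` / `rremtools.cli`** — one flat YAML config
  drives `simulate → qc → call → dml/dmr → annotate → coenrich` with a
  machine-readable run report; one global seed makes every output file
  byte-reproducible.

## Worked example

```python
from rremtools import pipeline

cfg, errs = pipeline.validate_config({
    "n_chromosomes": 1, "chromosome_length": 200_000, "island_count": 6,
    "groups": "WT,DKO", "seed": 7, "effects": "DKO:p_h:0.05:0.3",
})
report = pipeline.run_all(cfg, "demo_run")
```

The config gives the DKO group a +0.3 hydroxymethylation shift at 5% of
CpGs. Spike-in QC (`demo_run/qc/spikein_qc.tsv`) recovers the simulated
conversion error rates (`e_fail = e_over = 0.005`, `e_seq = 0.001`):

```
     sample  lambda_apparent  puc19_apparent
 RREM_WT_r1         0.005752        0.994019
RREhM_WT_r1         0.005748        0.005783
 RREM_WT_r2         0.005809        0.994378
```

Lambda (fully unmodified) shows ~0.6% apparent modification — the
conversion-failure plus sequencing-error floor. pUC19 (fully
CpG-methylated) reads ~99.4% modified in RREM, but only ~0.6% in RREhM:
5mC is *not* protected in the hydroxymethyl chemistry, so the spike-in
also verifies assay specificity. The differential stage then reports

```
RREM_DKO_vs_WT:  tested 1245, hyper 50, hypo 0
RREhM_DKO_vs_WT: tested 1245, hyper 55, hypo 0
```

— hyper-hydroxymethylated loci in DKO, visible in both chemistries
because the RREM signal contains 5hmC. Because the simulated lesion
track is independent of the DML here, the co-enrichment stage returns
`dml_median ≈ -0.05, mw_p ≈ 0.76, verdict "no co-enrichment"`.

The same run is available from the shell:

```bash
rremtools all --config demo.yaml --outdir demo_run
```

## Limitations

The simulator emits site-call records at true coordinates (alignment is
out of scope), models depth as per-site Poisson rather than
fragment-placement coverage, and does not model PCR duplication,
quality scores, or chemical (bisulfite) conversion. Error rates are
reported by QC but deliberately not used to correct levels. See
`docs/methods.md` for the full model description and design decisions.
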