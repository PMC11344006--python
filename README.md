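# vntrkit

Tools for characterizing **protein-coding VNTR haplotypes** — loci such as
the secreted mucin genes whose giant central exons are built from
degenerate tandem repeats — and for detecting **selection and
haplotype-tagging structure** around them in phased population panels.

The package is aimed at researchers working with haplotype-resolved
long-read assemblies and phased SNP cohorts who need the bespoke steps
between standard tools: projecting reference exons through assembly
alignments, decomposing repeat domains into motif catalogs, and scanning
for the population-genetic footprints (rare-variant excess, extended LD,
heterozygote excess) that repeat loci tend to display.

## What it computes

* **Exon projection** (`vntrkit.projection`) — lift reference exon
  intervals through PAF/CIGAR assembly alignments (edges inside deletions
  snap inward), splice, translate, and classify each predicted protein as
  complete / truncated (internal stop) / incomplete.
* **Domain architecture** (`vntrkit.domains`) — greedy exemplar matching
  of cysteine-rich domains (ungapped identity ≥ 0.8 by default),
  S/T-fraction calling of PTS stretches, copy-number architecture vectors,
  and protein groups (identical architectures, P1…Pk).
* **Motif catalogs** (`vntrkit.motifs`) — fixed-frame tiling of VNTR
  domains into consensus-size motifs (e.g. 8 aa / 24 nt), catalogs with
  occurrence/carrier counts, row- and per-motif-normalized usage matrices,
  UPGMA clustering (node height = half the average inter-cluster
  distance), S/T content, and position-frequency matrices.
* **Selection scan** (`vntrkit.popgen`) — Tajima's D in 10-kbp bins
  (≥ 10 SNPs), percentile flags against an autosome-wide background, and a
  permutation null built from replicate tail-percentile cut points with
  Bonferroni correction; plus Hardy-Weinberg and Pearson chi-square tests
  and VNTR length-class enrichment (< 1,500 bp short, > 2,000 bp long).
* **LD and tag SNPs** (`vntrkit.ld`) — D′ and r² from phased haplotypes,
  MAF/call-rate/HWE site filters, Gabriel-definition haplotype blocks from
  bootstrap confidence intervals on |D′|, block-size percentiles,
  haplogroup pseudo-site encoding, and tSNP discovery (r² strictly above
  the threshold).
* **Synthetic data** (`vntrkit.synthetic`) — generators with exact ground
  truth: motif-grammar VNTR cohorts, constructed-CIGAR alignment fixtures,
  site-frequency-spectrum haplotype matrices, planted LD blocks, and
  diploids with a tunable inbreeding coefficient.
* **Pipelines** (`vntrkit.pipeline`, `vntrkit` CLI) — config-driven
  characterize/scan runs with digest manifests and resumability.

The core statistic is Tajima's (1989) D,

```
D = (π − S/a₁) / √(e₁·S + e₂·S·(S−1)),   a₁ = Σ_{i<n} 1/i,
```

with π the mean pairwise difference count over haplotype pairs and S the
segregating-site count; D is reported as undefined when S = 0 or the
variance term vanishes (exactly the case at n = 2). LD follows Lewontin's
D′ = D/Dmax and the allele correlation r²; blocks follow Gabriel et al.
(strong-LD pairs — CI on |D′| with lower bound ≥ 0.70 and upper ≥ 0.98 —
must be ≥ 95 % of informative pairs).

## Worked example

`examples/` holds one short script per capability. For instance,
projecting exons through an assembly carrying a 24-bp VNTR insertion
(`python examples/01_exon_projection.py`):

```
reference protein: 60 aa
projected protein: 68 aa, status=complete
exon intervals on assembly: [(0, 36), (46, 217)]
length difference: 8 aa (one 24-bp insertion = 8 codons)
```

The insertion lengthens the projected protein by exactly 8 aa — the
codon-count of the inserted sequence — and the ORF stays complete.
Running the scan on a simulated rare-variant-excess region
(`python examples/03_selection_scan.py`) prints one row per 10-kbp bin:

```
     bin       D  SNPs flags              p_emp   p_adj
       0   -2.05    34 bottom10|bottom5  0.0010  0.0100
   10000   -2.51    47 bottom10|bottom5  0.0010  0.0100
   ...
```

Strongly negative D flagged in the bottom 5 % of the background with a
small adjusted p is the footprint the rare-excess spectrum was built to
produce. `examples/04_ld_blocks_tsnps.py` recovers two planted LD blocks
exactly and reports 8 tag SNPs with r² > 0.85 for the encoded haplogroup.

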