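# bsaseq

Significant-SNP bulked segregant analysis for whole-genome sequencing data
(BSA-Seq).

BSA-Seq experiments sequence two pooled DNA samples ("bulks") of
phenotypic-extreme individuals from a segregating population — say, the
most and least cold-tolerant plants of an F2 — and look for genomic
regions where the bulks' allele frequencies diverge.  The widely used
Δ(SNP index) and G-statistic scans test each SNP on its own read depth
and therefore need high sequencing coverage.  This package implements the
*significant-SNP* method: every SNP's 2×2 table of per-bulk REF/ALT read
counts

|        | REF      | ALT      |
|--------|----------|----------|
| bulk 1 | AD_REF1  | AD_ALT1  |
| bulk 2 | AD_REF2  | AD_ALT2  |

is scored with Fisher's exact test; SNPs with p < 0.01 are *significant
SNPs* (sSNPs); and the genome is scanned with the fraction of sSNPs among
all SNPs in 2-Mb sliding windows (10-kb step).  Because each window
aggregates hundreds-to-thousands of SNPs, the scan keeps its power at a
fraction of the coverage the per-SNP methods need.  Significance is
calibrated by simulation under the cross design's null (F2: ALT frequency
0.5 in both bulks; backcross: 0.75/0.25), including finite-bulk sampling
of the bulk allele frequency: a genome-wide threshold from resampled
average-sized SNP sets (99.5th percentile of 10,000 simulated
sSNP/totalSNP ratios at a deliberately liberal in-simulation α = 0.10),
then window-specific thresholds to re-verify each candidate peak.  The
Δ(SNP index) (AD_ALT2/DP2 − AD_ALT1/DP1) and G-statistic
(2·Σ O·ln(O/E)) scans are included as comparators, and a synthetic
two-bulk generator with planted QTLs and Haldane linkage decay makes the
whole pipeline testable end to end without any external data.

## Input

A tab-separated table derived from a joint-genotyped two-bulk VCF with
columns `CHROM POS REF ALT <fb>.AD <fb>.GQ <sb>.AD <sb>.GQ`, where AD
fields are `"REF,ALT"` comma pairs.  One way to produce it:

```bash
gatk VariantsToTable -V bulks.vcf \
    -F CHROM -F POS -F REF -F ALT -GF AD -GF GQ -O bulks.tsv
```

Per-bulk depth is always recomputed as `DP = AD_REF + AD_ALT`.

## Worked example

Simulate a 3-chromosome dataset with one planted QTL (allele-frequency
displacement δ = 0.3 on chromosome 2 at 1.5 Mb, 30× coverage), then run
the scan:

```bash
$ bsaseq simulate --n-chroms 3 --chrom-length 3000000 --snp-density 6e-4 \
      --qtl 2:1500000:0.3 --coverage 30 --seed 42 -o demo
wrote 5333 SNPs to demo.tsv
  QTL 2:1500000 delta=0.3

$ bsaseq run demo.tsv --n-reps 2000 --seed 7 -o out
SNPs analysed: 5333
genome-wide sSNP/totalSNP threshold: 0.1249 (avg 793 SNPs/window)
candidate peaks: 1; verified significant: 1
  2:540001-2540001 ratio=0.6684 n=1152 window_threshold=0.1198 significant
outputs in out
```

Reading the output: windows of ~800 SNPs drawn from a null F2 would
exceed an sSNP fraction of 0.1249 only 0.5% of the time, so the scan
flags the one run of windows above that line; its peak window (centered
1.54 Mb on chromosome 2, 40 kb from the planted QTL) holds 1152 SNPs of
which 67% are significant — far beyond its window-specific simulated
threshold of 0.1198 — and is verified as a significant peak.  `out/`
contains the per-window track TSV, the peak CSV, a per-chromosome
multi-panel figure (SNP counts, sSNP counts, ratio track with threshold
lines), the filter report and a run manifest echoing every parameter and
seed.  `bsaseq run --method all` adds the Δ(SNP index) and G tracks with
their simulated threshold curves; `bsaseq thresholds` and `bsaseq plot`
expose the threshold computation and plotting separately.

The library mirrors the CLI (`bsaseq.run_analysis`,
`bsaseq.simulate_table`, `bsaseq.genome_wide_threshold`, ...); see
`docs/methods.md` for the model, conventions and design rationale.

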