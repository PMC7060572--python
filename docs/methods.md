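# Methods

## The significant-SNP scan

Bulked segregant analysis with whole-genome sequencing (BSA-Seq) compares
two pools of phenotypic-extreme individuals from a segregating population.
At a locus unlinked to the trait, reads from both bulks sample the same
segregation frequency; at and around a causal locus, phenotypic selection
enriches opposite alleles in the two bulks.

For every biallelic SNP the package forms the 2x2 table of per-bulk
REF/ALT read counts (AD_REF1, AD_ALT1; AD_REF2, AD_ALT2) and computes:

* the two-sided Fisher's exact test p-value (minimum-likelihood rule).  A
  SNP with `p < alpha` is a *significant SNP* (sSNP); `alpha = 0.01` on
  observed data.
* `Delta(SNP index) = AD_ALT2/DP2 - AD_ALT1/DP1`, with `DP = AD_REF +
  AD_ALT` per bulk (caller-emitted DP columns are ignored because they can
  disagree with the AD sum).
* the G-test statistic `G = 2 * sum_i O_i ln(O_i / E_i)` over the four
  cells, with expectations from the margins under independence.

The genome is then scanned with overlapping windows (2 Mb wide, 10 kb
step, anchored at position 1, closed-open intervals).  The scan statistic
of the significant-SNP method is the fraction of a window's SNPs that are
sSNPs (sSNP/totalSNP); the comparator methods use the window mean of
Delta(SNP index) or G.  Windows with no SNPs inherit the previous window's
value on the same chromosome (leading runs back-fill from the first
non-empty window; fills never cross chromosomes).  No smoothing beyond the
windowing itself is applied.

Because the window statistic aggregates hundreds-to-thousands of SNPs
(typically far more observations than the read depth of any single SNP),
the scan retains power at low coverage, where the per-SNP comparator
methods degrade.

## Null model and thresholds

Under no association, the ALT frequency in each bulk is the design
frequency of the cross: 0.5/0.5 for an F2 (genotypes 1:2:1), 0.75/0.25
for a backcross (1:1 of the two compatible genotypes).  A simulated bulk
of `n` individuals draws genotype counts from these exact ratios
(multinomial), and its realized ALT frequency — expectation equal to the
design frequency, variance `1/(8n)` for F2 — is used as the success
probability of a binomial allele-depth draw at each SNP's *observed*
per-bulk depth: `smAD_ALT ~ Binomial(DP, alleleFreq)`,
`smAD_REF = DP - smAD_ALT`.  One frequency per bulk is drawn per
replicate and shared by that replicate's SNPs: a bulk is a single set of
individuals, so tightly linked SNPs share its sampling deviation.

Thresholds (defaults; all configurable):

| quantity | construction | default |
| --- | --- | --- |
| genome-wide sSNP-ratio threshold | per replicate, resample `m` = mean SNPs/window from the dataset (without replacement), simulate, score at `alpha_sim`; 99.5th percentile of replicate ratios | `n_reps = 10,000`, `alpha_sim = 0.10` |
| window-specific threshold | same, but exactly the window's own SNP depths | 99.5th percentile |
| Delta(SNP index) band | per-SNP central 99% interval of simulated Delta, window-averaged | 0.5th/99.5th |
| G threshold | per-SNP 99.5th percentile of simulated G, window-averaged | 99.5th |

`alpha_sim = 0.10` inside the simulation is deliberately more liberal than
the `alpha = 0.01` applied to observed data: it inflates the simulated
ratios, raising the threshold and buying an extra false-positive margin.
A consequence worth stating explicitly: with the default mismatched
alphas, null data essentially never exceed the thresholds; the nominal
~0.5% exceedance of the 99.5th-percentile construction is observable only
when the observed track is scored at `alpha_sim` too, which is how the
calibration checks are run.

Candidate peaks are the argmax windows of maximal above-threshold runs of
the sSNP-ratio track.  Each candidate is re-tested against a threshold
simulated from its own window's depths, since SNP-poor windows have
heavier-tailed null ratios than the average-sized resample behind the
genome-wide threshold; verification can only demote.  If a candidate is
demoted — typically a truncated, few-SNP window whose ratio is inflated by
tiny counts (a 1-SNP window's ratio is 0 or 1) — the next-highest window
of the same run is examined, up to five candidates per run; every examined
candidate is kept in the report so demotions remain auditable.

Percentiles use linear interpolation between order statistics throughout.
Degenerate inputs follow fixed conventions, all logged: a 2x2 table with
any zero margin has p = 1 (no evidence); Delta is undefined (excluded from
window means) when either bulk has zero depth; G of an all-zero table
is 0.

## Fisher backends

Scalar calls wrap `scipy.stats.fisher_exact`.  The simulation machinery
instead precomputes, per distinct (DP1, DP2) pair, the full grid of
two-sided p-values over all `(alt1, alt2)` outcomes (hypergeometric
enumeration via log-gamma), so millions of simulated tables reduce to
integer indexing.  Both paths implement the identical two-sided rule
(probability-tie tolerance 1 + 1e-7) and are tested to agree with an
independent exhaustive-enumeration oracle to 1e-9.

For all-window calibration studies, `window_thresholds_batch` simulates
one genome-wide replicate matrix and reduces it per window with
cumulative sums.  Each window's marginal threshold distribution is
identical to an independent per-window simulation (replicate frequencies
are shared within a window either way); sharing replicates across windows
only correlates their Monte-Carlo jitter, and is what makes
every-window thresholds affordable on one CPU.

## Synthetic data generator

`synthetic_bsa.SimDesign` draws ground-truth datasets: SNP positions at a
configurable density (default 4e-4/bp on five 5-Mb chromosomes, ~10,000
SNPs), per-bulk depths Poisson around the target coverage (default 30x),
allele depths binomial at the bulk's realized frequency.  A planted QTL at
position `q` displaces the high bulk's ALT frequency by `+delta` and the
low bulk's by `-delta`, decaying along the chromosome as
`delta_eff = delta * (1 - 2c)` with the Haldane recombination fraction
`c = (1 - exp(-2d))/2`, `d` in Morgans from a single global cM/Mb rate.

Two design choices deserve justification:

* **Scaled genetic map.**  The default genome is a miniature, so the map
  scales with it: 24 cM/Mb gives each 5-Mb chromosome the ~120 cM genetic
  length of a real plant chromosome.  Keeping a genome-average *physical*
  rate (~4 cM/Mb) instead would make a 5-Mb toy chromosome one tightly
  linked block (`delta_eff` ~ 0.8 x delta even at its ends), saturating
  the whole chromosome above threshold and making QTL localization
  impossible in principle — a property of the toy geometry, not of the
  method.
* **Chromosome-shared bulk deviation.**  Finite-bulk noise draws the
  genotype-sampling deviation once per (chromosome, bulk) using the same
  multinomial machinery as the null model, rather than independently per
  SNP.  Linked loci in a real bulk share the realized composition of that
  one set of individuals; per-SNP-independent deviations would give the
  observed window ratios materially lighter tails than the null
  simulation's (whose replicates share the frequency within a window) and
  break threshold calibration that the real design satisfies.

The generator emulates the *statistical* structure of a two-bulk
experiment, not its genomics: no read-level errors, no InDels, no
position-dependent coverage or mappability, uniform SNP density, a single
global recombination rate, and truncation selection summarized by a fixed
frequency displacement rather than simulated phenotypes.  Passing tests
therefore demonstrate the statistical machinery (calibration, thresholds,
detection and localization under the stated model), not robustness to
artifacts of real sequencing data.  `downsample_coverage` thins every AD
cell binomially — read subsampling seen through allele depths.

## Filters

Basic filter, in order: (1) organellar/unplaced chromosomes (configurable
name set; rice "Mt"/"Pt" style plus scaffold/contig patterns); (2) any
missing field; (3) multi-allelic ALT (comma in ALT; single-base REF/ALT is
*not* enforced, so small InDels pass); (4) genotype quality below 20 in
either bulk.  The surviving set is order-independent; removal counts are
attributed to the first failing rule.  A separate high-stringency subset
(GQ >= 99 both bulks, per-bulk DP >= 40, total DP in [100, 400])
reproduces the selection used when benchmarking the comparator methods on
high-coverage data.

## Problem sizes and reproducibility

The calibration and recovery studies shipped in the test suite and
`scripts/acceptance.py` use the default 25-Mb/~10,000-SNP genome, 2,000
simulation replicates per threshold, and 20 seeded end-to-end runs for
QTL recovery — sizes chosen so the whole suite completes in minutes on a
single core while keeping Monte-Carlo error well inside the asserted
tolerances (the order-statistic s.e. of a 99.5th-percentile threshold
from 2,000 replicates is ~0.0016 on the exceedance probability).  All
randomness flows from explicit seeds; identical input and seed give
byte-identical track and peak outputs.

Calibration caveat: the dataset-level "fraction of windows exceeding
their threshold" is a heavily clustered statistic — adjacent windows
share ~99.5% of their SNPs (2 Mb window, 10 kb step) and a whole
chromosome shares one bulk deviation — so its Monte-Carlo s.e. carries a
cluster factor of ~size/step and single-dataset values of 0 are common.
The sharp check is marginal: the probability that a fresh null window
ratio exceeds its simulated threshold, which the tests pin at
0.005 +/- 3 x sqrt(p(1-p)/(n_reps+2)).

## Known limitations

* Thresholds condition on observed depths; systematic depth artifacts
  (CNVs, collapsed repeats) are not modeled — the high-depth filter is the
  available mitigation.
* The F3 design of the reference dataset is treated as F2 segregation
  (null 0.5), as in the original analysis; residual-heterozygosity
  corrections are not implemented.
* Only two bulks are supported, and the scan reports peak windows, not
  QTL support intervals.
* The Delta/G comparator thresholds are window-averaged per-SNP
  percentile curves; they are comparators for display, not calibrated
  family-wise bounds.
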