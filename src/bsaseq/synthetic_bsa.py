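"""Synthetic two-bulk BSA-Seq datasets with known ground truth.

The generator emulates the allele-depth table produced by a two-bulk
variant-calling pipeline on a segregating population: SNP positions are
scattered along each chromosome at a given density; away from any causal
locus both bulks segregate at the design frequency (0.5/0.5 for an F2);
at and around a planted QTL, truncation selection on the phenotype shifts
the high bulk's ALT frequency up by ``delta`` and the low bulk's down by
``delta``, with the displacement decaying along the chromosome as
``delta_eff = delta * (1 - 2c)`` where ``c`` is the Haldane recombination
fraction to the QTL.  Finite-bulk noise resamples each bulk's realized
frequency from the configured number of individuals, drawing the sampling
deviation once per (chromosome, bulk): a bulk is one fixed set of
individuals, so linked loci share its realized allele-frequency deviation
rather than fluctuating independently.  The genotype-count draw is the
same one the null-threshold machinery uses, so with ``delta = 0`` a
window's simulated data are distributed exactly as its null-simulation
replicates at matched depths.  Read depths are Poisson around the target
coverage, and allele depths are binomial draws at the realized frequency.

Coverage down-sampling thins every allele-depth cell binomially, emulating
read subsampling at the AD level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snp_io import SnpTable

logger = logging.getLogger(__name__)

#: default genome: five 5-Mb chromosomes — small enough for desk-scale
#: simulation studies, large enough to hold several hundred 2-Mb windows
DEFAULT_CHROM_LENGTHS = {str(i): 5_000_000 for i in range(1, 6)}

_BASES = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Ground-truth design of a synthetic two-bulk experiment.

    ``snp_density`` defaults to 4e-4 SNPs/bp (~10,000 SNPs on the default
    25-Mb genome); ``coverage`` is the mean per-bulk read depth;
    ``recomb_rate`` (cM/Mb) sets linkage decay around planted QTLs.  The
    default genome is a miniature, so the map is scaled with it: 24 cM/Mb
    gives each 5-Mb synthetic chromosome the ~120 cM genetic length of a
    real plant chromosome, preserving how far linkage reaches *within* a
    chromosome rather than the per-Mb physical rate (at a genome-average
    ~4 cM/Mb a 5-Mb toy chromosome would be one tightly linked block and a
    QTL could not be localized even in principle).  ``bulk_sizes`` mirror
    the 430/385-plant bulks of the reference rice design.
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    snp_density: float = 4e-4
    qtls: list[tuple[str, int, float]] = field(default_factory=list)  # (chrom, pos, delta)
    coverage: float = 30.0
    bulk_sizes: tuple[int, int] = (430, 385)
    population: str = "F2"
    recomb_rate: float = 24.0    # cM per Mb
    gq_value: int = 99
    low_gq_fraction: float = 0.0  # spike-in fraction with GQ drawn in [0, 20)
    seed: int | None = None

    def __post_init__(self):
        if self.coverage <= 0 or self.snp_density <= 0:
            raise ValueError("coverage and snp_density must be positive")
        if self.population not in ("F2", "BC"):
            raise ValueError("population must be 'F2' or 'BC'")
        base_high = 0.5 if self.population == "F2" else 0.75
        base_low = 0.5 if self.population == "F2" else 0.25
        for chrom, pos, delta in self.qtls:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in chrom_lengths")
            if not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(f"QTL position {pos} outside chromosome {chrom}")
            if not 0.0 <= delta <= 0.5:
                raise ValueError("QTL delta must be in [0, 0.5]")
            if not (base_high + delta <= 1.0 and base_low - delta >= 0.0):
                raise ValueError("QTL delta pushes a bulk frequency outside [0, 1]")
        if not 0.0 <= self.low_gq_fraction <= 1.0:
            raise ValueError("low_gq_fraction must be in [0, 1]")


def haldane_c(distance_bp: np.ndarray, recomb_rate: float) -> np.ndarray:
    """Haldane recombination fraction at a physical distance.

    ``d = distance_bp * recomb_rate / 100 / 1e6`` Morgans, then
    ``c = (1 - exp(-2 d)) / 2``; c -> 0 at the locus and -> 0.5 far away.
    """
    d_morgans = np.asarray(distance_bp, dtype=float) * recomb_rate / 100.0 / 1e6
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def effective_delta(pos: np.ndarray, chrom: str, design: SimDesign) -> np.ndarray:
    """Allele-frequency displacement at each position from the nearest QTL
    on the same chromosome: ``delta * (1 - 2c)``; zero without a QTL."""
    pos = np.asarray(pos, dtype=float)
    best = np.zeros_like(pos)
    for qchrom, qpos, qdelta in design.qtls:
        if qchrom != chrom:
            continue
        c = haldane_c(np.abs(pos - qpos), design.recomb_rate)
        best = np.maximum(best, qdelta * (1.0 - 2.0 * c))
    return best


def simulate_table(design: SimDesign) -> tuple[SnpTable, list[dict]]:
    """Draw a synthetic SNP table plus the ground-truth QTL list.

    The first bulk is the *high* bulk (ALT-enriched at QTLs), the second
    the *low* bulk.  Finite-bulk noise: per chromosome and bulk, genotype
    counts for the bulk's individuals are drawn from the null segregation
    ratios and the resulting allele-frequency deviation from the design
    frequency is applied to every SNP's target frequency on that
    chromosome (linked loci share the bulk's realized deviation).
    """
    from .null_simulation import _genotype_probs

    rng = np.random.default_rng(design.seed)
    base = 0.5 if design.population == "F2" else 0.75
    base_low = 0.5 if design.population == "F2" else 0.25
    n1, n2 = design.bulk_sizes
    frames = []
    for chrom, length in design.chrom_lengths.items():
        n_snps = rng.poisson(design.snp_density * length)
        pos = np.sort(rng.choice(np.int64(length), size=n_snps, replace=False)) + 1
        d_eff = effective_delta(pos, chrom, design)

        g1 = rng.multinomial(n1, _genotype_probs(base))
        g2 = rng.multinomial(n2, _genotype_probs(base_low))
        dev_high = (g1[1] + 2 * g1[2]) / (2.0 * n1) - base
        dev_low = (g2[1] + 2 * g2[2]) / (2.0 * n2) - base_low
        f_high = np.clip(base + d_eff + dev_high, 0.0, 1.0)
        f_low = np.clip(base_low - d_eff + dev_low, 0.0, 1.0)

        dp_fb = rng.poisson(design.coverage, size=n_snps)
        dp_sb = rng.poisson(design.coverage, size=n_snps)
        ad_alt_fb = rng.binomial(dp_fb, f_high)
        ad_alt_sb = rng.binomial(dp_sb, f_low)

        ref = rng.choice(4, size=n_snps)
        alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
        gq_fb = np.full(n_snps, design.gq_value)
        gq_sb = np.full(n_snps, design.gq_value)
        if design.low_gq_fraction > 0:
            for gq in (gq_fb, gq_sb):
                spike = rng.random(n_snps) < design.low_gq_fraction
                gq[spike] = rng.integers(0, 20, size=int(spike.sum()))

        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": _BASES[ref], "alt": _BASES[alt],
            "ad_ref_fb": dp_fb - ad_alt_fb, "ad_alt_fb": ad_alt_fb, "gq_fb": gq_fb,
            "ad_ref_sb": dp_sb - ad_alt_sb, "ad_alt_sb": ad_alt_sb, "gq_sb": gq_sb,
        }))
    df = pd.concat(frames, ignore_index=True)
    table = SnpTable(df, chrom_order=list(design.chrom_lengths))
    truth = [
        {"chrom": chrom, "pos": int(pos), "delta": float(delta)}
        for chrom, pos, delta in design.qtls
    ]
    logger.info("simulated %d SNPs on %d chromosomes (%d QTLs)",
                len(table), len(design.chrom_lengths), len(truth))
    return table, truth


def downsample_coverage(table: SnpTable, fraction: float,
                        rng: np.random.Generator | None = None) -> SnpTable:
    """Binomially thin every allele-depth cell with retention ``fraction``.

    ``fraction = 1.0`` short-circuits to an exact copy; depths are
    recomputed from the thinned allele depths.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return SnpTable(table.df, chrom_order=table.chrom_order)
    if rng is None:
        rng = np.random.default_rng()
    df = table.df.copy()
    for col in ("ad_ref_fb", "ad_alt_fb", "ad_ref_sb", "ad_alt_sb"):
        v = df[col].to_numpy()
        ok = ~np.isnan(v)
        thinned = v.copy()
        thinned[ok] = rng.binomial(v[ok].astype(np.int64), fraction)
        df[col] = thinned
    return SnpTable(df, chrom_order=table.chrom_order)


def write_truth_json(truth: list[dict], design: SimDesign, path) -> None:
    """Dump the QTL ground truth and a design echo next to the TSV."""
    payload = {
        "qtls": truth,
        "design": {
            "chrom_lengths": design.chrom_lengths,
            "snp_density": design.snp_density,
            "coverage": design.coverage,
            "bulk_sizes": list(design.bulk_sizes),
            "population": design.population,
            "recomb_rate": design.recomb_rate,
            "gq_value": design.gq_value,
            "low_gq_fraction": design.low_gq_fraction,
            "seed": design.seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
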