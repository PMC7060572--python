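"""Ordered SNP filters applied before association testing.

The basic filter drops, in order: (1) records on organellar or unplaced
sequences, (2) records with any missing field, (3) multi-allelic records
(more than one ALT option), (4) records with genotype quality below the
cutoff in either bulk.  The surviving set does not depend on rule order;
only the per-rule attribution of removals does, so each removed record is
counted against the first rule that rejects it.

A separate high-stringency depth filter (GQ >= 99 in both bulks, per-bulk
DP >= 40, total DP in [100, 400]) reproduces the subset selection used when
benchmarking against allele-frequency-difference and G-statistic scans on
high-coverage data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .snp_io import SnpTable

logger = logging.getLogger(__name__)

#: chromosome names commonly used for organellar genomes (Ensembl Plants
#: and NCBI conventions); matching is exact against this set, plus a
#: substring scan for unplaced scaffolds/contigs.
DEFAULT_ORGANELLAR = frozenset({
    "Mt", "Pt", "MT", "PT", "Mito", "Pltd", "chrM", "chrC", "ChrM", "ChrC",
    "mitochondrion", "chloroplast",
})
UNPLACED_SUBSTRINGS = ("scaffold", "Scaffold", "contig", "Contig", "Un", "random")


@dataclass
class FilterConfig:
    """Parameters of the basic and high-depth SNP filters."""

    organellar_names: frozenset[str] = DEFAULT_ORGANELLAR
    min_gq: int = 20
    high_depth: bool = False
    hd_min_gq: int = 99
    hd_min_dp_each: int = 40
    hd_min_dp_total: int = 100
    hd_max_dp_total: int = 400

    def __post_init__(self):
        if self.min_gq < 0:
            raise ValueError("min_gq must be >= 0")
        if self.hd_min_dp_total > self.hd_max_dp_total:
            raise ValueError("hd_min_dp_total must be <= hd_max_dp_total")


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass: counts removed per rule, in order."""

    input_count: int
    removed_per_rule: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def __post_init__(self):
        assert self.input_count - sum(self.removed_per_rule.values()) == self.output_count or not self.removed_per_rule

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "removed_per_rule": self.removed_per_rule,
                "output_count": self.output_count,
            },
            indent=2,
        )


def _is_organellar_or_unplaced(chroms: np.ndarray, names: frozenset[str]) -> np.ndarray:
    exact = np.isin(chroms, list(names))
    sub = np.array([any(s in c for s in UNPLACED_SUBSTRINGS) for c in chroms])
    return exact | sub


def filter_basic(table: SnpTable, config: FilterConfig | None = None) -> tuple[SnpTable, FilterReport]:
    """Apply the four ordered basic filter rules; returns (table, report)."""
    if config is None:
        config = FilterConfig()
    df = table.df
    n_in = len(df)

    r1 = _is_organellar_or_unplaced(df["chrom"].to_numpy(), config.organellar_names)
    r2 = table.missing_flags
    r3 = df["alt"].str.contains(",", regex=False).to_numpy()
    gq_fb = df["gq_fb"].to_numpy()
    gq_sb = df["gq_sb"].to_numpy()
    with np.errstate(invalid="ignore"):
        r4 = (gq_fb < config.min_gq) | (gq_sb < config.min_gq)
    r4 = np.nan_to_num(r4.astype(float), nan=0).astype(bool)

    removed = np.zeros(n_in, dtype=bool)
    report = FilterReport(input_count=n_in)
    for name, mask in (
        ("organellar_or_unplaced", r1),
        ("missing_value", r2),
        ("multiple_alt", r3),
        ("low_gq", r4),
    ):
        new = mask & ~removed
        report.removed_per_rule[name] = int(new.sum())
        removed |= new
    out = table.subset(~removed)
    report.output_count = len(out)
    logger.info("basic filter: %d -> %d SNPs (%s)", n_in, len(out), report.removed_per_rule)
    return out, report


def filter_high_depth(table: SnpTable, config: FilterConfig | None = None) -> tuple[SnpTable, FilterReport]:
    """Apply the high-stringency GQ/DP subset filter (after :func:`filter_basic`)."""
    if config is None:
        config = FilterConfig()
    df = table.df
    n_in = len(df)
    keep = (
        (df["gq_fb"] >= config.hd_min_gq)
        & (df["gq_sb"] >= config.hd_min_gq)
        & (df["dp_fb"] >= config.hd_min_dp_each)
        & (df["dp_sb"] >= config.hd_min_dp_each)
        & (df["dp_fb"] + df["dp_sb"] >= config.hd_min_dp_total)
        & (df["dp_fb"] + df["dp_sb"] <= config.hd_max_dp_total)
    ).to_numpy()
    out = table.subset(keep)
    report = FilterReport(
        input_count=n_in,
        removed_per_rule={"high_depth": int(n_in - keep.sum())},
        output_count=int(keep.sum()),
    )
    logger.info("high-depth filter: %d -> %d SNPs", n_in, len(out))
    return out, report
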