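"""Read and write the two-bulk SNP table consumed by the BSA-Seq pipeline.

The expected input is a tab-separated file with one row per SNP and eight
columns: ``CHROM``, ``POS``, ``REF``, ``ALT``, plus per-bulk allele-depth
(``<bulk>.AD``, a ``"REF,ALT"`` comma pair) and genotype-quality
(``<bulk>.GQ``) columns for each of the two phenotype-selected bulks.  Such a
table is produced from a joint-genotyped VCF with, e.g.::

    gatk VariantsToTable -V bulks.vcf -F CHROM -F POS -F REF -F ALT \
        -GF AD -GF GQ -O bulks.tsv

Per-bulk depth (DP) is *always* recomputed as ``AD_REF + AD_ALT``; upstream
DP columns are ignored because caller-emitted DP can disagree with the sum
of the allele depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical numeric columns of a SNP table, in output order
NUMERIC_COLUMNS = [
    "ad_ref_fb", "ad_alt_fb", "gq_fb",
    "ad_ref_sb", "ad_alt_sb", "gq_sb",
    "dp_fb", "dp_sb",
]
#: columns that must be non-missing for a record to be complete
REQUIRED_FIELDS = [
    "chrom", "pos", "ref", "alt",
    "ad_ref_fb", "ad_alt_fb", "gq_fb",
    "ad_ref_sb", "ad_alt_sb", "gq_sb",
]

#: strings treated as a missing value in any input field
MISSING_TOKENS = {"", "NA", "na", ".", "NaN", "nan", "None"}


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP with per-bulk allele depths and genotype qualities."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    ad_ref_fb: int
    ad_alt_fb: int
    gq_fb: int | None
    ad_ref_sb: int
    ad_alt_sb: int
    gq_sb: int | None

    @property
    def dp_fb(self) -> int:
        return self.ad_ref_fb + self.ad_alt_fb

    @property
    def dp_sb(self) -> int:
        return self.ad_ref_sb + self.ad_alt_sb


class SnpTable:
    """Position-sorted collection of SNP records backed by a DataFrame.

    The frame holds the columns ``chrom, pos, ref, alt`` plus
    :data:`NUMERIC_COLUMNS`.  Missing numeric fields are NaN; ``dp_fb`` /
    ``dp_sb`` are recomputed from the allele depths on construction and are
    NaN whenever either summand is missing.  Records are sorted by
    ``(chrom, pos)`` following ``chrom_order`` and duplicate positions keep
    the first occurrence.
    """

    def __init__(self, df: pd.DataFrame, chrom_order: list[str] | None = None):
        df = df.copy()
        for col in ("chrom", "ref", "alt"):
            df[col] = df[col].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for col in NUMERIC_COLUMNS:
            if col.startswith("dp"):
                continue
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        # DP is defined as the sum of the allele depths, never trusted upstream
        df["dp_fb"] = df["ad_ref_fb"] + df["ad_alt_fb"]
        df["dp_sb"] = df["ad_ref_sb"] + df["ad_alt_sb"]

        if chrom_order is None:
            chrom_order = list(dict.fromkeys(df["chrom"]))
        self.chrom_order = list(chrom_order)
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        df["_rank"] = df["chrom"].map(rank)
        df = df.sort_values(["_rank", "pos"], kind="stable").drop(columns="_rank")
        n_dup = df.duplicated(subset=["chrom", "pos"]).sum()
        if n_dup:
            logger.warning("dropping %d duplicate (chrom, pos) records (keeping first)", n_dup)
            df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
        self.df = df[["chrom", "pos", "ref", "alt"] + NUMERIC_COLUMNS].reset_index(drop=True)

        bad_ad = (self.df[["ad_ref_fb", "ad_alt_fb", "ad_ref_sb", "ad_alt_sb"]] < 0).any().any()
        if bad_ad or (self.df["pos"] < 1).any():
            raise ValueError("SNP table has negative allele depths or positions < 1")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        cols = ["chrom", "pos", "ref", "alt"] + NUMERIC_COLUMNS
        try:
            pd.testing.assert_frame_equal(self.df[cols], other.df[cols], check_dtype=False)
        except AssertionError:
            return False
        return self.chrom_order == other.chrom_order

    @property
    def missing_flags(self) -> np.ndarray:
        """Boolean per record: any required field missing/unparseable."""
        return self.df[
            [c for c in REQUIRED_FIELDS if c in NUMERIC_COLUMNS]
        ].isna().any(axis=1).to_numpy() | (self.df["alt"].isin(MISSING_TOKENS)).to_numpy()

    def records(self) -> Iterator[SnpRecord]:
        for row in self.df.itertuples(index=False):
            yield SnpRecord(
                chrom=row.chrom, pos=int(row.pos), ref_base=row.ref, alt_base=row.alt,
                ad_ref_fb=int(row.ad_ref_fb), ad_alt_fb=int(row.ad_alt_fb),
                gq_fb=None if np.isnan(row.gq_fb) else int(row.gq_fb),
                ad_ref_sb=int(row.ad_ref_sb), ad_alt_sb=int(row.ad_alt_sb),
                gq_sb=None if np.isnan(row.gq_sb) else int(row.gq_sb),
            )

    def subset(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(self.df[mask], chrom_order=self.chrom_order)


def parse_ad(ad_text: object) -> tuple[int, int] | None:
    """Split an ``"REF,ALT"`` allele-depth pair into two integers.

    Returns ``None`` (a missing marker) for absent or malformed fields so
    that the missing-value filter rule can count them; never raises.
    """
    if ad_text is None or (isinstance(ad_text, float) and np.isnan(ad_text)):
        return None
    text = str(ad_text).strip()
    if text in MISSING_TOKENS:
        return None
    parts = text.split(",")
    if len(parts) != 2:
        return None
    try:
        ref_depth, alt_depth = int(parts[0]), int(parts[1])
    except ValueError:
        return None
    if ref_depth < 0 or alt_depth < 0:
        return None
    return ref_depth, alt_depth


def _resolve_columns(header: list[str], first_bulk_id: str, second_bulk_id: str) -> dict[str, str]:
    """Map canonical field names to actual header names, or raise naming the
    missing column."""
    mapping: dict[str, str] = {}
    for want in ("CHROM", "POS", "REF", "ALT"):
        if want not in header:
            raise ValueError(f"input table is missing required column {want!r}")
        mapping[want.lower()] = want
    for bulk, prefix in ((first_bulk_id, "fb"), (second_bulk_id, "sb")):
        for suffix, canon in ((".AD", f"ad_{prefix}"), (".GQ", f"gq_{prefix}")):
            candidates = [f"{bulk}{suffix}", f"{prefix}{suffix}"]
            found = next((c for c in candidates if c in header), None)
            if found is None:
                raise ValueError(
                    f"input table is missing required column {candidates[0]!r}"
                )
            mapping[canon] = found
    return mapping


def read_snp_tsv(path, first_bulk_id: str = "fb", second_bulk_id: str = "sb") -> SnpTable:
    """Read an 8-column two-bulk SNP TSV into a :class:`SnpTable`.

    ``first_bulk_id`` / ``second_bulk_id`` name the per-sample column
    prefixes (e.g. ``"834927"`` for a column ``834927.AD``); the literal
    prefixes ``fb.`` / ``sb.`` are always accepted as a fallback.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(raw.columns), first_bulk_id, second_bulk_id)

    out = pd.DataFrame()
    out["chrom"] = raw[cols["chrom"]].astype(str)
    pos = pd.to_numeric(raw[cols["pos"]].str.replace(",", "", regex=False), errors="coerce")
    n_badpos = int(pos.isna().sum())
    if n_badpos:
        logger.warning("dropping %d rows with unparseable POS", n_badpos)
    out["pos"] = pos
    out["ref"] = raw[cols["ref"]]
    out["alt"] = raw[cols["alt"]]
    for prefix in ("fb", "sb"):
        pairs = raw[cols[f"ad_{prefix}"]].map(parse_ad)
        out[f"ad_ref_{prefix}"] = [p[0] if p else np.nan for p in pairs]
        out[f"ad_alt_{prefix}"] = [p[1] if p else np.nan for p in pairs]
        gq = raw[cols[f"gq_{prefix}"]].map(lambda s: np.nan if s.strip() in MISSING_TOKENS else s)
        out[f"gq_{prefix}"] = pd.to_numeric(gq, errors="coerce")
    out = out[pos.notna().to_numpy()]
    out["pos"] = out["pos"].astype(np.int64)
    return SnpTable(out)


def write_snp_tsv(table: SnpTable, path) -> None:
    """Write a :class:`SnpTable` back to the standard 8-column TSV.

    Missing fields are emitted as ``NA``; the file round-trips through
    :func:`read_snp_tsv` to an identical table.
    """
    df = table.df
    out = pd.DataFrame()
    out["CHROM"] = df["chrom"]
    out["POS"] = df["pos"]
    out["REF"] = df["ref"]
    out["ALT"] = df["alt"]

    def fmt_ad(r, a):
        if np.isnan(r) or np.isnan(a):
            return "NA"
        return f"{int(r)},{int(a)}"

    def fmt_gq(g):
        return "NA" if np.isnan(g) else str(int(g))

    out["fb.AD"] = [fmt_ad(r, a) for r, a in zip(df["ad_ref_fb"], df["ad_alt_fb"])]
    out["fb.GQ"] = df["gq_fb"].map(fmt_gq)
    out["sb.AD"] = [fmt_ad(r, a) for r, a in zip(df["ad_ref_sb"], df["ad_alt_sb"])]
    out["sb.GQ"] = df["gq_sb"].map(fmt_gq)
    out.to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))
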