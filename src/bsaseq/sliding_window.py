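"""Sliding-window aggregation of per-SNP statistics into genome tracks.

Windows are 1-based, closed-open ``[start, start + size)`` intervals
anchored at position 1 and advanced by ``step``; with the defaults (2 Mb
window, 10 kb step) each SNP contributes to up to ``size/step = 200``
overlapping windows.  A window's sSNP/totalSNP ratio is the fraction of its
SNPs that are significant; its delta-SNP-index and G tracks are plain means
over the contained SNPs (NaN deltas from zero-depth records are excluded).

Windows with no SNPs inherit the value of the previous window on the same
chromosome; a leading run of empty windows is back-filled from the first
non-empty window.  Carry-forward never crosses a chromosome boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_io import SnpTable

logger = logging.getLogger(__name__)

#: per-window value columns subject to empty-window fill
VALUE_COLUMNS = ("ratio", "mean_delta", "mean_g")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: width and increment, both in bp."""

    size: int = 2_000_000
    step: int = 10_000

    def __post_init__(self):
        if not 0 < self.step <= self.size:
            raise ValueError("require 0 < step <= size")


def make_windows(chrom_lengths: dict[str, int], config: WindowConfig | None = None) -> pd.DataFrame:
    """Tile each chromosome with windows ``[1, 1+size), [1+step, ...], ...``.

    Window starts run while ``start <= chrom_length``; the last window is
    truncated at the chromosome end (``end = min(start + size, length + 1)``).
    """
    if config is None:
        config = WindowConfig()
    rows = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(1, length + 1, config.step, dtype=np.int64)
        ends = np.minimum(starts + config.size, length + 1)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def chrom_lengths_from_table(table: SnpTable) -> dict[str, int]:
    """Default chromosome lengths: the maximum SNP position per chromosome."""
    return table.df.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()


def _window_sums(pos: np.ndarray, values: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Sum of ``values`` (2d: n_values x n_snps, pos sorted) in each window."""
    cum = np.concatenate([np.zeros((values.shape[0], 1)), np.cumsum(values, axis=1)], axis=1)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    return cum[:, hi] - cum[:, lo]


def window_means(table: SnpTable, windows: pd.DataFrame, values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-window SNP counts plus NaN-aware means of each named value array.

    ``values`` arrays are aligned with ``table.df`` rows.  Returns a copy of
    ``windows`` with ``n_snps`` and one ``mean_<name>`` column per entry;
    windows without any finite value get NaN.
    """
    windows = windows.reset_index(drop=True)
    out = windows.copy()
    names = list(values)
    n_win = len(windows)
    sums = {name: np.zeros(n_win) for name in names}
    cnts = {name: np.zeros(n_win) for name in names}
    n_snps = np.zeros(n_win, dtype=np.int64)

    df = table.df
    for chrom, wmask in windows.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(wmask)
        smask = (df["chrom"] == chrom).to_numpy()
        pos = df.loc[smask, "pos"].to_numpy()
        starts = windows.loc[widx, "start"].to_numpy()
        ends = windows.loc[widx, "end"].to_numpy()
        stacked = []
        for name in names:
            v = np.asarray(values[name], dtype=float)[smask]
            finite = np.isfinite(v)
            stacked.append(np.where(finite, v, 0.0))
            stacked.append(finite.astype(float))
        stacked.append(np.ones_like(pos, dtype=float))
        sums_mat = _window_sums(pos, np.vstack(stacked), starts, ends)
        for i, name in enumerate(names):
            sums[name][widx] = sums_mat[2 * i]
            cnts[name][widx] = sums_mat[2 * i + 1]
        n_snps[widx] = sums_mat[-1].astype(np.int64)

    out["n_snps"] = n_snps
    for name in names:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"mean_{name}"] = np.where(cnts[name] > 0, sums[name] / np.maximum(cnts[name], 1), np.nan)
    return out


def window_stats(table: SnpTable, ssnp_flags: np.ndarray, windows: pd.DataFrame) -> pd.DataFrame:
    """Build the per-window track: counts, sSNP ratio, mean delta, mean G.

    Requires ``delta_snp_index`` and ``g_stat`` columns on the table (as
    attached by :func:`bsaseq.association_stats.classify_ssnps`); otherwise
    those tracks are NaN.
    """
    df = table.df
    ssnp = np.asarray(ssnp_flags, dtype=float)
    if len(ssnp) != len(df):
        raise ValueError("ssnp_flags must align with the table records")
    values = {"ssnp": ssnp}
    if "delta_snp_index" in df:
        values["delta"] = df["delta_snp_index"].to_numpy()
    if "g_stat" in df:
        values["g"] = df["g_stat"].to_numpy()

    out = window_means(table, windows, values)
    n = out["n_snps"].to_numpy()
    n_ssnps = np.round(np.nan_to_num(out.pop("mean_ssnp").to_numpy()) * n).astype(np.int64)
    out["n_ssnps"] = n_ssnps
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(n > 0, n_ssnps / np.maximum(n, 1), np.nan)
    out["mean_delta"] = out.pop("mean_delta") if "mean_delta" in out else np.nan
    out["mean_g"] = out.pop("mean_g") if "mean_g" in out else np.nan
    out["filled"] = False
    return out[["chrom", "start", "end", "n_snps", "n_ssnps", "ratio", "mean_delta", "mean_g", "filled"]]


def fill_empty_windows(stats: pd.DataFrame) -> pd.DataFrame:
    """Carry values into SNP-free windows, per chromosome.

    Empty windows inherit the previous window's ratio/means; leading runs
    of empty windows are back-filled from the first non-empty window.  An
    all-empty chromosome gets zeros with a warning.  ``filled`` is set on
    every inherited window.
    """
    out = stats.copy()
    value_cols = [c for c in VALUE_COLUMNS if c in out.columns]
    for chrom, grp in out.groupby("chrom", sort=False):
        idx = grp.index
        empty = grp["n_snps"].to_numpy() == 0
        if not empty.any():
            continue
        if empty.all():
            logger.warning("chromosome %s has no SNPs in any window; track set to 0", chrom)
            out.loc[idx, value_cols] = 0.0
            out.loc[idx, "filled"] = True
            continue
        for col in value_cols:
            v = out.loc[idx, col].to_numpy(dtype=float)
            v[empty] = np.nan
            filled = pd.Series(v).ffill().bfill().to_numpy()
            out.loc[idx, col] = filled
        out.loc[idx[empty], "filled"] = True
    return out


def write_track_tsv(stats: pd.DataFrame, path) -> None:
    """Export the window track (plus any threshold columns) as TSV."""
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")
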