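"""Candidate-peak detection, verification, and report/figure output.

Scanning the filled sSNP/totalSNP track against the genome-wide threshold
yields maximal runs of consecutive above-threshold windows; the argmax
window of each run (ties broken toward the smaller start) is a *candidate
peak*.  Because the genome-wide threshold is built from average-sized SNP
samples, a candidate in a SNP-poor region can be spurious, so each
candidate is re-tested against a threshold simulated from its own window's
depths: candidates whose observed ratio does not exceed their
window-specific threshold are demoted to false positives.  Verification
only ever demotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .null_simulation import NullModel, window_threshold
from .snp_io import SnpTable

logger = logging.getLogger(__name__)

PEAK_CSV_COLUMNS = ["chrom", "pos", "end", "ratio", "n_snps", "threshold", "verdict"]


@dataclass(frozen=True)
class PeakRecord:
    """One candidate peak window with its verification verdict."""

    chrom: str
    window_start: int
    window_end: int
    observed_ratio: float
    n_snps: int
    window_threshold: float
    verdict: str  # "significant" | "false_positive"


def _above_threshold_runs(track: pd.DataFrame, genome_threshold: float) -> list[pd.DataFrame]:
    """Maximal runs of consecutive above-threshold windows, per chromosome."""
    if track["ratio"].isna().any():
        raise ValueError("track has NaN ratios; run fill_empty_windows first")
    runs = []
    for _, grp in track.groupby("chrom", sort=False):
        above = (grp["ratio"] > genome_threshold).to_numpy()
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            runs.append(grp.iloc[run_start:run_end])
    return runs


def find_candidate_peaks(track: pd.DataFrame, genome_threshold: float) -> pd.DataFrame:
    """Candidate peak windows: argmax of each maximal above-threshold run
    (ties broken toward the smaller start).

    ``track`` must be a filled window track (no NaN ratios) ordered by
    (chrom, start).
    """
    rows = [run.iloc[int(np.argmax(run["ratio"].to_numpy()))]  # first max
            for run in _above_threshold_runs(track, genome_threshold)]
    if not rows:
        return track.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def verify_peaks(candidates: pd.DataFrame, table: SnpTable, model: NullModel) -> list[PeakRecord]:
    """Simulate a window-specific threshold for each candidate and compare.

    A candidate is ``significant`` iff its observed ratio strictly exceeds
    its own simulated threshold; a candidate window without SNPs cannot be
    verified and is flagged ``false_positive``.
    """
    df = table.df
    records: list[PeakRecord] = []
    for cand in candidates.itertuples(index=False):
        in_win = (
            (df["chrom"] == cand.chrom)
            & (df["pos"] >= cand.start)
            & (df["pos"] < cand.end)
        ).to_numpy()
        n_snps = int(in_win.sum())
        if n_snps == 0:
            logger.warning("candidate %s:%d-%d has no SNPs; marked false_positive",
                           cand.chrom, cand.start, cand.end)
            records.append(PeakRecord(cand.chrom, int(cand.start), int(cand.end),
                                      float(cand.ratio), 0, float("nan"), "false_positive"))
            continue
        dps = df.loc[in_win, ["dp_fb", "dp_sb"]].to_numpy(np.int64)
        thr = window_threshold(dps, model)
        verdict = "significant" if cand.ratio > thr else "false_positive"
        logger.info("peak %s:%d ratio=%.4f n=%d window_threshold=%.4f -> %s",
                    cand.chrom, cand.start, cand.ratio, n_snps, thr, verdict)
        records.append(PeakRecord(cand.chrom, int(cand.start), int(cand.end),
                                  float(cand.ratio), n_snps, thr, verdict))
    return records


def detect_and_verify_peaks(track: pd.DataFrame, genome_threshold: float,
                            table: SnpTable, model: NullModel,
                            max_attempts: int = 5) -> list[PeakRecord]:
    """Peak detection with demotion-aware re-examination of each run.

    Within each above-threshold run the argmax window is verified against
    its window-specific threshold; if it is demoted (typically a truncated
    or SNP-poor window whose ratio is inflated by tiny counts), the
    next-highest window of the same run is examined, up to ``max_attempts``
    candidates per run or until one verifies.  Every examined candidate is
    reported, so demoted attempts remain visible as false positives;
    verification never promotes a window that was not above the
    genome-wide threshold.
    """
    records: list[PeakRecord] = []
    for run in _above_threshold_runs(track, genome_threshold):
        ratios = run["ratio"].to_numpy()
        order = np.argsort(-ratios, kind="stable")  # ties -> smaller start
        for rank in range(min(max_attempts, len(run))):
            cand = run.iloc[[order[rank]]]
            rec = verify_peaks(cand, table, model)[0]
            records.append(rec)
            if rec.verdict == "significant":
                break
    return records


def peaks_to_frame(peaks: list[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom, "pos": p.window_start, "end": p.window_end,
                "ratio": p.observed_ratio, "n_snps": p.n_snps,
                "threshold": p.window_threshold, "verdict": p.verdict,
            }
            for p in peaks
        ],
        columns=PEAK_CSV_COLUMNS,
    )


def write_peak_csv(peaks: list[PeakRecord], path) -> None:
    """Emit one row per candidate peak (header-only file when none)."""
    peaks_to_frame(peaks).to_csv(path, index=False, float_format="%.10g")


def read_peak_csv(path) -> list[PeakRecord]:
    df = pd.read_csv(path, dtype={"chrom": str})
    return [
        PeakRecord(r.chrom, int(r.pos), int(r.end), float(r.ratio),
                   int(r.n_snps), float(r.threshold), r.verdict)
        for r in df.itertuples(index=False)
    ]


def render_figure(track: pd.DataFrame, genome_threshold: float, path,
                  delta_g_thresholds: pd.DataFrame | None = None) -> None:
    """Multi-panel genome-track figure.

    One column per chromosome; rows: SNP/sSNP counts, sSNP/totalSNP ratio
    with the genome-wide threshold line, and (when threshold curves are
    supplied) delta(SNP index) and G tracks with their simulated bands.
    Output format follows the file suffix (.pdf/.png/.svg).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(track["chrom"]))
    n_rows = 2 + (2 if delta_g_thresholds is not None else 0)
    fig, axes = plt.subplots(
        n_rows, len(chroms), figsize=(2.4 * len(chroms), 2.2 * n_rows),
        sharey="row", squeeze=False,
    )
    for j, chrom in enumerate(chroms):
        grp = track[track["chrom"] == chrom]
        x = grp["start"].to_numpy() / 1e6
        ax = axes[0][j]
        ax.plot(x, grp["n_snps"], color="tab:blue", lw=0.8, label="total SNPs")
        ax.plot(x, grp["n_ssnps"], color="black", lw=0.8, label="sSNPs")
        ax.set_title(f"chr {chrom}", fontsize=9)
        ax = axes[1][j]
        ax.plot(x, grp["ratio"], color="tab:green", lw=0.8)
        ax.axhline(genome_threshold, color="red", lw=0.8)
        if delta_g_thresholds is not None:
            thr = delta_g_thresholds[delta_g_thresholds["chrom"] == chrom]
            ax = axes[2][j]
            ax.plot(x, grp["mean_delta"], color="tab:purple", lw=0.8)
            ax.plot(x, thr["delta_lo"], color="red", lw=0.6)
            ax.plot(x, thr["delta_hi"], color="red", lw=0.6)
            ax = axes[3][j]
            ax.plot(x, grp["mean_g"], color="tab:orange", lw=0.8)
            ax.plot(x, thr["g_threshold"], color="red", lw=0.6)
        axes[-1][j].set_xlabel("Mb", fontsize=8)
    axes[0][0].set_ylabel("SNP counts", fontsize=8)
    axes[1][0].set_ylabel("sSNP/totalSNP", fontsize=8)
    if delta_g_thresholds is not None:
        axes[2][0].set_ylabel("Δ(SNP index)", fontsize=8)
        axes[3][0].set_ylabel("G", fontsize=8)
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_outputs(track: pd.DataFrame, genome_threshold: float, peaks: list[PeakRecord],
                   out_dir, figure_format: str = "pdf",
                   delta_g_thresholds: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the peak CSV and the genome-track figure into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "peaks.csv"
    fig_path = out_dir / f"bsaseq_tracks.{figure_format}"
    write_peak_csv(peaks, csv_path)
    render_figure(track, genome_threshold, fig_path, delta_g_thresholds=delta_g_thresholds)
    return {"csv": csv_path, "figure": fig_path}
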