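"""End-to-end analysis driver: read -> filter -> per-SNP stats -> windows
-> thresholds -> peaks -> outputs.

This is the library-level counterpart of the command-line ``run``
subcommand; every knob lives in :class:`RunConfig`, and a completed
:class:`RunResult` carries the filled track, the genome-wide threshold and
the verified peak list, along with the paths of everything written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_stats, null_simulation, peak_report, sliding_window, snp_filter, snp_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run (echoed to the run manifest)."""

    input_path: str | Path | None = None
    first_bulk_id: str = "fb"
    second_bulk_id: str = "sb"
    population: str = "F2"
    bulk_sizes: tuple[int, int] = (430, 385)
    filter_config: snp_filter.FilterConfig = field(default_factory=snp_filter.FilterConfig)
    high_depth: bool = False
    alpha_real: float = 0.01
    alpha_sim: float = 0.10
    window_size: int = 2_000_000
    window_step: int = 10_000
    n_reps: int = 10_000
    ratio_percentile: float = 99.5
    delta_ci: float = 0.99
    g_percentile: float = 99.5
    method: str = "ssnp"          # "ssnp" | "delta" | "gstat" | "all"
    seed: int | None = None
    out_dir: str | Path = "bsaseq_out"
    figure_format: str = "pdf"
    chrom_lengths: dict[str, int] | None = None

    def null_model(self) -> null_simulation.NullModel:
        return null_simulation.NullModel(
            population=self.population, bulk_sizes=tuple(self.bulk_sizes),
            n_reps=self.n_reps, alpha_sim=self.alpha_sim,
            ratio_percentile=self.ratio_percentile, delta_ci=self.delta_ci,
            g_percentile=self.g_percentile, seed=self.seed,
        )

    def window_config(self) -> sliding_window.WindowConfig:
        return sliding_window.WindowConfig(size=self.window_size, step=self.window_step)


@dataclass
class RunResult:
    table: snp_io.SnpTable
    track: pd.DataFrame
    genome_threshold: float
    peaks: list[peak_report.PeakRecord]
    avg_snps_per_window: int
    filter_reports: list[snp_filter.FilterReport]
    paths: dict[str, Path] = field(default_factory=dict)


def run_analysis(config: RunConfig, table: snp_io.SnpTable | None = None,
                 write_outputs: bool = True) -> RunResult:
    """Execute the full two-bulk scan.

    ``table`` may be passed directly (already read) or loaded from
    ``config.input_path``.  Writes the window-track TSV, peak CSV, figure,
    filter report and run manifest into ``config.out_dir`` unless
    ``write_outputs`` is disabled.
    """
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = snp_io.read_snp_tsv(config.input_path, config.first_bulk_id, config.second_bulk_id)
    logger.info("input: %d SNP records", len(table))

    table, rep_basic = snp_filter.filter_basic(table, config.filter_config)
    reports = [rep_basic]
    if config.high_depth:
        table, rep_hd = snp_filter.filter_high_depth(table, config.filter_config)
        reports.append(rep_hd)
    if len(table) == 0:
        raise ValueError("no SNPs left after filtering")

    flags = association_stats.classify_ssnps(table, alpha=config.alpha_real)

    chrom_lengths = config.chrom_lengths or sliding_window.chrom_lengths_from_table(table)
    windows = sliding_window.make_windows(chrom_lengths, config.window_config())
    stats = sliding_window.window_stats(table, flags, windows)
    track = sliding_window.fill_empty_windows(stats)

    model = config.null_model()
    nonempty = stats["n_snps"] > 0
    avg_snps = max(1, int(round(stats.loc[nonempty, "n_snps"].mean())))
    genome_thr = null_simulation.genome_wide_threshold(table, avg_snps, model)

    peaks = peak_report.detect_and_verify_peaks(track, genome_thr, table, model)

    track = track.copy()
    track["ratio_threshold"] = genome_thr
    delta_g = None
    if config.method in ("delta", "gstat", "all"):
        delta_g = null_simulation.delta_and_g_thresholds(table, windows, model)
        for col in ("delta_lo", "delta_hi", "g_threshold"):
            track[col] = delta_g[col].to_numpy()

    result = RunResult(table=table, track=track, genome_threshold=genome_thr,
                       peaks=peaks, avg_snps_per_window=avg_snps, filter_reports=reports)
    if write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sliding_window.write_track_tsv(track, out_dir / "window_track.tsv")
        paths = peak_report.render_outputs(
            track, genome_thr, peaks, out_dir,
            figure_format=config.figure_format, delta_g_thresholds=delta_g,
        )
        paths["track"] = out_dir / "window_track.tsv"
        (out_dir / "filter_report.json").write_text(
            json.dumps([json.loads(r.to_json()) for r in reports], indent=2)
        )
        manifest = asdict(config)
        manifest["input_path"] = str(manifest["input_path"])
        manifest["out_dir"] = str(manifest["out_dir"])
        manifest["filter_config"]["organellar_names"] = sorted(
            config.filter_config.organellar_names
        )
        manifest["genome_threshold"] = genome_thr
        manifest["avg_snps_per_window"] = avg_snps
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = out_dir / "run_manifest.json"
        result.paths = paths
    return result
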