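"""Null-model resampling for significance thresholds.

Under the no-association null, the ALT allele frequency in each bulk is the
cross design's segregation frequency (0.5 in both bulks for an F2; 0.75 and
0.25 for a backcross), perturbed by finite-bulk sampling: a bulk of *n*
diploid individuals is drawn from the exact segregation ratios, and its
realized ALT frequency is used as the binomial success probability when
simulated allele depths are drawn at each SNP's observed per-bulk depth
(``smAD_ALT ~ Binomial(DP, alleleFreq)``, ``smAD_REF = DP - smAD_ALT``).

Three thresholds are derived from replicates of this process:

* **genome-wide sSNP-ratio threshold** — each replicate samples as many
  SNPs as the average window holds (without replacement) from the whole
  dataset, simulates their depths, scores them with Fisher's exact test at
  the (deliberately liberal) in-simulation significance level, and records
  the simulated sSNP/totalSNP ratio; the threshold is a high percentile
  (default 99.5th) of the replicate ratios;
* **window-specific threshold** — identical, but each replicate re-simulates
  exactly the depths of one window's SNPs (no resampling);
* **delta-SNP-index / G thresholds** — per SNP, percentiles of the simulated
  statistic (the central 99% interval for delta, the 99.5th percentile for
  G), averaged over each window to form comparator threshold curves.

One bulk frequency per bulk is drawn per replicate and shared by all SNPs
in that replicate, so replicate-level frequency noise is common across the
window, mirroring that all SNPs in a real bulk were sequenced from the same
pool of individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import FisherGrid
from .snp_io import SnpTable
from . import sliding_window

logger = logging.getLogger(__name__)

#: SNP-chunk size for the per-SNP delta/G simulations (memory control)
_CHUNK = 512


@dataclass
class NullModel:
    """Population design and simulation conventions for threshold estimation.

    ``bulk_sizes`` defaults to the 430/385 individuals of the two
    phenotype-selected bulks of the rice cold-tolerance cross used as the
    reference design.  ``alpha_sim`` is the in-simulation sSNP cutoff
    (0.10, more liberal than the 0.01 applied to real data, which raises
    the simulated ratios and hence the threshold, trading sensitivity for
    fewer false positives).
    """

    population: str = "F2"          # "F2" or "BC" (backcross)
    bulk_sizes: tuple[int, int] = (430, 385)
    n_reps: int = 10_000
    alpha_sim: float = 0.10
    ratio_percentile: float = 99.5
    delta_ci: float = 0.99
    g_percentile: float = 99.5
    seed: int | None = None
    #: expected ALT frequency per bulk under the null; derived from
    #: ``population`` when left as None
    base_freqs: tuple[float, float] | None = None

    def __post_init__(self):
        if self.population not in ("F2", "BC"):
            raise ValueError("population must be 'F2' or 'BC'")
        if not 0.0 < self.alpha_sim < 1.0:
            raise ValueError("alpha_sim must be in (0, 1)")
        if self.n_reps < 1 or min(self.bulk_sizes) < 1:
            raise ValueError("n_reps and bulk_sizes must be >= 1")
        if self.base_freqs is None:
            self.base_freqs = (0.5, 0.5) if self.population == "F2" else (0.75, 0.25)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _genotype_probs(base_freq: float) -> np.ndarray:
    """Null genotype probabilities (#ALT alleles = 0, 1, 2 per individual).

    F2 (base 0.5): 1:2:1.  Backcross: the 1:1 mix of the two genotypes
    consistent with the design frequency (0.75 -> Aa:aa, 0.25 -> AA:Aa).
    """
    if base_freq == 0.5:
        return np.array([0.25, 0.5, 0.25])
    if base_freq == 0.75:
        return np.array([0.0, 0.5, 0.5])
    if base_freq == 0.25:
        return np.array([0.5, 0.5, 0.0])
    raise ValueError(f"unsupported null ALT frequency {base_freq}")


def sm_allele_freq(model: NullModel, bulk_index: int, rng: np.random.Generator,
                   size: int | None = None):
    """Realized ALT frequency of one simulated bulk.

    Draws genotype counts for ``bulk_sizes[bulk_index - 1]`` individuals
    from the null segregation ratios and returns the bulk ALT allele
    frequency; its expectation is the design frequency.  ``size`` draws a
    vector of independent bulks.
    """
    if bulk_index not in (1, 2):
        raise ValueError("bulk_index must be 1 or 2")
    n = model.bulk_sizes[bulk_index - 1]
    probs = _genotype_probs(model.base_freqs[bulk_index - 1])
    counts = rng.multinomial(n, probs, size=size)  # (..., 3)
    freq = (counts[..., 1] + 2 * counts[..., 2]) / (2.0 * n)
    return freq if size is not None else float(freq)


def sm_ad(dp, allele_freq, rng: np.random.Generator):
    """Simulated allele depths: ``smAD_ALT ~ Binomial(DP, alleleFreq)`` and
    ``smAD_REF = DP - smAD_ALT``.  Broadcasts over array inputs."""
    dp = np.asarray(dp)
    if np.any(dp < 0):
        raise ValueError("depths must be non-negative")
    sm_alt = rng.binomial(dp, allele_freq)
    return dp - sm_alt, sm_alt


def _prepare_grid(dp_fb: np.ndarray, dp_sb: np.ndarray) -> FisherGrid:
    grid = FisherGrid()
    grid.prepare(dp_fb, dp_sb)
    return grid


def simulate_ratio_once(dps, model: NullModel, rng: np.random.Generator,
                        grid: FisherGrid | None = None) -> float:
    """One replicate of the simulated sSNP/totalSNP ratio for given depth
    pairs ``dps = [(dp_fb, dp_sb), ...]``."""
    dp = np.asarray(dps, dtype=np.int64)
    if dp.size == 0:
        raise ValueError("dps must be non-empty")
    dp_fb, dp_sb = dp[:, 0], dp[:, 1]
    if grid is None:
        grid = _prepare_grid(dp_fb, dp_sb)
    f1 = sm_allele_freq(model, 1, rng)
    f2 = sm_allele_freq(model, 2, rng)
    _, alt1 = sm_ad(dp_fb, f1, rng)
    _, alt2 = sm_ad(dp_sb, f2, rng)
    p = grid.pvalues(alt1, alt2)
    return float(np.mean(p < model.alpha_sim))


def _simulated_ratios(dp_fb: np.ndarray, dp_sb: np.ndarray, model: NullModel,
                      rng: np.random.Generator, grid: FisherGrid) -> np.ndarray:
    """Vector of ``model.n_reps`` simulated sSNP ratios for a fixed SNP set."""
    reps = model.n_reps
    f1 = sm_allele_freq(model, 1, rng, size=reps)[:, None]
    f2 = sm_allele_freq(model, 2, rng, size=reps)[:, None]
    alt1 = rng.binomial(dp_fb[None, :], f1)
    alt2 = rng.binomial(dp_sb[None, :], f2)
    sig = grid.pvalues(alt1, alt2) < model.alpha_sim
    return sig.mean(axis=1)


def window_threshold(window_dps, model: NullModel, rng: np.random.Generator | None = None,
                     grid: FisherGrid | None = None) -> float:
    """Window-specific sSNP-ratio threshold: the ``ratio_percentile``-th
    percentile of ``n_reps`` simulated ratios of exactly this window's SNP
    depths.  Deterministic given ``model.seed`` when no rng is passed."""
    dp = np.asarray(window_dps, dtype=np.int64)
    if dp.size == 0:
        raise ValueError("window has no SNPs; threshold undefined")
    if rng is None:
        rng = model.rng()
    dp_fb, dp_sb = dp[:, 0], dp[:, 1]
    if grid is None:
        grid = _prepare_grid(dp_fb, dp_sb)
    ratios = _simulated_ratios(dp_fb, dp_sb, model, rng, grid)
    return float(np.percentile(ratios, model.ratio_percentile))


def genome_wide_threshold(table: SnpTable, avg_snps_per_window: int, model: NullModel,
                          rng: np.random.Generator | None = None) -> float:
    """Genome-wide sSNP-ratio threshold via resampling.

    Each of ``n_reps`` replicates samples ``avg_snps_per_window`` SNPs
    without replacement from the whole dataset, simulates null allele
    depths at their observed per-bulk depths, and records the simulated
    sSNP/totalSNP ratio; the threshold is the ``ratio_percentile``-th
    percentile of the replicate ratios.
    """
    if len(table) == 0:
        raise ValueError("table is empty")
    m = int(avg_snps_per_window)
    if m < 1:
        raise ValueError("avg_snps_per_window must be >= 1")
    if rng is None:
        rng = model.rng()
    df = table.df
    dp_fb = df["dp_fb"].to_numpy(np.int64)
    dp_sb = df["dp_sb"].to_numpy(np.int64)
    grid = _prepare_grid(dp_fb, dp_sb)
    m = min(m, len(df))

    reps = model.n_reps
    f1 = sm_allele_freq(model, 1, rng, size=reps)[:, None]
    f2 = sm_allele_freq(model, 2, rng, size=reps)[:, None]
    # one without-replacement sample of SNP indices per replicate
    idx = np.empty((reps, m), dtype=np.int64)
    for r in range(reps):
        idx[r] = rng.choice(len(df), size=m, replace=False)
    alt1 = rng.binomial(dp_fb[idx], f1)
    alt2 = rng.binomial(dp_sb[idx], f2)
    sig = grid.pvalues_at(idx, alt1, alt2) < model.alpha_sim
    ratios = sig.mean(axis=1)
    thr = float(np.percentile(ratios, model.ratio_percentile))
    logger.info("genome-wide sSNP-ratio threshold (m=%d, reps=%d): %.4f", m, reps, thr)
    return thr


def window_thresholds_batch(table: SnpTable, windows: pd.DataFrame, model: NullModel,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Window-specific sSNP-ratio thresholds for *every* window at once.

    Simulates one genome-wide replicate matrix (per-replicate bulk
    frequencies shared across SNPs, exactly as within a single window's
    simulation) and reduces it per window with cumulative sums.  Each
    window's marginal ratio distribution is identical to an independent
    :func:`window_threshold` run; replicates are shared across windows,
    which only smooths the Monte-Carlo jitter between overlapping windows.
    Returns one threshold per window (NaN for empty windows).
    """
    if rng is None:
        rng = model.rng()
    df = table.df
    dp_fb = df["dp_fb"].to_numpy(np.int64)
    dp_sb = df["dp_sb"].to_numpy(np.int64)
    grid = _prepare_grid(dp_fb, dp_sb)
    reps = model.n_reps
    n = len(df)

    sig_cum = np.zeros((reps, n + 1), dtype=np.float32)
    for s in range(0, n, 4 * _CHUNK):
        e = min(s + 4 * _CHUNK, n)
        f1 = sm_allele_freq(model, 1, rng, size=reps)[:, None]
        f2 = sm_allele_freq(model, 2, rng, size=reps)[:, None]
        alt1 = rng.binomial(dp_fb[None, s:e], f1)
        alt2 = rng.binomial(dp_sb[None, s:e], f2)
        sig_cum[:, s + 1:e + 1] = grid.pvalues_at(np.arange(s, e), alt1, alt2) < model.alpha_sim
    np.cumsum(sig_cum, axis=1, out=sig_cum)

    windows = windows.reset_index(drop=True)
    thresholds = np.full(len(windows), np.nan)
    chrom_pos = {c: np.flatnonzero((df["chrom"] == c).to_numpy()) for c in df["chrom"].unique()}
    pos_all = df["pos"].to_numpy()
    for chrom, grp in windows.groupby("chrom", sort=False):
        snp_idx = chrom_pos.get(chrom)
        if snp_idx is None or snp_idx.size == 0:
            continue
        base = snp_idx[0]
        pos = pos_all[snp_idx]
        lo = base + np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = base + np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        counts = (hi - lo).astype(float)
        nonempty = counts > 0
        if not nonempty.any():
            continue
        ratios = (sig_cum[:, hi[nonempty]] - sig_cum[:, lo[nonempty]]) / counts[nonempty]
        thresholds[np.asarray(grp.index)[nonempty]] = np.percentile(
            ratios, model.ratio_percentile, axis=0)
    return thresholds


def per_snp_delta_g_percentiles(table: SnpTable, model: NullModel,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulated null percentiles of delta(SNP index) and G for every SNP.

    Returns a frame aligned with ``table.df`` holding ``delta_lo`` /
    ``delta_hi`` (bounds of the central ``delta_ci`` interval) and
    ``g_thr`` (the ``g_percentile``-th percentile).
    """
    from .association_stats import delta_snp_index, g_statistic

    if rng is None:
        rng = model.rng()
    df = table.df
    dp_fb = df["dp_fb"].to_numpy(np.int64)
    dp_sb = df["dp_sb"].to_numpy(np.int64)
    n = len(df)
    reps = model.n_reps
    lo_q = 100.0 * (1.0 - model.delta_ci) / 2.0
    hi_q = 100.0 - lo_q

    delta_lo = np.empty(n)
    delta_hi = np.empty(n)
    g_thr = np.empty(n)
    for s in range(0, n, _CHUNK):
        e = min(s + _CHUNK, n)
        f1 = sm_allele_freq(model, 1, rng, size=reps)[:, None]
        f2 = sm_allele_freq(model, 2, rng, size=reps)[:, None]
        alt1 = rng.binomial(dp_fb[None, s:e], f1)
        alt2 = rng.binomial(dp_sb[None, s:e], f2)
        ref1 = dp_fb[s:e] - alt1
        ref2 = dp_sb[s:e] - alt2
        delta = delta_snp_index(alt1, dp_fb[s:e], alt2, dp_sb[s:e])
        g = g_statistic(ref1, alt1, ref2, alt2)
        delta_lo[s:e] = np.nanpercentile(delta, lo_q, axis=0)
        delta_hi[s:e] = np.nanpercentile(delta, hi_q, axis=0)
        g_thr[s:e] = np.percentile(g, model.g_percentile, axis=0)
    return pd.DataFrame({"delta_lo": delta_lo, "delta_hi": delta_hi, "g_thr": g_thr})


def delta_and_g_thresholds(table: SnpTable, windows: pd.DataFrame, model: NullModel,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Window-level threshold curves for the delta(SNP index) and G methods.

    The per-SNP null percentiles are averaged over each sliding window,
    mirroring how the observed statistics are window-averaged.  Returns the
    ``windows`` frame with ``delta_lo``, ``delta_hi`` and ``g_threshold``
    columns (NaN for empty windows; fill afterwards if needed).
    """
    pct = per_snp_delta_g_percentiles(table, model, rng=rng)
    means = sliding_window.window_means(
        table, windows,
        {"dlo": pct["delta_lo"].to_numpy(),
         "dhi": pct["delta_hi"].to_numpy(),
         "g": pct["g_thr"].to_numpy()},
    )
    out = windows.reset_index(drop=True).copy()
    out["delta_lo"] = means["mean_dlo"]
    out["delta_hi"] = means["mean_dhi"]
    out["g_threshold"] = means["mean_g"]
    return out
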