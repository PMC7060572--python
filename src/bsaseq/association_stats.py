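"""Per-SNP association statistics for two-bulk allele-depth tables.

For each SNP the 2x2 contingency table of read counts

    =========  =======  =======
    .          REF      ALT
    =========  =======  =======
    bulk 1     AD_REF1  AD_ALT1
    bulk 2     AD_REF2  AD_ALT2
    =========  =======  =======

is scored three ways:

* two-sided Fisher's exact test p-value (minimum-likelihood rule); a SNP
  with p below the significance level is a *significant SNP* (sSNP);
* the SNP-index difference ``delta = AD_ALT2/DP2 - AD_ALT1/DP1``, the
  between-bulk difference of ALT allele-frequency estimates;
* the log-likelihood-ratio (G-test) statistic
  ``G = 2 * sum_i O_i * ln(O_i / E_i)`` over the four cells, with expected
  counts from the table margins under independence.

Scalar entry points wrap :mod:`scipy.stats`; the :class:`FisherGrid` cache
precomputes whole p-value lookup tables per (DP1, DP2) pair so that the
resampling machinery can score millions of simulated tables cheaply.  The
two code paths implement the identical two-sided rule and agree to within
numerical round-off.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.special import gammaln, xlogy

from .snp_io import SnpTable

logger = logging.getLogger(__name__)

# relative tie tolerance of the minimum-likelihood two-sided rule; matches
# the convention used by the common Fisher's-exact implementations
_TIE_REL = 1e-7


def fisher_exact_p(ad_ref_fb: int, ad_alt_fb: int, ad_ref_sb: int, ad_alt_sb: int) -> float:
    """Two-sided Fisher's exact p for one allele-depth table.

    Any zero margin (e.g. a bulk with zero depth, or no ALT reads in either
    bulk) yields p = 1.0: the table carries no evidence of differential
    enrichment.
    """
    if min(ad_ref_fb, ad_alt_fb, ad_ref_sb, ad_alt_sb) < 0:
        raise ValueError("allele depths must be non-negative")
    if (ad_ref_fb + ad_alt_fb == 0 or ad_ref_sb + ad_alt_sb == 0
            or ad_ref_fb + ad_ref_sb == 0 or ad_alt_fb + ad_alt_sb == 0):
        return 1.0
    return float(stats.fisher_exact(
        [[ad_ref_fb, ad_alt_fb], [ad_ref_sb, ad_alt_sb]], alternative="two-sided"
    ).pvalue)


def _log_comb(n, r):
    return gammaln(n + 1.0) - gammaln(r + 1.0) - gammaln(n - r + 1.0)


def fisher_p_grid(dp_fb: int, dp_sb: int) -> np.ndarray:
    """Two-sided Fisher p for every table with fixed row margins.

    Returns an array ``P`` of shape ``(dp_fb + 1, dp_sb + 1)`` with
    ``P[alt1, alt2]`` the p-value of
    ``[[dp_fb - alt1, alt1], [dp_sb - alt2, alt2]]``.

    The conditional distribution of ``alt1`` given the ALT column total
    ``A = alt1 + alt2`` is hypergeometric; the two-sided p sums the
    probabilities of all tables in that support whose probability does not
    exceed the observed one.
    """
    n1, n2 = int(dp_fb), int(dp_sb)
    N = n1 + n2
    if N == 0:
        return np.ones((1, 1))
    k = np.arange(n1 + 1, dtype=float)          # alt reads in bulk 1
    A = np.arange(N + 1, dtype=float)[:, None]  # ALT column total
    valid = (k[None, :] <= A) & (n1 - k[None, :] <= N - A)
    with np.errstate(invalid="ignore"):
        logpmf = _log_comb(A, k[None, :]) + _log_comb(N - A, n1 - k[None, :]) - _log_comb(float(N), float(n1))
    pmf = np.where(valid, np.exp(logpmf), 0.0)  # (N+1, n1+1)

    # p[A, x] = sum over k of pmf[A, k] where pmf[A, k] <= pmf[A, x] * (1 + tol)
    le = pmf[:, None, :] <= pmf[:, :, None] * (1.0 + _TIE_REL)
    p_by_total = (pmf[:, None, :] * le).sum(axis=2)  # (N+1, n1+1)

    a1 = np.arange(n1 + 1)[:, None]
    a2 = np.arange(n2 + 1)[None, :]
    P = p_by_total[a1 + a2, np.broadcast_to(a1, (n1 + 1, n2 + 1))]
    return np.clip(P, 0.0, 1.0)


class FisherGrid:
    """Cache of per-(DP1, DP2) Fisher p-value grids with flat vectorized lookup.

    ``prepare(dp_fb, dp_sb)`` registers the depth pairs of a SNP set and
    builds one grid per distinct pair; ``pvalues(alt_fb, alt_sb)`` then maps
    simulated (or observed) ALT counts of any shape ``(..., n_snps)`` to
    p-values via integer indexing.
    """

    def __init__(self):
        self._grids: dict[tuple[int, int], np.ndarray] = {}
        self._flat: np.ndarray | None = None
        self._offsets: np.ndarray | None = None
        self._width: np.ndarray | None = None

    def grid(self, dp_fb: int, dp_sb: int) -> np.ndarray:
        key = (int(dp_fb), int(dp_sb))
        g = self._grids.get(key)
        if g is None:
            g = self._grids[key] = fisher_p_grid(*key)
        return g

    def prepare(self, dp_fb: np.ndarray, dp_sb: np.ndarray) -> None:
        dp_fb = np.asarray(dp_fb, dtype=np.int64)
        dp_sb = np.asarray(dp_sb, dtype=np.int64)
        pairs = np.stack([dp_fb, dp_sb], axis=1)
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        grids = [self.grid(d1, d2).ravel() for d1, d2 in uniq]
        sizes = np.array([g.size for g in grids], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self._flat = np.concatenate(grids)
        self._offsets = starts[inv]
        self._width = (uniq[:, 1] + 1)[inv]  # row stride = dp_sb + 1

    def pvalues(self, alt_fb: np.ndarray, alt_sb: np.ndarray) -> np.ndarray:
        """p-values for ALT-count arrays of shape (..., n_snps)."""
        if self._flat is None:
            raise RuntimeError("call prepare() with the SNP depth pairs first")
        idx = self._offsets + alt_fb * self._width + alt_sb
        return self._flat[idx]

    def pvalues_at(self, snp_idx: np.ndarray, alt_fb: np.ndarray, alt_sb: np.ndarray) -> np.ndarray:
        """As :meth:`pvalues` for a subset/resampling ``snp_idx`` of the
        prepared SNPs (same shape as the ALT-count arrays)."""
        if self._flat is None:
            raise RuntimeError("call prepare() with the SNP depth pairs first")
        idx = self._offsets[snp_idx] + alt_fb * self._width[snp_idx] + alt_sb
        return self._flat[idx]


def fisher_exact_vec(ad_ref_fb, ad_alt_fb, ad_ref_sb, ad_alt_sb) -> np.ndarray:
    """Vectorized two-sided Fisher p over arrays of tables (grid-backed)."""
    alt1 = np.asarray(ad_alt_fb, dtype=np.int64)
    alt2 = np.asarray(ad_alt_sb, dtype=np.int64)
    dp1 = np.asarray(ad_ref_fb, dtype=np.int64) + alt1
    dp2 = np.asarray(ad_ref_sb, dtype=np.int64) + alt2
    cache = FisherGrid()
    cache.prepare(dp1, dp2)
    return cache.pvalues(alt1, alt2)


def delta_snp_index(ad_alt_fb, dp_fb, ad_alt_sb, dp_sb) -> np.ndarray:
    """SNP-index difference ``AD_ALT2/DP2 - AD_ALT1/DP1`` (second minus
    first bulk).  Zero depth in either bulk yields NaN (undefined; such
    records are excluded from window means)."""
    dp_fb = np.asarray(dp_fb, dtype=float)
    dp_sb = np.asarray(dp_sb, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(ad_alt_sb, dtype=float) / dp_sb - np.asarray(ad_alt_fb, dtype=float) / dp_fb
    return np.where((dp_fb > 0) & (dp_sb > 0), out, np.nan)


def g_statistic(ad_ref_fb, ad_alt_fb, ad_ref_sb, ad_alt_sb) -> np.ndarray:
    """G-test statistic ``2 * sum O * ln(O/E)`` of the allele-depth table.

    Expected counts come from the table margins under independence; cells
    with an observed zero contribute zero, and an all-zero table gives
    G = 0 by convention.
    """
    a = np.asarray(ad_ref_fb, dtype=float)
    b = np.asarray(ad_alt_fb, dtype=float)
    c = np.asarray(ad_ref_sb, dtype=float)
    d = np.asarray(ad_alt_sb, dtype=float)
    n1, n2 = a + b, c + d
    ref_tot, alt_tot = a + c, b + d
    N = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_n = np.where(N > 0, N, 1.0)
        g = 2.0 * (
            xlogy(a, a * safe_n) - xlogy(a, n1 * ref_tot)
            + xlogy(b, b * safe_n) - xlogy(b, n1 * alt_tot)
            + xlogy(c, c * safe_n) - xlogy(c, n2 * ref_tot)
            + xlogy(d, d * safe_n) - xlogy(d, n2 * alt_tot)
        )
    g = np.where(N > 0, g, 0.0)
    # clamp tiny negative round-off on (near-)proportional tables
    return np.maximum(g, 0.0)


def classify_ssnps(table: SnpTable, alpha: float = 0.01) -> np.ndarray:
    """Per-record sSNP flags: ``p_fisher < alpha`` (strict).

    Also attaches ``p_fisher``, ``delta_snp_index``, ``g_stat`` and
    ``is_ssnp`` columns to ``table.df`` as a side effect, so downstream
    windowing and export can reuse them.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = table.df
    if df[["ad_ref_fb", "ad_alt_fb", "ad_ref_sb", "ad_alt_sb"]].isna().any().any():
        raise ValueError("classify_ssnps requires a table with no missing allele depths; run filter_basic first")
    a = df["ad_ref_fb"].to_numpy(np.int64)
    b = df["ad_alt_fb"].to_numpy(np.int64)
    c = df["ad_ref_sb"].to_numpy(np.int64)
    d = df["ad_alt_sb"].to_numpy(np.int64)
    p = fisher_exact_vec(a, b, c, d)
    df["p_fisher"] = p
    df["delta_snp_index"] = delta_snp_index(b, a + b, d, c + d)
    df["g_stat"] = g_statistic(a, b, c, d)
    flags = p < alpha
    df["is_ssnp"] = flags
    logger.info("sSNPs at alpha=%g: %d / %d", alpha, int(flags.sum()), len(df))
    return flags
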