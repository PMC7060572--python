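import numpy as np
import pytest

from bsaseq import snp_io
from bsaseq.synthetic_bsa import SimDesign, simulate_table

# First five data rows of a GATK-derived two-bulk SNP table (rice cold
# tolerance bulks, sample IDs 834927/834931); used as the worked example
# throughout the unit tests.
TABLE2_TSV = """\
CHROM\tPOS\tREF\tALT\t834927.AD\t834927.GQ\t834931.AD\t834931.GQ
1\t29759\tC\tG\t0,26\t1\t0,26\t13
1\t31071\tA\tG\t25,39\t99\t33,29\t99
1\t31478\tC\tT\t27,38\t99\t48,32\t99
1\t33667\tA\tG\t21,46\t99\t39,32\t99
1\t34057\tC\tT\t29,37\t99\t32,31\t99
"""

#: (ad_ref_fb, ad_alt_fb, ad_ref_sb, ad_alt_sb) per row, by POS
TABLE2_ADS = {
    29759: (0, 26, 0, 26),
    31071: (25, 39, 33, 29),
    31478: (27, 38, 48, 32),
    33667: (21, 46, 39, 32),
    34057: (29, 37, 32, 31),
}


@pytest.fixture
def table2_path(tmp_path):
    path = tmp_path / "table2.tsv"
    path.write_text(TABLE2_TSV)
    return path


@pytest.fixture
def table2(table2_path):
    return snp_io.read_snp_tsv(table2_path, "834927", "834931")


@pytest.fixture(scope="session")
def null_table_small():
    """~2,000-SNP null dataset (no QTL) on two 2.5-Mb chromosomes, 30x."""
    design = SimDesign(
        chrom_lengths={"1": 2_500_000, "2": 2_500_000},
        snp_density=4e-4, coverage=30.0, seed=421,
    )
    table, _ = simulate_table(design)
    return table


def exhaustive_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: two-sided Fisher p by exhaustive hypergeometric
    enumeration (minimum-likelihood rule), via lgamma only."""
    import math

    n1, n2 = a + b, c + d
    N = n1 + n2
    if N == 0 or n1 == 0 or n2 == 0 or a + c == 0 or b + d == 0:
        return 1.0
    R = a + c

    def log_comb(n, r):
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    def pmf(k):
        return math.exp(log_comb(n1, k) + log_comb(n2, R - k) - log_comb(N, R))

    lo, hi = max(0, R - n2), min(n1, R)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)
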