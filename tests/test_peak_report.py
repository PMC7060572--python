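import numpy as np
import pandas as pd
import pytest

from bsaseq import peak_report as pr
from bsaseq.null_simulation import NullModel
from bsaseq.snp_io import SnpTable


def _track(ratios, chrom="1"):
    n = len(ratios)
    return pd.DataFrame({
        "chrom": chrom, "start": np.arange(n) * 10_000 + 1,
        "end": np.arange(n) * 10_000 + 100_001,
        "n_snps": 50,
        "n_ssnps": np.nan_to_num(np.asarray(ratios, dtype=float) * 50).astype(int),
        "ratio": ratios, "mean_delta": 0.0, "mean_g": 1.0, "filled": False,
    })


class TestFindCandidatePeaks:
    def test_all_below_threshold_gives_empty(self):
        out = pr.find_candidate_peaks(_track([0.01, 0.02, 0.01]), 0.1)
        assert len(out) == 0

    def test_single_run_yields_its_argmax(self):
        out = pr.find_candidate_peaks(_track([0.01, 0.2, 0.5, 0.3, 0.01]), 0.1)
        assert len(out) == 1 and out.iloc[0]["ratio"] == 0.5

    def test_two_runs_give_two_candidates(self):
        out = pr.find_candidate_peaks(
            _track([0.3, 0.05, 0.05, 0.2, 0.4, 0.05]), 0.1)
        assert list(out["ratio"]) == [0.3, 0.4]

    def test_tie_breaks_to_smaller_start(self):
        out = pr.find_candidate_peaks(_track([0.4, 0.4, 0.4]), 0.1)
        assert len(out) == 1 and out.iloc[0]["start"] == 1

    def test_runs_do_not_span_chromosomes(self):
        t1, t2 = _track([0.3, 0.3]), _track([0.3, 0.3], chrom="2")
        track = pd.concat([t1, t2], ignore_index=True)
        out = pr.find_candidate_peaks(track, 0.1)
        assert list(out["chrom"]) == ["1", "2"]

    def test_strict_inequality_at_threshold(self):
        out = pr.find_candidate_peaks(_track([0.1, 0.1]), 0.1)
        assert len(out) == 0

    def test_nan_track_rejected(self):
        track = _track([0.1, np.nan])
        with pytest.raises(ValueError, match="fill_empty_windows"):
            pr.find_candidate_peaks(track, 0.05)


def _snp_table(n, dp=30, alt_frac=0.5, chrom="1", span=100_000, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(span, size=n, replace=False)) + 1
    alt1 = rng.binomial(dp, alt_frac, size=n)
    alt2 = rng.binomial(dp, 1 - alt_frac, size=n)
    return SnpTable(pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
        "ad_ref_fb": dp - alt1, "ad_alt_fb": alt1, "gq_fb": 99,
        "ad_ref_sb": dp - alt2, "ad_alt_sb": alt2, "gq_sb": 99,
    }))


class TestVerifyPeaks:
    def test_extreme_ratio_verified_significant(self):
        table = _snp_table(200, alt_frac=0.9, seed=1)
        cand = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [100_001], "ratio": [0.9]})
        peaks = pr.verify_peaks(cand, table, NullModel(n_reps=500, seed=2))
        assert peaks[0].verdict == "significant"
        assert peaks[0].n_snps == 200

    def test_null_level_ratio_demoted(self):
        table = _snp_table(200, alt_frac=0.5, seed=1)
        cand = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [100_001], "ratio": [0.02]})
        peaks = pr.verify_peaks(cand, table, NullModel(n_reps=500, seed=2))
        assert peaks[0].verdict == "false_positive"

    def test_empty_candidate_window_flagged(self):
        table = _snp_table(50, seed=3)
        cand = pd.DataFrame({"chrom": ["1"], "start": [5_000_000], "end": [5_100_000], "ratio": [0.5]})
        peaks = pr.verify_peaks(cand, table, NullModel(n_reps=100, seed=2))
        assert peaks[0].verdict == "false_positive"
        assert peaks[0].n_snps == 0 and np.isnan(peaks[0].window_threshold)

    def test_deterministic_verdicts_under_seed(self):
        table = _snp_table(100, alt_frac=0.6, seed=5)
        cand = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [100_001], "ratio": [0.3]})
        model = NullModel(n_reps=400, seed=11)
        p1 = pr.verify_peaks(cand, table, model)
        p2 = pr.verify_peaks(cand, table, model)
        assert p1 == p2

    def test_verification_only_demotes(self):
        # every verified-significant peak came from an above-threshold run
        table = _snp_table(300, alt_frac=0.8, seed=7)
        track = _track([0.05, 0.4, 0.05])
        genome_thr = 0.1
        cand = pr.find_candidate_peaks(track, genome_thr)
        peaks = pr.verify_peaks(cand, table, NullModel(n_reps=300, seed=1))
        for p in peaks:
            if p.verdict == "significant":
                assert p.observed_ratio > genome_thr


class TestDetectAndVerifyPeaks:
    def test_demoted_tiny_window_unmasks_real_peak(self):
        # run argmax is a 1-SNP window with ratio 1.0; its window-specific
        # threshold is also 1.0 so it is demoted, and the next-highest
        # window (the genuine enriched region) must then be examined
        rng = np.random.default_rng(2)
        n, dp = 400, 30
        pos = np.sort(rng.choice(200_000, size=n, replace=False)) + 1
        alt1 = rng.binomial(dp, 0.8, size=n)
        alt2 = rng.binomial(dp, 0.2, size=n)
        table = SnpTable(pd.DataFrame({
            "chrom": "1", "pos": np.append(pos, 900_000), "ref": "A", "alt": "T",
            "ad_ref_fb": np.append(dp - alt1, 0), "ad_alt_fb": np.append(alt1, dp), "gq_fb": 99,
            "ad_ref_sb": np.append(dp - alt2, dp), "ad_alt_sb": np.append(alt2, 0), "gq_sb": 99,
        }))
        track = pd.DataFrame({
            "chrom": "1",
            "start": [1, 850_001],
            "end": [850_001, 1_000_001],
            "n_snps": [n, 1], "n_ssnps": [int(0.9 * n), 1],
            "ratio": [0.9, 1.0], "mean_delta": 0.0, "mean_g": 1.0, "filled": False,
        })
        peaks = pr.detect_and_verify_peaks(track, 0.1, table, NullModel(n_reps=400, seed=3))
        verdicts = {(p.window_start, p.verdict) for p in peaks}
        assert (850_001, "false_positive") in verdicts
        assert (1, "significant") in verdicts

    def test_all_attempts_reported_and_capped(self):
        table = _snp_table(50, alt_frac=0.5, seed=9, span=600_000)
        track = pd.DataFrame({
            "chrom": "1", "start": np.arange(6) * 100_000 + 1,
            "end": np.arange(6) * 100_000 + 100_001,
            "n_snps": 5, "n_ssnps": 4, "ratio": np.linspace(0.9, 0.4, 6),
            "mean_delta": 0.0, "mean_g": 1.0, "filled": False,
        })
        peaks = pr.detect_and_verify_peaks(track, 0.1, table, NullModel(n_reps=400, seed=3),
                                           max_attempts=3)
        assert len(peaks) <= 3


class TestOutputs:
    def test_csv_roundtrip(self, tmp_path):
        peaks = [
            pr.PeakRecord("1", 1, 100_001, 0.42, 321, 0.08, "significant"),
            pr.PeakRecord("2", 50_001, 150_001, 0.09, 60, 0.12, "false_positive"),
        ]
        path = tmp_path / "peaks.csv"
        pr.write_peak_csv(peaks, path)
        assert pr.read_peak_csv(path) == peaks

    def test_zero_candidates_header_only_csv(self, tmp_path):
        path = tmp_path / "peaks.csv"
        pr.write_peak_csv([], path)
        assert path.read_text().strip() == ",".join(pr.PEAK_CSV_COLUMNS)

    def test_render_outputs_files_exist(self, tmp_path):
        track = _track([0.05, 0.2, 0.05])
        peaks = [pr.PeakRecord("1", 10_001, 110_001, 0.2, 50, 0.1, "significant")]
        paths = pr.render_outputs(track, 0.1, peaks, tmp_path, figure_format="png")
        assert paths["csv"].exists() and paths["csv"].stat().st_size > 0
        assert paths["figure"].exists() and paths["figure"].stat().st_size > 0
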