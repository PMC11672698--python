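"""The scan core: Nei F_ST, local regression, control chart, signatures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstscan.env_grouping import assign_groups
from fstscan.fst_scan import (
    OutlierCall,
    ScanParams,
    cluster_signatures,
    detect_outliers,
    group_allele_frequencies,
    loess_span,
    lowess_smooth_chromosome,
    nei_fst,
    run_scan,
)
from fstscan.io_formats import MISSING, GenotypeDataset


def gst_oracle(freqs):
    """Generic k-population G_ST: 1 - H_S/H_T, coded independently."""
    freqs = np.asarray(freqs, float)
    p_bar = freqs.mean()
    h_t = 2 * p_bar * (1 - p_bar)
    h_s = np.mean(2 * freqs * (1 - freqs))
    if h_t == 0:
        return math.nan
    return 1.0 - h_s / h_t


def lowess_oracle(x, y, span):
    """Per-point weighted least-squares solve via lstsq (independent route)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = min(n, max(1, math.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nb = np.argsort(d, kind="stable")[:q]
        dm = d[nb].max()
        if dm == 0:
            out[i] = y[nb].mean()
            continue
        w = (1 - (d[nb] / dm) ** 3) ** 3
        design = np.column_stack([np.ones(q), x[nb]])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(sw[:, None] * design, sw * y[nb], rcond=None)
        out[i] = beta[0] + beta[1] * x[i]
    return out


class TestNeiFst:
    def test_equal_frequencies_give_zero(self):
        _, _, fst = nei_fst(0.3, 0.3)
        assert fst == pytest.approx(0.0, abs=1e-15)

    def test_fixed_alternative_alleles_give_one(self):
        _, _, fst = nei_fst(0.0, 1.0)
        assert fst == pytest.approx(1.0, abs=1e-15)

    def test_hand_derived_case(self):
        h_t, h_s, fst = nei_fst(0.2, 0.8)
        assert h_t == pytest.approx(0.5, abs=1e-12)
        assert h_s == pytest.approx(0.32, abs=1e-12)
        assert fst == pytest.approx(0.36, abs=1e-12)

    def test_undefined_when_pooled_monomorphic(self):
        _, _, fst = nei_fst(0.0, 0.0)
        assert math.isnan(fst)

    def test_matches_generic_gst_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            p1, p2 = rng.random(2)
            _, _, fst = nei_fst(p1, p2)
            assert fst == pytest.approx(gst_oracle([p1, p2]), abs=1e-12)

    # frequencies quantized so 1-p is exactly representable (sub-epsilon
    # values make h_t underflow on one side of the swap)
    @settings(max_examples=100, derandomize=True)
    @given(
        p1=st.floats(0, 1).map(lambda v: round(v, 6)),
        p2=st.floats(0, 1).map(lambda v: round(v, 6)),
    )
    def test_invariant_to_allele_coding_swap(self, p1, p2):
        _, _, a = nei_fst(p1, p2)
        _, _, b = nei_fst(1 - p1, 1 - p2)
        if math.isnan(a):
            assert math.isnan(b)
        else:
            assert a == pytest.approx(b, abs=1e-12)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            nei_fst(-0.1, 0.5)


class TestLoessSpan:
    @pytest.mark.parametrize("n,expected", [(1000, 0.02), (40, 0.5), (20, 1.0), (10, 1.0)])
    def test_window_rule(self, n, expected):
        assert loess_span(n) == pytest.approx(expected)

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            loess_span(0)


class TestLowessSmoothing:
    def test_exact_line_reproduced_at_full_span(self):
        x = np.sort(np.random.default_rng(0).choice(10_000, 30, replace=False)).astype(float)
        y = 1.5 + 0.002 * x
        smoothed = lowess_smooth_chromosome(x, y, span=1.0)
        assert np.allclose(smoothed, y, atol=1e-10)

    def test_constant_values_stay_constant(self):
        x = np.arange(1, 21, dtype=float)
        smoothed = lowess_smooth_chromosome(x, np.full(20, 0.7), span=0.5)
        assert np.allclose(smoothed, 0.7, atol=1e-12)

    def test_matches_per_point_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.choice(1_000_000, 15, replace=False)).astype(float)
        y = rng.normal(size=15)
        mine = lowess_smooth_chromosome(x, y, span=0.5)
        assert np.allclose(mine, lowess_oracle(x, y, 0.5), atol=1e-8)

    def test_smoothing_reduces_white_noise_variance(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.choice(10_000_000, 200, replace=False)).astype(float)
            y = rng.normal(size=200)
            smoothed = lowess_smooth_chromosome(x, y, span=0.1)
            assert smoothed.var() < y.var()

    def test_invalid_inputs_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError):
            lowess_smooth_chromosome(x, np.ones(5), span=1.5)
        with pytest.raises(ValueError):
            lowess_smooth_chromosome([1.0], [2.0], span=0.5)
        with pytest.raises(ValueError):
            lowess_smooth_chromosome([1.0, 1.0, 2.0], np.ones(3), span=0.5)
        with pytest.raises(ValueError):
            lowess_smooth_chromosome(x, [1, 2, np.nan, 4, 5], span=0.5)


class TestDetectOutliers:
    def test_constant_values_give_zero_sd_and_no_flags(self):
        call = detect_outliers(list("abcde"), [0.3] * 5, chromosome=1)
        assert call.sd_smoothed == 0.0
        assert call.flagged_snp_ids == []

    def test_hand_arithmetic_single_spike_among_five(self):
        call = detect_outliers(list("abcde"), [1, 1, 1, 1, 10], chromosome=1)
        assert call.mean_smoothed == pytest.approx(2.8)
        assert call.sd_smoothed == pytest.approx(4.02492, abs=1e-5)
        assert call.upper_limit == pytest.approx(14.8748, abs=1e-4)
        assert call.flagged_snp_ids == []

    def test_hand_arithmetic_spike_among_ten(self):
        ids = [f"s{i}" for i in range(10)]
        call = detect_outliers(ids, [0] * 9 + [1], chromosome=1)
        assert call.mean_smoothed == pytest.approx(0.1)
        assert call.sd_smoothed == pytest.approx(0.316228, abs=1e-6)
        assert call.upper_limit == pytest.approx(1.048683, abs=1e-6)
        assert call.flagged_snp_ids == []
        # a spike of 2 still cannot exceed mean + 3 sample SDs: the maximum
        # standardized deviation for n=10 is (n-1)/sqrt(n) = 2.846 < 3
        call2 = detect_outliers(ids, [0] * 9 + [2], chromosome=1)
        assert call2.upper_limit == pytest.approx(2.097366, abs=1e-6)
        assert call2.flagged_snp_ids == []
        # the moving-range sigma estimate does flag it
        call3 = detect_outliers(
            ids, [0] * 9 + [2], chromosome=1, sd_estimator="moving_range"
        )
        assert call3.upper_limit == pytest.approx(0.2 + 3 * (2 / 9) / 1.128, abs=1e-9)
        assert call3.flagged_snp_ids == ["s9"]

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers(["a"], [1.0], chromosome=1)


class TestClusterSignatures:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position", "fst_smoothed"])

    def test_nearby_outliers_merge_into_one_signature(self):
        df = self._frame(
            [("a", 1, 1_000_000, 0.1), ("b", 1, 1_050_000, 0.3), ("c", 1, 1_100_000, 0.2)]
        )
        sigs = cluster_signatures(df, max_gap=1_000_000)
        assert len(sigs) == 1
        sig = sigs.iloc[0]
        assert (sig["start"], sig["end"], sig["n_outlier_snps"]) == (1_000_000, 1_100_000, 3)
        assert sig["peak_snp_id"] == "b"

    def test_wide_gap_splits_signatures(self):
        df = self._frame([("a", 1, 1_000_000, 0.1), ("b", 1, 3_000_000, 0.2)])
        assert len(cluster_signatures(df, max_gap=1_000_000)) == 2

    def test_chromosome_boundary_never_merges(self):
        df = self._frame([("a", 1, 1_000_000, 0.1), ("b", 2, 1_000_000, 0.2)])
        assert len(cluster_signatures(df, max_gap=10_000_000)) == 2

    def test_peak_tie_goes_to_lowest_position(self):
        df = self._frame([("a", 1, 100, 0.5), ("b", 1, 200, 0.5)])
        assert cluster_signatures(df)["peak_snp_id"].iloc[0] == "a"

    def test_empty_input_gives_empty_table(self):
        assert len(cluster_signatures(self._frame([]))) == 0


class TestGroupFrequencies:
    def _dataset(self, calls):
        n, m = calls.shape
        return GenotypeDataset(
            samples=pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(n)], "flock_id": "F"}
            ),
            markers=pd.DataFrame(
                {
                    "snp_id": [f"m{j}" for j in range(m)],
                    "chromosome": 1,
                    "position": (np.arange(m) + 1) * 100,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            ),
            calls=calls.astype(np.int8),
        )

    def _assignment(self, groups):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(groups))],
                "flock_id": "F",
                "station_id": "ST",
                "distance_km": 1.0,
                "group": groups,
            }
        )

    def test_two_sample_group_with_opposite_homozygotes(self):
        calls = np.array([[0], [2], [1], [1]])
        freqs = group_allele_frequencies(
            self._dataset(calls), self._assignment(["CE", "CE", "HE", "HE"])
        )
        assert freqs["p1"].iloc[0] == pytest.approx(0.5)
        assert freqs["p2"].iloc[0] == pytest.approx(0.5)
        assert freqs["n1"].iloc[0] == 2

    def test_all_missing_group_flags_undefined(self):
        calls = np.array([[MISSING], [MISSING], [1], [2]])
        freqs = group_allele_frequencies(
            self._dataset(calls), self._assignment(["CE", "CE", "HE", "HE"])
        )
        assert not freqs["defined"].iloc[0]

    def test_hand_counted_five_sample_fixture(self):
        calls = np.array([[0], [1], [2], [2], [1]])
        freqs = group_allele_frequencies(
            self._dataset(calls), self._assignment(["CE", "CE", "CE", "HE", "HE"])
        )
        assert freqs["p1"].iloc[0] == pytest.approx(3 / 6)
        assert freqs["p2"].iloc[0] == pytest.approx(3 / 4)

    def test_missing_group_entirely_raises(self):
        calls = np.array([[0], [1]])
        with pytest.raises(ValueError):
            group_allele_frequencies(
                self._dataset(calls), self._assignment(["CE", "CE"])
            )


class TestRunScan:
    def test_sample_order_invariance(self, small_study):
        assignments = assign_groups(
            small_study.dataset.samples, small_study.flocks, small_study.stations
        )
        base = run_scan(small_study.dataset, assignments)

        rng = np.random.default_rng(3)
        perm = rng.permutation(small_study.dataset.n_samples)
        shuffled = GenotypeDataset(
            samples=small_study.dataset.samples.iloc[perm].reset_index(drop=True),
            markers=small_study.dataset.markers,
            calls=small_study.dataset.calls[perm],
        )
        other = run_scan(shuffled, assignments)
        pd.testing.assert_frame_equal(base.scan_table, other.scan_table)
        pd.testing.assert_frame_equal(base.signatures, other.signatures)

    def test_scan_table_is_manhattan_ready(self, small_study):
        assignments = assign_groups(
            small_study.dataset.samples, small_study.flocks, small_study.stations
        )
        result = run_scan(small_study.dataset, assignments)
        tab = result.scan_table
        for col in ("snp_id", "chromosome", "position", "p1", "p2", "h_t", "h_s",
                    "fst_raw", "fst_smoothed", "outlier"):
            assert col in tab.columns
        defined = tab[tab["defined"]]
        assert ((defined["fst_raw"] >= 0) & (defined["fst_raw"] <= 1)).all()
        assert (defined["h_s"] <= defined["h_t"] + 1e-12).all()
        # the planted region dominates the flags on its chromosome
        assert tab["outlier"].sum() >= 1
        assert len(result.signatures) >= 1
        assert (result.signatures["start"] <= result.signatures["end"]).all()

    def test_span_per_chromosome_uses_informative_markers(self, small_study):
        assignments = assign_groups(
            small_study.dataset.samples, small_study.flocks, small_study.stations
        )
        result = run_scan(small_study.dataset, assignments)
        assert all(call.sd_smoothed >= 0 for call in result.outlier_calls)
        assert len(result.outlier_calls) == small_study.dataset.markers["chromosome"].nunique()
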