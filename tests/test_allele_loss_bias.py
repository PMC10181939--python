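"""Neoepitope allele ratio, bucketed bootstraps and the KS bias tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from giescan import (
    bootstrap_bias, calibrated_bias_test, collect_records, ks_bias_test,
    neoepitope_ratio,
)
from giescan.allele_loss_bias import BUCKET_EDGES, bucket_of


class TestNeoepitopeRatio:
    @pytest.mark.parametrize("n1,n2,expected", [(120, 80, 0.6), (50, 50, 0.5)])
    def test_ratio(self, n1, n2, expected):
        assert neoepitope_ratio(n1, n2) == pytest.approx(expected)

    def test_undefined_ratio(self):
        with pytest.raises(ValueError, match="undefined"):
            neoepitope_ratio(0, 0)


class TestBuckets:
    def test_bounds_partition_unit_interval(self):
        assert BUCKET_EDGES[0] == 0.0 and BUCKET_EDGES[-1] == 1.0
        assert (np.diff(BUCKET_EDGES) > 0).all()

    def test_half_falls_in_045_05_bucket(self):
        b = bucket_of([0.5])
        lo, hi = BUCKET_EDGES[b[0]], BUCKET_EDGES[b[0] + 1]
        assert (lo, hi) == (0.45, 0.5)

    def test_right_closed_edges(self):
        assert bucket_of([0.35])[0] == 0
        assert bucket_of([0.35 + 1e-9])[0] == 1


def _events(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "pathway", "gene", "event_class", "focality",
                       "biallelic", "subclass"]
    )


def _hla(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "allele1", "allele2", "cn1", "cn2",
                       "neo1", "neo2"]
    )


class TestCollectRecords:
    def _tables(self):
        events = _events([
            ("s1", 1, "HLA-A", "LOH_HLA", "focal", False, ""),
            ("s1", 1, "HLA-B", "LOH_HLA", "highly_focal", False, ""),
            ("s1", 1, "HLA-C", "LOH_HLA", "focal", False, ""),   # homozygous
            ("s2", 1, "HLA-A", "LOH_HLA", "nonfocal", False, ""),
        ])
        hla = _hla([
            ("s1", "HLA-A", "A*01:01", "A*02:01", 0.1, 1.1, 100, 50),
            ("s1", "HLA-B", "B*01:01", "B*02:01", 1.0, 0.2, 80, 120),
            ("s1", "HLA-C", "C*01:01", "C*01:01", 0.1, 1.0, 60, 60),
            ("s2", "HLA-A", "A*03:01", "A*04:01", 0.0, 1.0, 10, 30),
        ])
        return hla, events

    def test_focality_filter_and_homozygous_exclusion(self):
        hla, events = self._tables()
        focal = collect_records(hla, events, "focal", seed=0)
        assert len(focal) == 2 and set(focal["gene"]) == {"HLA-A", "HLA-B"}
        nonfocal = collect_records(hla, events, "nonfocal", seed=0)
        assert len(nonfocal) == 1
        everything = collect_records(hla, events, "all", seed=0)
        assert len(everything) == 3

    def test_focal_subset_never_larger(self):
        hla, events = self._tables()
        assert len(collect_records(hla, events, "focal", seed=0)) <= len(
            collect_records(hla, events, "all", seed=0)
        )

    def test_lost_allele_and_nr_are_consistent(self):
        hla, events = self._tables()
        rec = collect_records(hla, events, "all", seed=0)
        row = rec[rec["gene"] == "HLA-A"].iloc[0]
        # s1/HLA-A: allele with 100 neoepitopes has CN 0.1 (lost); numbering may flip
        if row["a1_lost"]:
            assert row["nr"] == pytest.approx(100 / 150)
        else:
            assert row["nr"] == pytest.approx(50 / 150)

    def test_missing_cn_error(self):
        _, events = self._tables()
        with pytest.raises(ValueError, match="per-allele CN"):
            collect_records(_hla([]), events, "all", seed=0)

    def test_relabeling_under_different_seeds_mirrors(self):
        hla, events = self._tables()
        a = collect_records(hla, events, "all", seed=0)
        b = collect_records(hla, events, "all", seed=1)
        for (_, ra), (_, rb) in zip(a.iterrows(), b.iterrows()):
            same = ra["nr"] == pytest.approx(rb["nr"]) and ra["a1_lost"] == rb["a1_lost"]
            flipped = ra["nr"] == pytest.approx(1 - rb["nr"]) and \
                ra["a1_lost"] != rb["a1_lost"]
            assert same or flipped


def _records(nr, lost):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(nr))],
        "gene": "HLA-A", "nr": nr, "a1_lost": lost, "focality": "focal",
    })


class TestBootstrapBias:
    def test_all_lost_bucket_is_degenerate(self):
        rec = _records([0.52] * 10, [True] * 10)
        res = bootstrap_bias(rec, seed=0)
        row = res.buckets[res.buckets["n"] == 10].iloc[0]
        assert row["f_obs_mean"] == pytest.approx(1.0)
        assert row["f_obs_sd"] == pytest.approx(0.0)

    def test_subsample_size_is_floored(self):
        rec = _records([0.52] * 10, [True, False] * 5)
        res = bootstrap_bias(rec, seed=0)
        b = bucket_of([0.52])[0]
        # floor(0.75 * 10) = 7: every bootstrap F is a multiple of 1/7
        values = res.f_obs[b] * 7
        assert np.allclose(values, np.round(values))

    def test_fair_coin_expectation_is_half(self):
        rec = _records([0.52] * 200, [True] * 100 + [False] * 100)
        res = bootstrap_bias(rec, n_boot=400, seed=1)
        b = bucket_of([0.52])[0]
        se = res.buckets.set_index("bucket").loc[b, "f_exp_sd"] / np.sqrt(400)
        assert abs(res.buckets.set_index("bucket").loc[b, "f_exp_mean"] - 0.5) < 4 * se

    def test_empty_bucket_reported_with_nan(self):
        rec = _records([0.52] * 10, [True] * 10)
        res = bootstrap_bias(rec, seed=0)
        empty = res.buckets[res.buckets["n"] == 0]
        assert not empty.empty and empty["f_obs_mean"].isna().all()

    def test_relabeling_equivariance_elementwise(self):
        rng = np.random.default_rng(5)
        nr = rng.uniform(0.05, 0.95, 120)
        lost = rng.random(120) < 0.5
        rec = _records(nr, lost)
        mirrored = rec.copy()
        mirrored["nr"] = 1 - mirrored["nr"]
        mirrored["a1_lost"] = ~mirrored["a1_lost"]
        res = bootstrap_bias(rec, seed=3)
        res_m = bootstrap_bias(mirrored, seed=3)
        # bucket b maps to its mirror 7-b with identical record sets, hence
        # identical subsample draws and exactly mirrored observed F values
        for b, fo in res.f_obs.items():
            assert np.allclose(res_m.f_obs[7 - b], 1 - fo)
        counts = res.buckets.set_index("bucket")["n"]
        counts_m = res_m.buckets.set_index("bucket")["n"]
        for b in range(8):
            assert counts[b] == counts_m[7 - b]


class TestKSBiasTest:
    def test_identical_constant_arms_give_null(self):
        ks = stats.ks_2samp([0.5] * 8, [0.5] * 8)
        assert ks.statistic == 0.0 and ks.pvalue == 1.0

    def test_requires_two_buckets(self):
        rec = _records([0.52] * 10, [True] * 10)
        res = bootstrap_bias(rec, seed=0)
        with pytest.raises(ValueError, match="two non-empty"):
            ks_bias_test(res)

    def test_bucket_means_variant_runs(self):
        rng = np.random.default_rng(2)
        rec = _records(rng.uniform(0.05, 0.95, 200), rng.random(200) < 0.5)
        res = bootstrap_bias(rec, seed=2)
        pooled = ks_bias_test(res, "pooled")
        means = ks_bias_test(res, "bucket_means")
        assert pooled.variant == "pooled" and means.variant == "bucket_means"
        assert 0 <= means.D <= 1

    def test_calibrated_test_controls_null_rejection(self):
        # the Monte-Carlo-calibrated empirical p is approximately uniform under
        # fair-coin loss assignment
        rng = np.random.default_rng(10)
        rejections = 0
        n_runs = 20
        for k in range(n_runs):
            nr = rng.beta(8, 8, 300)
            lost = rng.random(300) < 0.5
            rec = _records(nr, lost)
            out = calibrated_bias_test(rec, n_null=59, seed=k)
            rejections += out["p_empirical"] < 0.05
        assert rejections <= 4  # ~binomial(20, 0.05) upper tail

    def test_strong_bias_is_detected_by_both_tests(self):
        rng = np.random.default_rng(11)
        nr = rng.beta(4, 4, 500)
        p_lose = 1 / (1 + np.exp(-6.0 * (nr - 0.5)))
        lost = rng.random(500) < p_lose
        rec = _records(nr, lost)
        res = bootstrap_bias(rec, seed=0)
        assert ks_bias_test(res).p < 1e-6
        out = calibrated_bias_test(rec, n_null=199, seed=0)
        assert out["p_empirical"] < 0.01
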