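"""GIE calling rules, prevalence counting, cohort comparison and mutual exclusivity."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from giescan import (
    GeneDef, HLAGeneState, annotate_cohort, call_amplification, call_inactivation,
    call_loh_hla, compare_cohorts, mutual_exclusivity, prevalence, qc_filter,
)

B2M = GeneDef("B2M", "chr15", 45_003_675, 45_011_075, 2, "loss", 360)
JAK1 = GeneDef("JAK1", "chr1", 65_298_912, 65_432_187, 3, "loss", 3399)
CALR = GeneDef("CALR", "chr19", 13_049_413, 13_055_304, 2, "loss", 1254)
CD274 = GeneDef("CD274", "chr9", 5_450_503, 5_470_567, 4, "gain", 873)
SETDB1 = GeneDef("SETDB1", "chr1", 150_898_814, 150_937_220, 6, "gain", 3867)


def _muts(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "consequence", "clonal", "biallelic"]
    )


def _state(**kw):
    base = dict(sample_id="S", gene="HLA-A", allele1="A*01:01", allele2="A*02:01",
                cn1=1.0, cn2=1.0, neo1=10, neo2=10, minor_ploidy=1.0, major_ploidy=1.0)
    base.update(kw)
    return HLAGeneState(**base)


class TestQCFilter:
    def test_boundaries_and_reasons(self):
        samples = pd.DataFrame({
            "sample_id": ["a", "b", "c", "d"],
            "purity": [0.19, 0.5, 0.2, 0.1],
            "tmb": [100, 49, 50, 10],
        })
        kept, excl = qc_filter(samples)
        assert kept == ["c"]
        reasons = dict(zip(excl["sample_id"], excl["reason"]))
        assert reasons == {"a": "purity", "b": "TMB", "d": "purity,TMB"}

    def test_missing_field_names_sample(self):
        samples = pd.DataFrame(
            {"sample_id": ["x"], "purity": [np.nan], "tmb": [100]}
        )
        with pytest.raises(ValueError, match="x"):
            qc_filter(samples)


class TestCallLOH:
    @pytest.mark.parametrize(
        "minor,major,called",
        [(0.1, 1.2, True),   # within thresholds
         (0.3, 0.8, False),  # minor at boundary: strict inequality
         (0.25, 0.65, False),  # major fails: both conditions required
         (0.29, 0.71, True)],
    )
    def test_thresholds(self, minor, major, called):
        ev = call_loh_hla(_state(cn1=minor, cn2=major,
                                 minor_ploidy=minor, major_ploidy=major))
        assert (ev is not None) == called
        if called:
            assert ev.event_class == "LOH_HLA" and ev.subclass == ""

    def test_homozygous_deletion_subflag(self):
        ev = call_loh_hla(_state(cn1=0.2, cn2=0.3, minor_ploidy=0.2, major_ploidy=0.3))
        assert ev is not None and ev.subclass == "homozygous_deletion"

    def test_negative_ploidy_error(self):
        with pytest.raises(ValueError):
            call_loh_hla(_state(cn1=-0.1, minor_ploidy=-0.1))


class TestCallInactivation:
    def test_monoallelic_clonal_lof(self):
        ev = call_inactivation(
            B2M, _muts([("s", "B2M", "stop_gained", True, False)]), min_cn=2.0
        )
        assert ev is not None and ev.event_class == "inactivating_mutation"
        assert not ev.biallelic

    def test_missense_needs_biallelic(self):
        none = call_inactivation(
            JAK1, _muts([("s", "JAK1", "missense_variant", True, False)]), 2.0
        )
        assert none is None
        ev = call_inactivation(
            JAK1, _muts([("s", "JAK1", "missense_variant", True, True)]), 2.0
        )
        assert ev is not None and ev.biallelic

    def test_subclonal_lof_does_not_call(self):
        assert call_inactivation(
            B2M, _muts([("s", "B2M", "stop_gained", False, False)]), 2.0
        ) is None

    def test_homozygous_deletion_without_mutations(self):
        ev = call_inactivation(CALR, _muts([]), min_cn=0.4)
        assert ev is not None and ev.event_class == "HD"

    def test_unknown_consequence_lists_vocabulary(self):
        with pytest.raises(ValueError, match="frameshift_variant"):
            call_inactivation(
                B2M, _muts([("s", "B2M", "weird_consequence", True, False)]), 2.0
            )


class TestCallAmplification:
    @pytest.mark.parametrize(
        "min_cn,ploidy,called",
        [(7.0, 2.0, True), (6.0, 2.0, False), (3.2, 1.0, True)],
    )
    def test_three_times_ploidy_strict(self, min_cn, ploidy, called):
        ev = call_amplification(CD274, min_cn, ploidy)
        assert (ev is not None) == called

    def test_non_positive_ploidy_error(self):
        with pytest.raises(ValueError):
            call_amplification(SETDB1, 10.0, 0.0)


class TestAnnotateCohort:
    def test_fixture_is_reproduced_exactly(self, fixture_cohort, registry, hg19):
        f = fixture_cohort
        events = annotate_cohort(
            f["samples"], f["segments"], f["mutations"], f["hla"], registry, hg19
        )
        key = ["sample_id", "pathway", "gene"]
        got = events.sort_values(key).reset_index(drop=True)
        want = f["expected_events"].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_row_order_invariance(self, fixture_cohort, registry, hg19):
        f = fixture_cohort
        rng = np.random.default_rng(1)
        shuffled = {
            name: f[name].sample(frac=1.0, random_state=7).reset_index(drop=True)
            for name in ("segments", "mutations", "hla")
        }
        events = annotate_cohort(
            f["samples"], shuffled["segments"], shuffled["mutations"],
            shuffled["hla"], registry, hg19
        )
        key = ["sample_id", "pathway", "gene"]
        got = events.sort_values(key).reset_index(drop=True)
        want = f["expected_events"].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_sample_without_alterations_has_no_events(self, fixture_cohort, registry,
                                                      hg19):
        f = fixture_cohort
        events = annotate_cohort(
            f["samples"], f["segments"], f["mutations"], f["hla"], registry, hg19
        )
        assert "S09" not in set(events["sample_id"])


class TestPrevalence:
    def _samples(self, n):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "cohort": "metastatic", "cancer_type": "X",
        })

    def _events(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "pathway", "gene", "event_class",
                           "focality", "biallelic", "subclass"]
        )

    def test_counting_with_multiple_events_per_sample(self):
        events = self._events([
            ("s0", 1, "HLA-A", "LOH_HLA", "focal", False, ""),
            ("s0", 1, "HLA-B", "LOH_HLA", "focal", False, ""),
            ("s1", 2, "B2M", "HD", "not_applicable", False, ""),
        ])
        prev = prevalence(events, self._samples(3))
        by_pw = prev.set_index("pathway")["proportion"]
        assert by_pw["1"] == pytest.approx(1 / 3)
        assert by_pw["2"] == pytest.approx(1 / 3)
        assert by_pw["any"] == pytest.approx(2 / 3)

    def test_no_events_and_all_escaped(self):
        prev0 = prevalence(self._events([]), self._samples(4))
        assert (prev0["proportion"] == 0).all()
        events = self._events(
            [(f"s{i}", 1, "HLA-A", "LOH_HLA", "focal", False, "") for i in range(4)]
        )
        prev1 = prevalence(events, self._samples(4))
        assert prev1.set_index("pathway")["proportion"]["any"] == 1.0

    def test_union_conservation(self):
        events = self._events([
            ("s0", 1, "HLA-A", "LOH_HLA", "focal", False, ""),
            ("s0", 3, "JAK1", "inactivating_mutation", "not_applicable", False, ""),
            ("s2", 5, "CD58", "inactivating_mutation", "not_applicable", False, ""),
        ])
        prev = prevalence(events, self._samples(5))
        union = len(set(events["sample_id"]))
        assert prev.set_index("pathway")["numerator"]["any"] == union

    def test_orphan_event_error(self):
        events = self._events([("ghost", 1, "HLA-A", "LOH_HLA", "focal", False, "")])
        with pytest.raises(ValueError, match="ghost"):
            prevalence(events, self._samples(2))


class TestCompareCohorts:
    def _cohorts(self, esc_a, n_a, esc_b, n_b):
        ids_a = [f"a{i}" for i in range(n_a)]
        ids_b = [f"b{i}" for i in range(n_b)]
        samples = pd.DataFrame({
            "sample_id": ids_a + ids_b,
            "cohort": ["met"] * n_a + ["pri"] * n_b,
            "cancer_type": "X",
        })
        rows = [(s, 1, "HLA-A", "LOH_HLA", "focal", False, "")
                for s in ids_a[:esc_a] + ids_b[:esc_b]]
        events = pd.DataFrame(
            rows, columns=["sample_id", "pathway", "gene", "event_class",
                           "focality", "biallelic", "subclass"]
        )
        return events, samples

    def test_odds_ratio_cross_product(self):
        events, samples = self._cohorts(10, 50, 2, 50)
        out, _ = compare_cohorts(events, samples, "met", "pri")
        row = out[out["pathway"] == "1"].iloc[0]
        assert row["odds_ratio"] == pytest.approx((10 * 48) / (40 * 2))

    def test_identical_proportions_are_null(self):
        events, samples = self._cohorts(5, 20, 5, 20)
        out, _ = compare_cohorts(events, samples, "met", "pri")
        row = out[out["pathway"] == "1"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        events, samples = self._cohorts(10, 50, 2, 50)
        out, _ = compare_cohorts(events, samples, "met", "pri")
        p_impl = out[out["pathway"] == "1"]["p"].iloc[0]
        # brute-force enumeration over all tables with the observed margins
        a, n1, c, n2 = 10, 50, 2, 50
        k = a + c
        pmf = [stats.hypergeom.pmf(x, n1 + n2, k, n1) for x in range(k + 1)]
        p_obs = pmf[a]
        p_oracle = sum(p for p in pmf if p <= p_obs * (1 + 1e-12))
        assert p_impl == pytest.approx(p_oracle, rel=1e-9)


class TestMutualExclusivity:
    def _build(self, n, loh_ids, other_ids):
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "cohort": "met", "cancer_type": "X",
        })
        rows = [(f"s{i}", 1, "HLA-A", "LOH_HLA", "focal", False, "") for i in loh_ids]
        rows += [(f"s{i}", 2, "B2M", "HD", "not_applicable", False, "")
                 for i in other_ids]
        events = pd.DataFrame(
            rows, columns=["sample_id", "pathway", "gene", "event_class",
                           "focality", "biallelic", "subclass"]
        )
        return events, samples

    def test_perfect_cooccurrence_gives_p_near_one(self):
        events, samples = self._build(10, range(10), range(10))
        res = mutual_exclusivity(events, samples, "X", n_rand=2000, seed=0)
        assert res["empirical_p"] > 0.99

    def test_zero_frequency_group_degenerates_to_one(self):
        events, samples = self._build(10, range(5), [])
        res = mutual_exclusivity(events, samples, "X", n_rand=500, seed=0)
        assert res["empirical_p"] == 1.0

    def test_empirical_p_matches_monte_carlo_oracle(self):
        # 20 samples, each group at frequency 0.5, zero observed co-occurrence
        events, samples = self._build(20, range(10), range(10, 20))
        res = mutual_exclusivity(events, samples, "X", n_rand=20_000, seed=1)
        # independent oracle: binomial model of co-occurrence counts
        rng = np.random.default_rng(99)
        co = rng.binomial(20, 0.25, size=20_000)
        p_oracle = (1 + (co <= 0).sum()) / (1 + 20_000)
        se = np.sqrt(p_oracle * (1 - p_oracle) / 20_000)
        assert abs(res["empirical_p"] - p_oracle) < 3 * se + 2 / 20_000

    def test_absent_cancer_type_error(self):
        events, samples = self._build(5, range(2), range(2))
        with pytest.raises(ValueError, match="Y"):
            mutual_exclusivity(events, samples, "Y")

    def test_fisher_left_sided_direction(self):
        # exclusive pattern: left-sided p should be small
        events, samples = self._build(40, range(20), range(20, 40))
        res = mutual_exclusivity(events, samples, "X", n_rand=100, seed=0)
        assert res["fisher_left_p"] < 0.01
        assert res["empirical_p"] < 0.05
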