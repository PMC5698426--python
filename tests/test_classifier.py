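"""Hard-filter fidelity, the trained decision rule, and cohort classification."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_frame
from gatkcan.classify import (
    classify_cohort,
    classify_variant,
    exclude_known_sites,
    hard_filter_indel,
    hard_filter_snv,
)
from gatkcan.estimators import HardFilterClassifier, ThresholdRuleClassifier
from gatkcan.stats import DerivedStats
from gatkcan.types import (
    AnnotationVector,
    Label,
    SiteCatalog,
    StrandCounts,
    ThresholdSet,
    VariantCall,
    VariantClass,
)

PASSING_SNV = dict(qd=5.0, fs=10.0, mq=60.0, mq_rank_sum=0.0, read_pos_rank_sum=0.0)

ROW1_SNV = ThresholdSet(
    scope=VariantClass.SNV, alpha=0.5, dnm_min=991.1, fs_max=46.1,
    qd_min=0.11, mw_p_min=0.010, mq_min=50.0, mq_rank_sum_min=-7.85,
)


class TestHardFilterSnv:
    @pytest.mark.parametrize(
        "override,expect_artifact,expect_failed",
        [
            ({}, False, set()),
            ({"qd": 1.9}, True, {"QD"}),
            ({"qd": 2.0}, False, set()),  # boundary passes (strict <)
            ({"fs": 60.0}, False, set()),
            ({"fs": 60.1}, True, {"FS"}),
            ({"mq": 39.9}, True, {"MQ"}),
            ({"mq": 40.0}, False, set()),
            ({"mq_rank_sum": -12.5}, False, set()),
            ({"mq_rank_sum": -12.6}, True, {"MQRankSum"}),
            ({"read_pos_rank_sum": -8.0}, False, set()),
            ({"read_pos_rank_sum": -8.1}, True, {"ReadPosRankSum"}),
            ({"qd": 1.0, "fs": 100.0}, True, {"QD", "FS"}),
        ],
    )
    def test_boundary_rules(self, override, expect_artifact, expect_failed):
        ann = AnnotationVector(**{**PASSING_SNV, **override})
        pred = hard_filter_snv(ann)
        assert (pred.label is Label.ARTIFACT) == expect_artifact
        assert set(pred.failed_statistics) == expect_failed

    def test_missing_statistics_pass(self):
        pred = hard_filter_snv(AnnotationVector())
        assert pred.label is Label.TRUE_MUTATION


class TestHardFilterIndel:
    @pytest.mark.parametrize(
        "ann,expect_artifact",
        [
            (dict(qd=3.0, fs=60.5), False),  # indel rule ignores MQ cutoffs and FS<=200
            (dict(fs=201.0), True),
            (dict(fs=200.0), False),
            (dict(read_pos_rank_sum=-20.1), True),
            (dict(read_pos_rank_sum=-20.0), False),
        ],
    )
    def test_rules(self, ann, expect_artifact):
        pred = hard_filter_indel(AnnotationVector(**ann))
        assert (pred.label is Label.ARTIFACT) == expect_artifact

    def test_all_three_violated(self):
        pred = hard_filter_indel(
            AnnotationVector(qd=1.0, fs=250.0, read_pos_rank_sum=-25.0)
        )
        assert pred.failed_statistics == {"QD", "FS", "ReadPosRankSum"}


class TestExcludeKnownSites:
    def _calls(self):
        return [
            VariantCall("T1", "chr1", p, "A", "G", 10.0) for p in (10, 20, 30, 40, 50)
        ]

    def test_matching_calls_dropped_in_order(self):
        snp = SiteCatalog([("chr1", 20, "A", "G", None), ("chr1", 50, "A", "G", None)])
        kept, dropped = exclude_known_sites(self._calls(), snp)
        assert dropped == 2
        assert [c.pos for c in kept] == [10, 30, 40]

    def test_empty_lists_identity(self):
        calls = self._calls()
        kept, dropped = exclude_known_sites(calls)
        assert kept == calls and dropped == 0

    def test_allele_mismatch_not_dropped(self):
        snp = SiteCatalog([("chr1", 20, "A", "T", None)])
        kept, dropped = exclude_known_sites(self._calls(), snp)
        assert dropped == 0 and len(kept) == 5


class TestClassifyVariant:
    def _call(self, **ann):
        return VariantCall("T1", "chr1", 100, "A", "G", 50.0, AnnotationVector(**ann))

    def test_dnm_zero_shortcut_overrides_everything(self):
        v = self._call(qd=0.01, fs=300.0, mq=1.0, mq_rank_sum=-19.0)
        pred = classify_variant(v, DerivedStats(dnm=0.0, mw_p=0.0001), ROW1_SNV)
        assert pred.label is Label.TRUE_MUTATION
        assert pred.shortcut_used

    def test_small_dnm_fails_band(self):
        v = self._call(qd=5.0, fs=10.0, mq=60.0, mq_rank_sum=0.0)
        pred = classify_variant(v, DerivedStats(dnm=500.0, mw_p=0.9), ROW1_SNV)
        assert pred.label is Label.ARTIFACT
        assert pred.failed_statistics == {"dNM"}

    def test_all_statistics_passing(self):
        # dNM=5000>991.1, FS=1<46.1, QD=10>0.11, MQ=60>50, MQRankSum=0>-7.85, p=0.9>0.01
        v = self._call(qd=10.0, fs=1.0, mq=60.0, mq_rank_sum=0.0)
        pred = classify_variant(v, DerivedStats(dnm=5000.0, mw_p=0.9), ROW1_SNV)
        assert pred.label is Label.TRUE_MUTATION
        assert not pred.failed_statistics

    def test_read_pos_rank_sum_never_consulted(self):
        v = self._call(qd=10.0, fs=1.0, mq=60.0, mq_rank_sum=0.0, read_pos_rank_sum=-50.0)
        pred = classify_variant(v, DerivedStats(dnm=5000.0, mw_p=0.9), ROW1_SNV)
        assert pred.label is Label.TRUE_MUTATION

    def test_scope_mismatch_rejected(self):
        indel = VariantCall("T1", "chr1", 100, "A", "AT", 50.0, AnnotationVector())
        with pytest.raises(ValueError, match="scope"):
            classify_variant(indel, DerivedStats(dnm=5000.0, mw_p=None), ROW1_SNV)

    def test_missing_statistics_pass_cutoffs(self):
        v = self._call()
        pred = classify_variant(v, DerivedStats(dnm=math.inf, mw_p=None), ROW1_SNV)
        assert pred.label is Label.TRUE_MUTATION


class TestRuleProperties:
    def test_monotone_in_each_cutoff(self):
        """Relaxing any single cutoff never flips TRUE_MUTATION to ARTIFACT."""
        rng = np.random.default_rng(17)
        X = random_feature_frame(rng, 400)
        base = dict(dnm_min=800.0, fs_max=50.0, qd_min=1.5, mw_p_min=0.05,
                    mq_min=45.0, mq_rank_sum_min=-10.0)
        rule = ThresholdRuleClassifier(scope="snv", **base).fit()
        pred0 = rule.predict(X)
        relaxations = dict(dnm_min=400.0, fs_max=80.0, qd_min=0.5, mw_p_min=0.01,
                           mq_min=30.0, mq_rank_sum_min=-15.0)
        for name, relaxed in relaxations.items():
            relaxed_rule = ThresholdRuleClassifier(scope="snv", **{**base, name: relaxed}).fit()
            pred1 = relaxed_rule.predict(X)
            assert np.all(pred1 >= pred0), f"relaxing {name} flipped a passing call"

    def test_limit_equivalence_with_hard_filter(self):
        """dnm_min→0, mw_p_min→0, GATK cutoffs ⇒ hard filter minus ReadPosRankSum."""
        rng = np.random.default_rng(23)
        X = random_feature_frame(rng, 2000)
        rule = ThresholdRuleClassifier(
            scope="snv", dnm_min=0.0, mw_p_min=0.0,
            qd_min=2.0, fs_max=60.0, mq_min=40.0, mq_rank_sum_min=-12.5,
        ).fit()
        got = rule.predict(X)
        with np.errstate(invalid="ignore"):
            artifact = (
                (X["qd"].to_numpy() < 2.0)
                | (X["fs"].to_numpy() > 60.0)
                | (X["mq"].to_numpy() < 40.0)
                | (X["mq_rank_sum"].to_numpy() < -12.5)
            )
        assert np.array_equal(got, (~artifact).astype(int))

    def test_shortcut_dominates_for_any_thresholds(self):
        rng = np.random.default_rng(5)
        X = random_feature_frame(rng, 50)
        X["dnm"] = 0.0
        X["qd"] = 0.0
        X["fs"] = 500.0
        for _ in range(10):
            rule = ThresholdRuleClassifier(
                scope="snv",
                dnm_min=float(rng.uniform(1, 1e4)), fs_max=float(rng.uniform(0, 300)),
                qd_min=float(rng.uniform(0, 4)), mw_p_min=float(rng.uniform(0, 0.3)),
                mq_min=float(rng.uniform(0, 70)), mq_rank_sum_min=float(rng.uniform(-20, 10)),
            ).fit()
            assert np.all(rule.predict(X) == 1)


class TestClassifyCohort:
    def _cohort(self):
        catalog = SiteCatalog([("chr1", 100, "A", "G", None)])
        calls = [
            VariantCall("T1", "chr1", 100, "A", "G", 50.0, AnnotationVector(qd=0.01)),
            VariantCall("T2", "chr1", 5000, "C", "T", 50.0,
                        AnnotationVector(qd=10.0, fs=1.0, mq=60.0, mq_rank_sum=0.0)),
            VariantCall("T3", "chr1", 400, "G", "A", 50.0,
                        AnnotationVector(qd=10.0, fs=1.0, mq=60.0, mq_rank_sum=0.0)),
        ]
        return calls, catalog

    def test_catalog_match_predicted_true(self):
        calls, catalog = self._cohort()
        preds, tally, dropped = classify_cohort(
            calls[:1], catalog, thresholds_snv=ROW1_SNV
        )
        assert preds[calls[0].key].label is Label.TRUE_MUTATION
        assert dropped == 0

    def test_deterministic_and_tally(self):
        calls, catalog = self._cohort()
        out1 = classify_cohort(calls, catalog, thresholds_snv=ROW1_SNV)
        out2 = classify_cohort(calls, catalog, thresholds_snv=ROW1_SNV)
        assert out1[0] == out2[0]
        # T3 sits 300 bp from the catalog site: inside the dNM band
        assert out1[0][calls[2].key].label is Label.ARTIFACT
        assert out1[1]["dNM"] == 1

    def test_snp_list_excluded_before_classification(self):
        calls, catalog = self._cohort()
        snp = SiteCatalog([("chr1", 5000, "C", "T", None)])
        preds, _, dropped = classify_cohort(calls, catalog, [snp], thresholds_snv=ROW1_SNV)
        assert dropped == 1
        assert calls[1].key not in preds
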