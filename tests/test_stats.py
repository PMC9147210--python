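"""Validation statistics: confusion metrics, truth-set comparison,
replicate concordance, pooled t-test, clinical sensitivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from panelval.formatting import format_percent, round_percent
from panelval.intervals import TargetInterval
from panelval.simulate import make_replicates, make_truth_pair
from panelval.stats import (
    ConcordanceReport,
    ConfusionCounts,
    Exclusion,
    category_concordance,
    clinical_sensitivity,
    compare_callsets,
    compute_metrics,
    metrics_table,
    pooled_t_test,
    replicate_concordance,
)
from panelval.variants import GenotypeCall


class TestComputeMetrics:
    def test_published_snv_column(self):
        """A validation column with TP 10164 / TN 366657 / FP 53 /
        FN 253 yields 99.92 / 97.57 / 99.99 / 99.48 / 99.93."""
        rep = compute_metrics(ConfusionCounts(tp=10164, tn=366657, fp=53, fn=253))
        assert rep.formatted() == {
            "Accuracy": "99.92%",
            "Sensitivity": "97.57%",
            "Specificity": "99.99%",
            "Positive predictive value": "99.48%",
            "Negative predictive value": "99.93%",
        }

    def test_published_indel_column(self):
        rep = compute_metrics(ConfusionCounts(tp=689, tn=7073, fp=193, fn=235))
        assert rep.formatted() == {
            "Accuracy": "94.77%",
            "Sensitivity": "74.57%",
            "Specificity": "97.34%",
            "Positive predictive value": "78.12%",
            "Negative predictive value": "96.78%",
        }

    def test_perfect_counts(self):
        rep = compute_metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert all(v == "100.00%" for v in rep.formatted().values())

    def test_zero_denominator_is_na(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert rep.sensitivity is None and rep.ppv is None
        assert rep.formatted()["Sensitivity"] == "NA"

    def test_imperfect_rate_never_displays_as_100(self):
        """Display convention: a rate with any error never rounds up to
        100.00% (366657 TN / 10 FP shows 99.99%, not 100.00%)."""
        rep = compute_metrics(ConfusionCounts(tp=10164, tn=366657, fp=10, fn=54))
        assert rep.formatted()["Specificity"] == "99.99%"
        assert rep.specificity < 1

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 10_000),
        tn=st.integers(0, 10_000),
        fp=st.integers(0, 10_000),
        fn=st.integers(0, 10_000),
    )
    def test_accuracy_bounded_by_sens_and_spec(self, tp, tn, fp, fn):
        """Accuracy is a weighted mean of sensitivity and specificity,
        so it lies between them; swapping (TP<->TN, FP<->FN) swaps
        sensitivity<->specificity and PPV<->NPV."""
        rep = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        if rep.sensitivity is not None and rep.specificity is not None:
            lo, hi = sorted([rep.sensitivity, rep.specificity])
            assert lo - 1e-12 <= rep.accuracy <= hi + 1e-12
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert v is None or 0 <= v <= 1
        swapped = compute_metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert swapped.sensitivity == rep.specificity
        assert swapped.specificity == rep.sensitivity
        assert swapped.ppv == rep.npv
        assert swapped.npv == rep.ppv


def _snv(pos, alt="G", dosage=1, chrom="chrT1"):
    return GenotypeCall(chrom, pos, "A", alt, dosage)


class TestCompareCallsets:
    CONFIDENT = [TargetInterval("chrT1", 0, 1000)]

    def test_identical_callsets(self):
        calls = [_snv(10), _snv(20), _snv(30)]
        counts = compare_callsets(calls, calls, self.CONFIDENT)
        c = counts[("snv", "all")]
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)
        assert c.tn == 997

    def test_planted_fixture_counts(self):
        """Manifest-driven fixture: 100 truth SNVs over 1000 bases with
        5 planted misses and 3 planted spurious calls must come back as
        exactly (TP 95, TN 897, FP 3, FN 5)."""
        pair = make_truth_pair(
            n_targeted_bases=1000, n_snv=100, n_indel=0,
            fp_rate=0.03, fn_rate=0.05, seed=42,
        )
        counts = compare_callsets(pair.truth, pair.observed, pair.confident)
        c = counts[("snv", "all")]
        want = pair.manifest["expected_counts"]["snv"]
        assert (c.tp, c.tn, c.fp, c.fn) == (95, 897, 3, 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (
            want["tp"], want["tn"], want["fp"], want["fn"],
        )

    def test_call_outside_confident_regions_ignored(self):
        truth = [_snv(10)]
        observed = [_snv(10), _snv(5000)]  # second lies outside the mask
        counts = compare_callsets(truth, observed, self.CONFIDENT)
        c = counts[("snv", "all")]
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_reportable_stratum_masks(self):
        truth = [_snv(10), _snv(600)]
        observed = [_snv(10)]
        reportable = [TargetInterval("chrT1", 0, 500)]
        counts = compare_callsets(truth, observed, self.CONFIDENT, reportable)
        allc = counts[("snv", "all")]
        rep = counts[("snv", "reportable")]
        assert (allc.tp, allc.fn) == (1, 1)
        assert (rep.tp, rep.fn) == (1, 0)  # the miss at 600 is outside reportable
        assert rep.tn == 499

    def test_unnormalized_input_rejected(self):
        bad = [GenotypeCall("chrT1", 10, "ATT", "GTT", 1)]
        with pytest.raises(ValueError, match="unnormalized"):
            compare_callsets(bad, [], self.CONFIDENT)

    def test_truth_conservation(self):
        """TP + FN equals the number of truth variants in the mask."""
        pair = make_truth_pair(
            n_targeted_bases=2000, n_snv=80, n_indel=40,
            fp_rate=0.1, fn_rate=0.1, seed=7,
        )
        counts = compare_callsets(pair.truth, pair.observed, pair.confident)
        for vclass in ("snv", "indel"):
            c = counts[(vclass, "all")]
            n_truth = len(pair.manifest["planted"][f"truth_{vclass}"])
            assert c.tp + c.fn == n_truth

    def test_metrics_table_shape(self):
        pair = make_truth_pair(n_targeted_bases=1000, n_snv=50, n_indel=10, seed=3)
        counts = compare_callsets(pair.truth, pair.observed, pair.confident)
        table = metrics_table(counts)
        assert list(table.index) == [
            "True positives", "True negatives", "False positives",
            "False negatives", "Accuracy", "Sensitivity", "Specificity",
            "Positive predictive value", "Negative predictive value",
        ]
        assert set(table.columns) == {"all:snv", "all:indel"}


class TestReplicateConcordance:
    def test_published_inter_run_counts(self):
        """1317 concordant / 52 discordant with replicate sizes
        1348/1339/1339 -> 96.20%."""
        report = ConcordanceReport(1317, 52, (1348, 1339, 1339))
        assert report.concordance_pct == 96.20

    def test_identical_replicates(self):
        calls = [_snv(10), _snv(20)]
        report = replicate_concordance([calls, list(calls), list(calls)])
        assert report.discordant == 0
        assert report.concordance_pct == 100.00

    def test_private_calls_are_discordant(self):
        """90 shared calls plus 10 private to one replicate: union 100,
        concordant 90 -> 90.00%."""
        shared = [_snv(10 * i) for i in range(1, 91)]
        private = [_snv(10 * i) for i in range(91, 101)]
        report = replicate_concordance([shared + private, shared, shared])
        assert (report.concordant, report.discordant) == (90, 10)
        assert report.concordance_pct == 90.00
        assert report.per_replicate_variant_counts == (100, 90, 90)

    def test_dosage_disagreement_is_discordant(self):
        a = [_snv(10, dosage=1)]
        b = [_snv(10, dosage=2)]
        report = replicate_concordance([a, b, a])
        assert (report.concordant, report.discordant) == (0, 1)

    def test_order_invariance(self):
        pair = make_truth_pair(n_targeted_bases=1000, n_snv=60, n_indel=0, seed=5)
        reps = make_replicates(pair.truth, 3, 12, seed=6).replicates
        base = replicate_concordance(reps)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            again = replicate_concordance([reps[i] for i in perm])
            assert (again.concordant, again.discordant) == (
                base.concordant, base.discordant,
            )

    def test_planted_discordances_recovered(self):
        pair = make_truth_pair(n_targeted_bases=1200, n_snv=100, n_indel=0, seed=8)
        reps = make_replicates(pair.truth, 3, 10, seed=9)
        report = replicate_concordance(reps.replicates)
        assert report.discordant == 10
        assert report.concordance_pct == 90.00

    def test_fewer_than_two_replicates_error(self):
        with pytest.raises(ValueError, match="2 replicates"):
            replicate_concordance([[_snv(10)]])


class TestPooledTTest:
    def test_identical_groups(self):
        t = pooled_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t.t_statistic == 0.0 and t.p_value == pytest.approx(1.0)

    def test_textbook_example_against_scipy(self):
        ours = pooled_t_test([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        ref = sps.ttest_ind([0.1, 0.2, 0.3], [0.2, 0.3, 0.4], equal_var=True)
        assert ours.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        assert ours.degrees_of_freedom == 4

    def test_antisymmetry(self):
        a, b = [0.1, 0.25, 0.3, 0.4], [0.2, 0.3, 0.5]
        fwd = pooled_t_test(a, b)
        rev = pooled_t_test(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.pooled_variance == pytest.approx(rev.pooled_variance)

    def test_zero_variance_unequal_means(self):
        t = pooled_t_test([0.1, 0.1], [0.3, 0.3])
        assert math.isinf(t.t_statistic) and t.t_statistic < 0
        assert t.p_value == 0.0

    def test_zero_variance_equal_means(self):
        t = pooled_t_test([0.2, 0.2], [0.2, 0.2])
        assert t.t_statistic == 0.0 and t.p_value == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test([0.1], [0.2, 0.3])

    def test_oracle_agreement_on_random_instances(self):
        """Hand-coded pooled t agrees with scipy's equal-variance t to
        1e-10 relative tolerance on random draws."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            n1, n2 = rng.integers(2, 30, size=2)
            x1 = rng.random(n1)
            x2 = rng.random(n2)
            ours = pooled_t_test(x1, x2)
            ref = sps.ttest_ind(x1, x2, equal_var=True)
            assert ours.t_statistic == pytest.approx(float(ref.statistic), rel=1e-10)
            assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)


class TestCategoryConcordance:
    @staticmethod
    def _tests_with_p(pvals):
        return [
            pooled_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) if p >= 0.5
            else pooled_t_test([0.0, 0.0, 0.001], [0.9, 0.9, 0.901])
            for p in pvals
        ]

    def test_none_rejected(self):
        tests = self._tests_with_p([0.9] * 10)
        assert category_concordance(tests, 0.05) == 100.00

    def test_one_in_hundred_rejected(self):
        tests = self._tests_with_p([0.9] * 99 + [0.0])
        assert category_concordance(tests, 0.05) == 99.00

    def test_empty_is_na(self):
        assert category_concordance([], 0.05) is None

    def test_type_i_rate_under_null(self):
        """Both groups drawn from one distribution: non-rejection rate
        approximates 100(1 - alpha) within binomial error."""
        rng = np.random.default_rng(777)
        alpha = 0.05
        n_alleles = 400
        tests = []
        for _ in range(n_alleles):
            tests.append(pooled_t_test(rng.normal(0.3, 0.05, 8), rng.normal(0.3, 0.05, 8)))
        got = category_concordance(tests, alpha)
        se = 100 * math.sqrt(alpha * (1 - alpha) / n_alleles)
        assert abs(got - 100 * (1 - alpha)) <= 3 * se


class TestClinicalSensitivity:
    def test_cnv_tally(self):
        rep = clinical_sensitivity(34, 36)
        assert rep.sensitivity_pct == 94.44

    def test_monogenic_with_documented_exclusions(self):
        """30 expected, 29 detected; excluding one detected mosaic indel
        and one missed disputed variant leaves 28/28 = 100%."""
        rep = clinical_sensitivity(
            29, 30,
            exclusions=[
                Exclusion("NF2 c.1026_1027delAG", "mosaic state", detected=True),
                Exclusion("GALT c.130G>A", "presence disputed by Sanger and NGS",
                          detected=False),
            ],
        )
        assert (rep.detected, rep.evaluable) == (28, 28)
        assert rep.sensitivity_pct == 100.00
        assert len(rep.describe_exclusions()) == 2

    def test_no_exclusions(self):
        rep = clinical_sensitivity(10, 10)
        assert rep.sensitivity_pct == 100.00

    def test_detected_cannot_exceed_evaluable(self):
        with pytest.raises(ValueError):
            clinical_sensitivity(11, 10)


class TestFormatting:
    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.9444444, 94.44),
            (0.997382, 99.74),
            (0.95335, 95.34),  # round-half-up at the second decimal
            (1.0, 100.0),
            (0.9999973, 99.99),  # imperfect rates cap below 100
        ],
    )
    def test_round_percent(self, frac, expected):
        assert round_percent(frac) == expected

    def test_format_na(self):
        assert format_percent(None) == "NA"
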