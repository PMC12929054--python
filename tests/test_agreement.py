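"""Confusion matrices, accuracy statistics, kappa, and scale pooling."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import grassaudit as ga
from grassaudit.agreement import BINARY_CLASSES


def _records(rows):
    """rows: (site, psu, ref_code, wc_token) tuples."""
    return pd.DataFrame(
        [
            {"site_id": s, "psu": p, "cell": f"A{i % 10 + 1}", "ref_code": r, "wc": m}
            for i, (s, p, r, m) in enumerate(rows)
        ]
    )


def _binary_oracle(records, scheme):
    """Independent dictionary-count tally of the binary confusion matrix."""
    legend = scheme.legend("wc")
    tally = Counter()
    excluded = 0
    for _, row in records.iterrows():
        ref = scheme.to_binary(row["ref_code"])
        tok = row["wc"]
        if legend.harmonize(tok) == "U" or ref == "excluded":
            excluded += 1
            continue
        mp = "grassland" if legend.is_grassland_token(tok) else "non-grassland"
        tally[(mp, ref)] += 1
    return tally, excluded


class TestBuildConfusion:
    def test_all_matching_records_are_diagonal(self, scheme):
        recs = _records([("s", 0, "G1", "grassland")] * 4)
        cm = ga.build_confusion(recs, "wc", scheme, "binary")
        assert cm.count("grassland", "grassland") == 4
        assert cm.total == 4
        assert cm.n_excluded == 0

    def test_unfilled_reference_excluded(self, scheme):
        recs = _records([("s", 0, "U", "grassland")])
        cm = ga.build_confusion(recs, "wc", scheme, "binary")
        assert cm.total == 0
        assert cm.n_excluded == 1

    def test_unsure_code_binary_vs_simplified(self, scheme):
        recs = _records([("s", 0, "7", "grassland")] * 3)
        binary = ga.build_confusion(recs, "wc", scheme, "binary")
        assert binary.count("grassland", "grassland") == 3
        simplified = ga.build_confusion(recs, "wc", scheme, "simplified")
        assert simplified.total == 0
        assert simplified.n_excluded == 3

    def test_thousand_record_fixture_matches_dictionary_oracle(self, scheme, rng):
        codes = [rc.code for rc in scheme.reference_classes]
        tokens = list(scheme.legend("wc").classes)
        recs = _records(
            [
                ("s", 0, rng.choice(codes), rng.choice(tokens))
                for _ in range(1000)
            ]
        )
        cm = ga.build_confusion(recs, "wc", scheme, "binary")
        oracle, excluded = _binary_oracle(recs, scheme)
        assert cm.n_excluded == excluded
        for mp in BINARY_CLASSES:
            for ref in BINARY_CLASSES:
                assert cm.count(mp, ref) == oracle[(mp, ref)]
        assert cm.total + cm.n_excluded == 1000

    def test_full_level_is_rectangular_and_drops_unsure(self, scheme):
        recs = _records(
            [("s", 0, "G1", "grassland"), ("s", 0, "7", "grassland"),
             ("s", 0, "N1", "tree_cover")]
        )
        cm = ga.build_confusion(recs, "wc", scheme, "full")
        assert not cm.is_square
        assert cm.total == 2
        assert cm.n_excluded == 1
        assert cm.count("grassland", "G1") == 1
        assert cm.count("forest", "N1") == 1


class TestAccuracyStatistics:
    def test_printed_count_proportions(self):
        # the worked-example arithmetic behind the headline accuracies
        assert ga.accuracy_from_counts(240_266, 281_735) == pytest.approx(0.853, abs=5e-4)
        assert ga.accuracy_from_counts(70_864, 281_735) == pytest.approx(0.252, abs=5e-4)

    def test_hand_countable_two_by_two(self, scheme):
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES,
            np.array([[8, 2], [1, 9]]), 0,
        )
        assert ga.users_accuracy(cm, "grassland") == pytest.approx(0.8)
        assert ga.producers_accuracy(cm, "grassland") == pytest.approx(8 / 9)
        assert ga.overall_accuracy(cm) == pytest.approx(17 / 20)

    def test_perfect_matrix(self):
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES, np.diag([3, 7]), 0
        )
        assert ga.users_accuracy(cm, "grassland") == 1.0
        assert ga.producers_accuracy(cm, "non-grassland") == 1.0
        assert ga.overall_accuracy(cm) == 1.0
        assert ga.cohens_kappa(cm) == pytest.approx(1.0)

    def test_empty_row_or_column_flagged_not_zero(self):
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES, np.array([[0, 0], [3, 7]]), 0
        )
        assert math.isnan(ga.users_accuracy(cm, "grassland"))
        assert ga.producers_accuracy(cm, "grassland") == 0.0


class TestKappa:
    def test_independent_marginals_give_zero(self):
        # counts exactly proportional to marginal products
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES,
            np.array([[16, 24], [24, 36]]), 0,
        )
        assert ga.cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES,
            np.array([[40, 10], [10, 40]]), 0,
        )
        assert ga.cohens_kappa(cm) == pytest.approx(0.6)

    def test_degenerate_single_class(self):
        cm = ga.ConfusionMatrix(
            "binary", BINARY_CLASSES, BINARY_CLASSES, np.array([[5, 0], [0, 0]]), 0
        )
        # perfect agreement on one occupied class: p_e = 1 with p_o = 1
        assert ga.cohens_kappa(cm) == 1.0

    def test_kappa_at_most_one_and_one_iff_diagonal(self, scheme, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=(2, 2))
            if counts.sum() == 0:
                continue
            cm = ga.ConfusionMatrix("binary", BINARY_CLASSES, BINARY_CLASSES, counts, 0)
            k = ga.cohens_kappa(cm)
            if not math.isnan(k):
                assert k <= 1.0 + 1e-12
            off_diag = counts[0, 1] + counts[1, 0]
            occupied = (counts.sum(axis=1) > 0).sum()
            if k == 1.0 and occupied >= 2:
                assert off_diag == 0


class TestScalesAndPooling:
    def test_single_psu_equals_overall(self, scheme):
        recs = _records([("s", 0, "G1", "grassland"), ("s", 0, "N1", "tree_cover")])
        reports = ga.accuracy_by_scale(recs, "wc", scheme, "binary")
        psu = reports["PSU"][0]
        overall = reports["overall"][0]
        np.testing.assert_array_equal(psu.matrix.counts, overall.matrix.counts)
        assert psu.overall == overall.overall

    def test_disjoint_psus_are_additive(self, scheme):
        recs = _records(
            [("s", 0, "G1", "grassland")] * 3 + [("s", 1, "N1", "tree_cover")] * 2
        )
        reports = ga.accuracy_by_scale(recs, "wc", scheme, "binary")
        pooled = ga.pool_matrices(r.matrix for r in reports["PSU"])
        np.testing.assert_array_equal(
            pooled.counts, reports["overall"][0].matrix.counts
        )

    def test_count_conservation_on_simulated_study(self, scheme, small_study):
        recs = small_study.records
        reports = ga.accuracy_by_scale(recs, "wc", scheme, "binary")
        psu_pool = ga.pool_matrices(r.matrix for r in reports["PSU"])
        loc_pool = ga.pool_matrices(r.matrix for r in reports["location"])
        overall = reports["overall"][0].matrix
        np.testing.assert_array_equal(psu_pool.counts, overall.counts)
        np.testing.assert_array_equal(loc_pool.counts, overall.counts)
        assert psu_pool.n_excluded == overall.n_excluded == loc_pool.n_excluded
        assert overall.total + overall.n_excluded == len(recs)

    def test_binary_from_simplified_pooling(self, scheme, small_study):
        # pooling equality holds on records without the unsure code, which is
        # excluded at the simplified level but grassland at the binary level
        recs = small_study.records
        recs = recs[recs["ref_code"] != "7"]
        simp = ga.build_confusion(recs, "wc", scheme, "simplified")
        pooled = ga.binary_from_simplified(simp)
        direct = ga.build_confusion(recs, "wc", scheme, "binary")
        np.testing.assert_array_equal(pooled.counts, direct.counts)


class TestClassCorrectCounts:
    def test_all_open_grassland_perfect_product(self, scheme):
        recs = _records([("s", 0, "G1", "grassland")] * 50)
        counts = ga.class_correct_counts(recs, "wc", scheme)
        assert counts.loc["G1", "correct"] == 50
        assert counts.loc["G1", "incorrect"] == 0
        assert counts.loc["G2"].tolist() == [0, 0]  # empty class

    def test_sensitivity_fixture_binomial(self, scheme, rng):
        # product finds wooded grassland ~65% of the time
        n, p = 4000, 0.65
        tokens = np.where(rng.random(n) < p, "grassland", "tree_cover")
        recs = _records([("s", 0, "G2", t) for t in tokens])
        counts = ga.class_correct_counts(recs, "wc", scheme)
        se = math.sqrt(p * (1 - p) / n)
        assert counts.loc["G2", "correct"] / n == pytest.approx(p, abs=3 * se)


class TestEstimatedAccuraciesConvergeToSpecifiedConfusion:
    def test_simulated_product_recovers_error_rates(self, scheme, rng):
        # binary sensitivity/specificity injected at the record level must be
        # recovered by the confusion matrix within 3 binomial s.e. at n=10,000
        n = 10_000
        sens, spec_ = 0.85, 0.70
        truth = np.where(rng.random(n) < 0.7, "G1", "N1")
        is_grass = truth == "G1"
        tok = np.empty(n, dtype=object)
        tok[is_grass] = np.where(rng.random(is_grass.sum()) < sens, "grassland", "tree_cover")
        tok[~is_grass] = np.where(
            rng.random((~is_grass).sum()) < spec_, "tree_cover", "grassland"
        )
        recs = _records([("s", 0, r, m) for r, m in zip(truth, tok)])
        cm = ga.build_confusion(recs, "wc", scheme, "binary")
        n_g, n_n = is_grass.sum(), (~is_grass).sum()
        pa_g = ga.producers_accuracy(cm, "grassland")
        pa_n = ga.producers_accuracy(cm, "non-grassland")
        assert pa_g == pytest.approx(sens, abs=3 * math.sqrt(sens * (1 - sens) / n_g))
        assert pa_n == pytest.approx(spec_, abs=3 * math.sqrt(spec_ * (1 - spec_) / n_n))
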