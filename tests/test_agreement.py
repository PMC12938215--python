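"""Kappa statistics: hand-tally oracles, statsmodels cross-checks, nulls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from usgrad_audit.agreement import (
    cohen_kappa, compute_agreement_report, fleiss_kappa, interpret_kappa,
    percent_agreement,
)
from usgrad_audit.annotation import LABELS, AnnotationLabel

A, B, C, D = (lab.value for lab in LABELS)


class TestCohenKappa:
    def test_identical_sequences_give_one(self):
        seq = [A, B, A, C, D, B]
        assert cohen_kappa(seq, seq) == pytest.approx(1.0)

    def test_independence_pattern_gives_zero(self):
        a = [A, A, B, B]
        b = [A, B, A, B]
        assert cohen_kappa(a, b, categories=[A, B]) == pytest.approx(0.0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        a = [LABELS[i].value for i in rng.integers(0, 4, size=20)]
        b = [LABELS[i].value for i in rng.integers(0, 4, size=20)]
        # brute force: explicit tallying of observed and chance agreement
        n = len(a)
        p_o = sum(x == y for x, y in zip(a, b)) / n
        p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in {x.value for x in LABELS})
        expected = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, size=200)
        b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 4, size=200))
        table = np.zeros((4, 4))
        for x, y in zip(a, b):
            table[x, y] += 1
        expected = cohens_kappa(table, return_results=False)
        ours = cohen_kappa([LABELS[i].value for i in a], [LABELS[i].value for i in b])
        assert ours == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = [LABELS[i].value for i in rng.integers(0, 4, size=50)]
        b = [LABELS[i].value for i in rng.integers(0, 4, size=50)]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a = [LABELS[i].value for i in rng.integers(0, 4, size=80)]
        b = [LABELS[i].value for i in rng.integers(0, 4, size=80)]
        perm = {A: C, B: D, C: A, D: B}
        assert cohen_kappa([perm[x] for x in a], [perm[x] for x in b]) == \
            pytest.approx(cohen_kappa(a, b))

    def test_constant_raters_edge_cases(self):
        assert cohen_kappa([A, A, A], [A, A, A]) == 1.0
        assert math.isnan(cohen_kappa([A, A, A, A], [A, A, A, B],
                                      categories=[A, B])) is False  # p_e < 1 here
        # both constant on the same label but with zero-width marginals
        assert math.isnan(cohen_kappa([A] * 3, [B] * 3, categories=[A, B])) is False

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa([A, B], [A])
        with pytest.raises(ValueError, match="category"):
            cohen_kappa(["x", "y"], ["x", "y"])


class TestFleissKappa:
    def test_unanimous_items_across_categories_give_one(self):
        counts = np.array([[3, 0, 0, 0], [0, 3, 0, 0], [0, 0, 3, 0]])
        assert fleiss_kappa(counts) == pytest.approx(1.0)

    def test_six_item_table_matches_hand_computation(self):
        counts = np.array([
            [3, 0, 0, 0],
            [2, 1, 0, 0],
            [0, 2, 1, 0],
            [1, 1, 1, 0],
            [0, 0, 0, 3],
            [0, 1, 0, 2],
        ])
        # direct-formula oracle on scalars
        n_r = 3
        p_i = [(r * (r - 1)).sum() / (n_r * (n_r - 1)) for r in counts]
        p_bar = float(np.mean(p_i))
        p_j = counts.sum(axis=0) / counts.sum()
        p_e = float((p_j ** 2).sum())
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(9)
        counts = np.zeros((300, 4), dtype=int)
        for i in range(300):
            votes = rng.integers(0, 4, size=3)
            for v in votes:
                counts[i, v] += 1
        assert fleiss_kappa(counts) == pytest.approx(sm_fleiss(counts), abs=1e-10)

    def test_uniform_random_votes_are_near_zero(self):
        rng = np.random.default_rng(123)
        n = 10_000
        counts = np.zeros((n, 4), dtype=int)
        votes = rng.integers(0, 4, size=(n, 3))
        for i in range(n):
            for v in votes[i]:
                counts[i, v] += 1
        kappa = fleiss_kappa(counts)
        # asymptotic null variance for m raters and category proportions p_j
        m, p = 3, np.full(4, 0.25)
        s2, s3 = (p ** 2).sum(), (p ** 3).sum()
        var = (2.0 / (n * m * (m - 1))
               * (s2 - (2 * m - 3) * s2 ** 2 + 2 * (m - 2) * s3) / (1 - s2) ** 2)
        assert abs(kappa) <= 3 * np.sqrt(var)

    def test_single_category_perfect_agreement_flagged_undefined(self):
        counts = np.array([[3, 0, 0, 0], [3, 0, 0, 0]])
        assert math.isnan(fleiss_kappa(counts))

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged|raters"):
            fleiss_kappa(np.array([[3, 0, 0, 0], [2, 0, 0, 0]]))


class TestInterpretKappa:
    @pytest.mark.parametrize("value,band", [
        (0.529, "moderate"),
        (0.598, "moderate"),
        (1.0, "almost perfect"),
        (0.0, "slight"),
        (0.20, "slight"),
        (0.21, "fair"),
        (0.61, "substantial"),
        (-0.2, "poor"),
    ])
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestPercentAgreement:
    def test_all_unanimous(self):
        assert percent_agreement([[A, A, A]] * 5) == 100.0

    def test_reference_counts(self):
        rows = [[A, A, A]] * 2554 + [[A, A, B]] * (3131 - 2554)
        assert percent_agreement(rows) == 81.6

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            percent_agreement([[A, None, A]])

    def test_matches_complete_share_of_distribution(self):
        from usgrad_audit.annotation import AnnotationRecord, agreement_distribution, consensus

        rng = np.random.default_rng(4)
        rows = [[LABELS[i].value for i in rng.integers(0, 3, size=3)] for _ in range(60)]
        results = [consensus([AnnotationRecord(f"i{k}", f"r{j}", AnnotationLabel(lab))
                              for j, lab in enumerate(row)])
                   for k, row in enumerate(rows)]
        dist = agreement_distribution(results)
        assert percent_agreement(rows) == dist["percentages"]["complete"]


class TestAgreementReport:
    def _annotations(self, flip, n=5000, seed=0):
        from usgrad_audit.annotation import RaterModel, simulate_rater

        rng = np.random.default_rng(seed)
        truth_dist = [0.6, 0.2, 0.1, 0.1]  # fixed truth distribution
        raters = [RaterModel(f"r{j+1}", flip) for j in range(3)]
        rows = []
        for i in range(n):
            truth = LABELS[int(rng.choice(4, p=truth_dist))]
            for r in raters:
                rows.append({"image_id": f"i{i:05d}", "rater_id": r.rater_id,
                             "label": simulate_rater(truth, r, rng).value})
        return pd.DataFrame(rows)

    def test_noiseless_raters_agree_perfectly(self):
        df = self._annotations(flip=0.0, n=200)
        report = compute_agreement_report(df)
        assert report.percent_agreement == 100.0
        assert report.fleiss == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in report.cohen.values())
        assert report.interpretations["fleiss"] == "almost perfect"

    def test_kappa_decreases_with_rater_noise(self):
        kappas = [compute_agreement_report(self._annotations(p, seed=7)).fleiss
                  for p in (0.05, 0.15, 0.30)]
        assert kappas[0] > kappas[1] > kappas[2]

    def test_report_shape_and_rounding(self):
        df = self._annotations(flip=0.2, n=300, seed=1)
        report = compute_agreement_report(df)
        d = report.to_dict()
        assert set(d["cohen"]) == {"r1-r2", "r1-r3", "r2-r3"}
        assert d["n_items"] == 300 and d["n_raters"] == 3
        assert all(-1 <= v <= 1 for v in d["cohen"].values())
        assert d["fleiss"] == round(d["fleiss"], 3)

    def test_incomplete_table_rejected(self):
        df = self._annotations(flip=0.0, n=10).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            compute_agreement_report(df)

    def test_two_raters_report_both_chance_models(self):
        df = self._annotations(flip=0.1, n=400, seed=2)
        df = df[df["rater_id"] != "r3"]
        report = compute_agreement_report(df)
        assert set(report.cohen) == {"r1-r2"}
        assert not math.isnan(report.fleiss)
        # different chance models: close but generally not identical
        assert abs(report.cohen["r1-r2"] - report.fleiss) < 0.1
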