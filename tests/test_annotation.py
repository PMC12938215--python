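"""Annotation oracle, simulated raters, and the majority-rule consensus."""

import itertools

import numpy as np
import pytest

from usgrad_audit.annotation import (
    LABELS, AnnotationLabel, AnnotationRecord, OverlapRules, RaterModel,
    adjudicate, agreement_distribution, consensus, oracle_label, simulate_rater,
)
from usgrad_audit.gradcam import ActivationRegion
from usgrad_audit.phantom import MASK_CATEGORIES, PhantomFrame


def _frame(size=70, quality=1.0, **mask_cells):
    """Frame whose masks fully cover the given grid cells (size 70 -> 10 px cells)."""
    masks = {k: np.zeros((size, size), dtype=bool) for k in MASK_CATEGORIES}
    cell = size // 7
    for category, cells in mask_cells.items():
        for (r, c) in cells:
            masks[category][r * cell:(r + 1) * cell, c * cell:(c + 1) * cell] = True
    return PhantomFrame(image=np.zeros((size, size)), masks=masks,
                        station="4L", patient_id="p0", quality=quality)


def _region(*cells):
    return ActivationRegion(cells=frozenset(cells), max_cell=min(cells) if cells else None)


class TestOracleLabel:
    def test_vessel_overlap_wins(self):
        frame = _frame(vessel=[(2, 2)], artifact=[(2, 2)])
        assert oracle_label(_region((2, 2)), frame) == AnnotationLabel.LYMPH_NODE_VESSEL

    def test_low_quality_overrides_overlap(self):
        frame = _frame(quality=0.0, lymph_node=[(2, 2)])
        assert oracle_label(_region((2, 2)), frame) == AnnotationLabel.NOT_INTERPRETABLE

    def test_background_region_is_other_structure(self):
        frame = _frame()
        assert oracle_label(_region((5, 5)), frame) == AnnotationLabel.OTHER_STRUCTURE

    def test_artifact_overlap_without_anatomy(self):
        frame = _frame(artifact=[(1, 4)])
        assert oracle_label(_region((1, 4)), frame) == AnnotationLabel.ARTIFACT

    def test_empty_region_is_not_interpretable(self):
        assert oracle_label(_region(), _frame()) == AnnotationLabel.NOT_INTERPRETABLE

    def test_overlap_fraction_threshold_respected(self):
        # mask covers ~10% of the cell: below the default 25% rule
        frame = _frame()
        frame.masks["lymph_node"][20:23, 20:24] = True
        assert oracle_label(_region((2, 2)), frame) == AnnotationLabel.OTHER_STRUCTURE
        relaxed = OverlapRules(min_cell_fraction=0.01)
        assert oracle_label(_region((2, 2)), frame, relaxed) == AnnotationLabel.LYMPH_NODE_VESSEL

    def test_determinism(self):
        frame = _frame(vessel=[(3, 3)], artifact=[(0, 0)])
        region = _region((3, 3), (0, 0))
        labels = {oracle_label(region, frame) for _ in range(10)}
        assert labels == {AnnotationLabel.LYMPH_NODE_VESSEL}


class TestSimulateRater:
    def test_zero_flip_probability_returns_truth(self):
        rng = np.random.default_rng(0)
        rater = RaterModel("r1", flip_probability=0.0)
        for truth in LABELS:
            assert simulate_rater(truth, rater, rng) == truth

    def test_certain_flip_with_uniform_kernel_never_returns_truth(self):
        rng = np.random.default_rng(0)
        rater = RaterModel("r1", flip_probability=1.0)
        for truth in LABELS:
            for _ in range(50):
                assert simulate_rater(truth, rater, rng) != truth

    def test_complete_agreement_rate_matches_closed_form(self):
        # three independent raters with flip probability p and uniform
        # confusion: P(all three agree) = (1-p)^3 + 3*(1-p)*(p/3)^2*0 ... the
        # exact value is sum_j P(all output j), computed from the kernel.
        p = 0.2
        rater = RaterModel("r", flip_probability=p)
        truth = AnnotationLabel.ARTIFACT
        t = LABELS.index(truth)
        out_probs = np.full(len(LABELS), 0.0)
        for j in range(len(LABELS)):
            out_probs[j] = (1 - p) * (j == t) + p * rater.kernel[t, j]
        expected = float((out_probs ** 3).sum())

        rng = np.random.default_rng(99)
        n = 5000
        agree = 0
        for _ in range(n):
            labels = [simulate_rater(truth, rater, rng) for _ in range(3)]
            agree += len(set(labels)) == 1
        observed = agree / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            RaterModel("r", kernel=np.ones((4, 4)))


class TestConsensus:
    def _records(self, labels):
        return [AnnotationRecord("img1", f"r{i}", lab)
                for i, lab in enumerate(labels)]

    def test_unanimous(self):
        res = consensus(self._records([AnnotationLabel.ARTIFACT] * 3))
        assert (res.agreement_level, res.final_label) == ("complete", AnnotationLabel.ARTIFACT)

    def test_majority_label_wins(self):
        res = consensus(self._records([AnnotationLabel.ARTIFACT,
                                       AnnotationLabel.ARTIFACT,
                                       AnnotationLabel.OTHER_STRUCTURE]))
        assert (res.agreement_level, res.final_label) == ("majority", AnnotationLabel.ARTIFACT)

    def test_three_way_disagreement_is_pending(self):
        res = consensus(self._records([AnnotationLabel.ARTIFACT,
                                       AnnotationLabel.OTHER_STRUCTURE,
                                       AnnotationLabel.NOT_INTERPRETABLE]))
        assert res.agreement_level == "disagreement"
        assert res.pending

    def test_all_64_label_tuples_against_brute_force(self):
        for combo in itertools.product(LABELS, repeat=3):
            res = consensus(self._records(list(combo)))
            distinct = len(set(combo))
            expected_level = {1: "complete", 2: "majority", 3: "disagreement"}[distinct]
            assert res.agreement_level == expected_level
            if distinct < 3:
                expected_label = max(set(combo), key=combo.count)
                assert res.final_label == expected_label
            else:
                assert res.final_label is None

    def test_wrong_record_count_and_duplicate_rater_rejected(self):
        with pytest.raises(ValueError, match="3 records"):
            consensus(self._records([AnnotationLabel.ARTIFACT] * 2))
        dup = [AnnotationRecord("img1", "r1", AnnotationLabel.ARTIFACT)] * 3
        with pytest.raises(ValueError, match="distinct raters"):
            consensus(dup)

    def test_adjudication_resolves_pending_items(self):
        res = consensus(self._records([AnnotationLabel.ARTIFACT,
                                       AnnotationLabel.OTHER_STRUCTURE,
                                       AnnotationLabel.NOT_INTERPRETABLE]))
        resolved, = adjudicate([res], {"img1": AnnotationLabel.ARTIFACT})
        assert resolved.final_label == AnnotationLabel.ARTIFACT
        assert resolved.agreement_level == "disagreement"
        with pytest.raises(KeyError):
            adjudicate([res], {})


class TestAgreementDistribution:
    def _results(self, n_complete, n_majority, n_disagreement):
        out = []
        for i in range(n_complete):
            out.append(consensus([AnnotationRecord(f"c{i}", f"r{j}", AnnotationLabel.ARTIFACT)
                                  for j in range(3)]))
        for i in range(n_majority):
            labs = [AnnotationLabel.ARTIFACT, AnnotationLabel.ARTIFACT,
                    AnnotationLabel.OTHER_STRUCTURE]
            out.append(consensus([AnnotationRecord(f"m{i}", f"r{j}", labs[j])
                                  for j in range(3)]))
        for i in range(n_disagreement):
            labs = [AnnotationLabel.ARTIFACT, AnnotationLabel.OTHER_STRUCTURE,
                    AnnotationLabel.NOT_INTERPRETABLE]
            out.append(consensus([AnnotationRecord(f"d{i}", f"r{j}", labs[j])
                                  for j in range(3)]))
        return out

    def test_reference_split_percentages(self):
        dist = agreement_distribution(self._results(2554, 474, 103))
        assert dist["n"] == 3131
        assert dist["percentages"] == {"complete": 81.6, "majority": 15.1,
                                       "disagreement": 3.3}

    def test_all_complete(self):
        dist = agreement_distribution(self._results(10, 0, 0))
        assert dist["percentages"] == {"complete": 100.0, "majority": 0.0,
                                       "disagreement": 0.0}

    def test_percentages_sum_to_about_100(self):
        dist = agreement_distribution(self._results(7, 5, 3))
        assert abs(sum(dist["percentages"].values()) - 100.0) <= 0.2
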