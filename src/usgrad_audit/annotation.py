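"""Four-category attention annotation, simulated raters, and consensus.

Every activation region receives one of four labels — lymph node/blood
vessel, other structure, artifact, or not interpretable. On synthetic
frames with ground-truth masks, a deterministic oracle annotator replaces
the expert: a region counts as overlapping a structure when at least a
configurable fraction (default 25%) of one of its grid-cell footprints
intersects that structure's mask, with clinically motivated precedence
lymph node/vessel > artifact > other structure. Noisy raters are simulated
by flipping the oracle label through a confusion kernel, which lets the
agreement statistics be exercised without human annotators.

Consensus over three raters follows the majority rule: a label shared by at
least two raters is final; three-way disagreement stays pending until an
adjudication table (the stand-in for a consensus meeting) resolves it.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from usgrad_audit.gradcam import GRID_SIZE, ActivationRegion
from usgrad_audit.phantom import PhantomFrame


class AnnotationLabel(str, enum.Enum):
    LYMPH_NODE_VESSEL = "lymph_node_vessel"
    OTHER_STRUCTURE = "other_structure"
    ARTIFACT = "artifact"
    NOT_INTERPRETABLE = "not_interpretable"


LABELS = tuple(AnnotationLabel)


@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    rater_id: str
    label: AnnotationLabel


@dataclass(frozen=True)
class ConsensusResult:
    image_id: str
    final_label: Optional[AnnotationLabel]   # None while pending adjudication
    agreement_level: str                     # complete | majority | disagreement

    @property
    def pending(self) -> bool:
        return self.final_label is None


@dataclass(frozen=True)
class OverlapRules:
    """Numeric proxy for the expert overlap judgement."""

    min_cell_fraction: float = 0.25   # fraction of a cell footprint inside a mask
    quality_floor: float = 0.30       # below this, frames are not interpretable


def _cell_bounds(size: int) -> np.ndarray:
    return np.round(np.linspace(0, size, GRID_SIZE + 1)).astype(int)


def _cell_overlap_fraction(mask: np.ndarray, cell: tuple[int, int]) -> float:
    h_b = _cell_bounds(mask.shape[0])
    w_b = _cell_bounds(mask.shape[1])
    r, c = cell
    patch = mask[h_b[r]:h_b[r + 1], w_b[c]:w_b[c + 1]]
    return float(patch.mean()) if patch.size else 0.0


def oracle_label(region: ActivationRegion, frame: PhantomFrame,
                 rules: OverlapRules = OverlapRules()) -> AnnotationLabel:
    """Deterministic label from ground-truth masks.

    Order of decision: low-quality frame or empty region -> not
    interpretable; overlap with the lymph-node or vessel mask -> lymph
    node/vessel; else overlap with the artifact mask -> artifact; else ->
    other structure.
    """
    if frame.quality < rules.quality_floor:
        return AnnotationLabel.NOT_INTERPRETABLE
    if region.empty:
        return AnnotationLabel.NOT_INTERPRETABLE
    anatomical = frame.masks["lymph_node"] | frame.masks["vessel"]
    for cell in sorted(region.cells):
        if _cell_overlap_fraction(anatomical, cell) >= rules.min_cell_fraction:
            return AnnotationLabel.LYMPH_NODE_VESSEL
    for cell in sorted(region.cells):
        if _cell_overlap_fraction(frame.masks["artifact"], cell) >= rules.min_cell_fraction:
            return AnnotationLabel.ARTIFACT
    return AnnotationLabel.OTHER_STRUCTURE


# ---------------------------------------------------------------------------
# simulated raters

def _default_kernel() -> np.ndarray:
    """Uniform confusion over the three non-true labels."""
    k = np.full((len(LABELS), len(LABELS)), 1.0 / (len(LABELS) - 1))
    np.fill_diagonal(k, 0.0)
    return k


@dataclass
class RaterModel:
    rater_id: str
    flip_probability: float = 0.15
    kernel: np.ndarray = field(default_factory=_default_kernel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.shape != (len(LABELS), len(LABELS)):
            raise ValueError("kernel must be 4x4")
        if not np.allclose(self.kernel.sum(axis=1), 1.0):
            raise ValueError("kernel rows must be probability vectors")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")


def simulate_rater(truth: AnnotationLabel, rater: RaterModel,
                   rng: np.random.Generator) -> AnnotationLabel:
    """Return `truth` with probability 1 - flip_probability, else draw from
    the confusion-kernel row of the true label."""
    if rng.uniform() >= rater.flip_probability:
        return truth
    row = rater.kernel[LABELS.index(truth)]
    return LABELS[int(rng.choice(len(LABELS), p=row))]


# ---------------------------------------------------------------------------
# consensus

def consensus(records: Sequence[AnnotationRecord]) -> ConsensusResult:
    """Merge exactly three raters' labels for one image.

    All equal -> complete; exactly two equal -> majority (the shared label
    wins); all distinct -> disagreement with the final label pending.
    """
    if len(records) != 3:
        raise ValueError(f"consensus requires exactly 3 records, got {len(records)}")
    image_ids = {r.image_id for r in records}
    if len(image_ids) != 1:
        raise ValueError(f"records span multiple images: {sorted(image_ids)}")
    if len({r.rater_id for r in records}) != 3:
        raise ValueError("records must come from three distinct raters")
    image_id = records[0].image_id
    counts = Counter(r.label for r in records)
    label, top = counts.most_common(1)[0]
    if top == 3:
        return ConsensusResult(image_id, label, "complete")
    if top == 2:
        return ConsensusResult(image_id, label, "majority")
    return ConsensusResult(image_id, None, "disagreement")


def adjudicate(results: Iterable[ConsensusResult],
               table: Mapping[str, AnnotationLabel]) -> list[ConsensusResult]:
    """Resolve pending items with a supplied adjudication table."""
    out = []
    for res in results:
        if res.pending:
            if res.image_id not in table:
                raise KeyError(f"no adjudication entry for pending image {res.image_id!r}")
            out.append(ConsensusResult(res.image_id, AnnotationLabel(table[res.image_id]),
                                       res.agreement_level))
        else:
            out.append(res)
    return out


def agreement_distribution(results: Sequence[ConsensusResult]) -> dict:
    """Counts and one-decimal percentages per agreement level."""
    if not results:
        raise ValueError("no consensus results supplied")
    levels = ("complete", "majority", "disagreement")
    counts = Counter(r.agreement_level for r in results)
    n = len(results)
    return {
        "n": n,
        "counts": {lv: counts.get(lv, 0) for lv in levels},
        "percentages": {lv: round(100.0 * counts.get(lv, 0) / n, 1) for lv in levels},
    }
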