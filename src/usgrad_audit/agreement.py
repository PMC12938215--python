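"""Inter-rater agreement: percent agreement, Cohen's and Fleiss' kappa.

Both kappas are chance-corrected agreement coefficients,
kappa = (p_o - p_e) / (1 - p_e), differing in the chance model: Cohen's
uses the product of the two raters' marginal label proportions, Fleiss'
uses squared pooled category proportions across all raters. They are
computed over the fixed four-category annotation space even when some
categories go unobserved (zero marginals add nothing to chance agreement,
keeping reports comparable across runs), and always from the raters'
independent pre-consensus labels. Interpretation uses the conventional
Landis-Koch bands.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from usgrad_audit.annotation import LABELS, AnnotationLabel


def _to_values(seq: Sequence) -> list[str]:
    return [AnnotationLabel(x).value for x in seq]


def cohen_kappa(a: Sequence, b: Sequence,
                categories: Sequence = LABELS) -> float:
    """Cohen's kappa between two raters over a fixed category set.

    Chance agreement is the inner product of the two raters' marginal
    proportions. When p_e == 1 (both raters constant on one category) the
    statistic is undefined unless observed agreement is also perfect, in
    which case 1.0 is returned; otherwise NaN flags the undefined case.
    """
    cats = [AnnotationLabel(c).value if isinstance(c, AnnotationLabel) else str(c)
            for c in categories]
    va, vb = [str(getattr(x, "value", x)) for x in a], [str(getattr(x, "value", x)) for x in b]
    if len(va) != len(vb):
        raise ValueError(f"sequences differ in length: {len(va)} vs {len(vb)}")
    if len(va) < 2:
        raise ValueError("need at least 2 items")
    unknown = (set(va) | set(vb)) - set(cats)
    if unknown:
        raise ValueError(f"labels outside the category set: {sorted(unknown)}")
    n = len(va)
    idx = {c: i for i, c in enumerate(cats)}
    p_o = sum(x == y for x, y in zip(va, vb)) / n
    ma = np.bincount([idx[x] for x in va], minlength=len(cats)) / n
    mb = np.bincount([idx[x] for x in vb], minlength=len(cats)) / n
    p_e = float(ma @ mb)
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else math.nan
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(counts: np.ndarray) -> float:
    """Fleiss' kappa from an items x categories vote-count matrix.

    Every row must sum to the same number of raters (>= 2). Returns NaN
    when the pooled chance agreement is 1 (all votes in one category),
    where the statistic is undefined.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D items x categories matrix")
    row_sums = counts.sum(axis=1)
    n_raters = row_sums[0] if len(row_sums) else 0
    if not np.all(row_sums == n_raters):
        raise ValueError("ragged rows: every item needs the same number of raters")
    if n_raters < 2:
        raise ValueError("need at least 2 raters per item")
    n_items = counts.shape[0]
    p_i = ((counts * (counts - 1)).sum(axis=1)) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0 - 1e-12:
        return math.nan
    return (p_bar - p_e) / (1.0 - p_e)


_BANDS = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch band: <0 poor, 0-0.20 slight, 0.21-0.40 fair,
    0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect."""
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor"
    band = "slight"
    for lo, name in _BANDS:
        if kappa > lo:
            band = name
    return band


def percent_agreement(table: Sequence[Sequence]) -> float:
    """100 x (items on which all raters agree) / n, to one decimal.

    `table` is a complete rectangular items x raters label table; missing
    cells (None/NaN) are an error.
    """
    rows = list(table)
    if not rows:
        raise ValueError("empty table")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"row {i} has {len(row)} cells, expected {width}")
        for cell in row:
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                raise ValueError(f"missing cell in row {i}")
    unanimous = sum(1 for row in rows if len({str(getattr(c, "value", c)) for c in row}) == 1)
    return round(100.0 * unanimous / len(rows), 1)


@dataclass
class AgreementReport:
    percent_agreement: float
    fleiss: float
    cohen: dict[str, float]               # "r1-r2" -> kappa
    interpretations: dict[str, str]
    n_items: int
    n_raters: int
    categories: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "percent_agreement": self.percent_agreement,
            "fleiss": None if math.isnan(self.fleiss) else round(self.fleiss, 3),
            "cohen": {k: (None if math.isnan(v) else round(v, 3))
                      for k, v in self.cohen.items()},
            "interpretations": self.interpretations,
            "n_items": self.n_items,
            "n_raters": self.n_raters,
            "categories": list(self.categories),
        }


def compute_agreement_report(annotations: pd.DataFrame,
                             categories: Sequence = LABELS) -> AgreementReport:
    """Full agreement report from a long-format annotation table.

    `annotations` needs columns image_id, rater_id, label, complete over
    the image x rater grid. Kappas are reported to 3 decimals, percent
    agreement to 1 decimal. With two raters both Fleiss' (pooled-marginal
    chance) and Cohen's (per-rater-marginal chance) are reported; they are
    different statistics and are not conflated.
    """
    cats = [AnnotationLabel(c).value if isinstance(c, AnnotationLabel) else str(c)
            for c in categories]
    pivot = annotations.pivot(index="image_id", columns="rater_id", values="label")
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()[:5]
        raise ValueError(f"incomplete annotation table; e.g. images {missing}")
    pivot = pivot.map(lambda x: str(getattr(x, "value", x)))
    raters = list(pivot.columns)
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(pivot), len(cats)), dtype=np.int64)
    for j, r in enumerate(raters):
        for i, lab in enumerate(pivot[r]):
            counts[i, idx[lab]] += 1

    pa = percent_agreement(pivot.values.tolist())
    fk = fleiss_kappa(counts)
    cohen = {}
    interpretations = {"fleiss": interpret_kappa(fk)}
    for ra, rb in itertools.combinations(raters, 2):
        key = f"{ra}-{rb}"
        ck = cohen_kappa(pivot[ra].tolist(), pivot[rb].tolist(), cats)
        cohen[key] = ck
        interpretations[f"cohen:{key}"] = interpret_kappa(ck)
    return AgreementReport(
        percent_agreement=pa, fleiss=fk, cohen=cohen,
        interpretations=interpretations, n_items=len(pivot),
        n_raters=len(raters), categories=tuple(cats),
    )
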