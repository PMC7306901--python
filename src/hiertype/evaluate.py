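"""Seven-category evaluation of hierarchical predictions.

Every (true label, prediction) pair falls into exactly one of seven
categories, extending the usual confusion dichotomy to classifiers
that can stop part-way down the hierarchy ("intermediate") or reject
("unassigned"), and to query cell types absent from the reference:

====================== =========================================
category               meaning
====================== =========================================
correctly_classified   true type in reference, leaf prediction matches
misclassified          true type in reference, leaf prediction differs
correct_intermediate   intermediate set contains the true type
incorrect_intermediate intermediate set misses the true type
incorrectly_unassigned true type in reference but rejected
incorrectly_assigned   true type absent yet assigned somewhere
correctly_unassigned   true type absent and rejected
====================== =========================================
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import PredictionRecord
from .containers import CellAnnotation, ValidationError

UNASSIGNED = "unassigned"

CATEGORIES = (
    "correctly_classified",
    "misclassified",
    "correct_intermediate",
    "incorrect_intermediate",
    "incorrectly_unassigned",
    "incorrectly_assigned",
    "correctly_unassigned",
)


@dataclass
class EvalRecord:
    cell_id: str
    true_label: str
    predicted: str | frozenset
    category: str


def categorize(
    true_label: str,
    predicted: str | frozenset | set,
    reference_label_set: set,
    tree=None,
) -> str:
    """Assign one of the seven evaluation categories.

    ``predicted`` is a leaf label string, the string "unassigned", or
    a set of labels (an intermediate node's cell-type set, taken from
    the reference tree). ``tree`` is accepted for context but the
    intermediate check only needs the predicted node's label set.
    """
    in_ref = true_label in reference_label_set
    if isinstance(predicted, (set, frozenset)):
        if not in_ref:
            return "incorrectly_assigned"
        return (
            "correct_intermediate"
            if true_label in predicted
            else "incorrect_intermediate"
        )
    if predicted == UNASSIGNED:
        return "incorrectly_unassigned" if in_ref else "correctly_unassigned"
    # leaf prediction
    if not in_ref:
        return "incorrectly_assigned"
    return "correctly_classified" if predicted == true_label else "misclassified"


def evaluate_predictions(
    records: list[PredictionRecord],
    truth: CellAnnotation,
    reference_label_set: set,
    tree=None,
) -> list[EvalRecord]:
    out = []
    for r in records:
        t = truth[r.cell_id]
        out.append(
            EvalRecord(
                r.cell_id,
                t,
                r.final_label,
                categorize(t, r.final_label, set(reference_label_set), tree),
            )
        )
    return out


def category_counts(records: list[EvalRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return counts


def accuracy(records: list[EvalRecord], method_class: str = "plain") -> float:
    """Classification accuracy under one of three scoring rules.

    ``plain`` scores only leaf-level calls (for methods without
    rejection); ``with_unassigned`` additionally scores the
    unassigned-related categories, counting correct rejections as
    correct; ``with_both`` further counts correct intermediate
    assignments as correct.
    """
    c = category_counts(records)
    num = c["correctly_classified"]
    den = c["correctly_classified"] + c["misclassified"]
    if method_class in ("with_unassigned", "with_both"):
        num += c["correctly_unassigned"]
        den += (
            c["incorrectly_unassigned"]
            + c["incorrectly_assigned"]
            + c["correctly_unassigned"]
        )
    if method_class == "with_both":
        num += c["correct_intermediate"]
        den += c["correct_intermediate"] + c["incorrect_intermediate"]
    elif method_class not in ("plain", "with_unassigned"):
        raise ValueError(f"unknown method class {method_class!r}")
    if den == 0:
        raise ValidationError("no records in the accuracy denominator")
    return num / den


def summary_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "true_label": [r.true_label for r in records],
            "predicted": [
                "|".join(sorted(r.predicted))
                if isinstance(r.predicted, frozenset)
                else str(r.predicted)
                for r in records
            ],
            "category": [r.category for r in records],
        }
    )
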