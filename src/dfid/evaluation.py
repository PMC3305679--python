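"""Per-monograph precision/recall/F-measure and macro-averaged summaries.

For a monograph with predicted dosage-form set D and reference set F:

    Precision = |D ∩ F| / |D|        Recall = |D ∩ F| / |F|
    F-Measure = 2 P R / (P + R)

Matching is exact set identity on concept ids.  Conventions: an empty
prediction scores P = 0 (a monograph for which the method returns nothing
counts as a failure, not a skip), and F = 0 whenever P + R = 0.  The
overall figure is the macro average — the mean of per-monograph values —
reported together with the sample standard deviation, median and
interquartile range of each metric.

An optional hierarchical-credit mode relaxes exactness: a predicted
concept also counts as correct when it is an ancestor or descendant of a
reference concept (and symmetrically for recall).  It is off by default;
exact match is the primary scoring mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .normalizer import IdentificationResult
from .standards import ReferenceStandard
from .terminology import DFTree


@dataclass(frozen=True)
class PerMonographMetrics:
    monograph_id: str
    precision: float
    recall: float
    f_measure: float
    n_predicted: int
    n_reference: int
    n_correct: int


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    standard_deviation: float
    median: float
    interquartile_range: float


@dataclass(frozen=True)
class EvaluationSummary:
    precision: MetricSummary
    recall: MetricSummary
    f_measure: MetricSummary
    n_monographs: int


def _hier_related(tree: DFTree, a: str, b: str) -> bool:
    return a == b or tree.is_ancestor(a, b) or tree.is_ancestor(b, a)


def prf(
    predicted: set[str],
    reference: set[str],
    monograph_id: str = "",
    *,
    tree: DFTree | None = None,
    hierarchical: bool = False,
) -> PerMonographMetrics:
    """Exact-match precision/recall/F for one monograph.

    *reference* must be nonempty — monographs without reference forms are
    excluded upstream, so an empty reference signals a standards bug.
    With ``hierarchical=True`` (requires *tree*), ancestor/descendant
    pairs count as matches.
    """
    if not reference:
        raise ValueError(
            f"empty reference set for monograph {monograph_id!r}"
        )
    if hierarchical:
        if tree is None:
            raise ValueError("hierarchical scoring requires the DFTree")
        correct_pred = sum(
            1 for p in predicted
            if any(_hier_related(tree, p, r) for r in reference)
        )
        correct_ref = sum(
            1 for r in reference
            if any(_hier_related(tree, p, r) for p in predicted)
        )
    else:
        correct_pred = correct_ref = len(predicted & reference)

    precision = correct_pred / len(predicted) if predicted else 0.0
    recall = correct_ref / len(reference)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return PerMonographMetrics(
        monograph_id=monograph_id,
        precision=precision,
        recall=recall,
        f_measure=f,
        n_predicted=len(predicted),
        n_reference=len(reference),
        n_correct=correct_pred,
    )


def _summarize(values: Sequence[float]) -> MetricSummary:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    q1, q3 = np.percentile(arr, [25, 75])  # linear-interpolation quantiles
    return MetricSummary(
        mean=float(np.mean(arr)),
        standard_deviation=sd,
        median=float(np.median(arr)),
        interquartile_range=float(q3 - q1),
    )


def evaluate_monographs(
    predictions: Mapping[str, set[str]],
    standard: ReferenceStandard,
    *,
    tree: DFTree | None = None,
    hierarchical: bool = False,
) -> list[PerMonographMetrics]:
    """Per-monograph metrics for every entry of the standard.

    A monograph missing from *predictions* is scored as an empty
    prediction; monographs in ``standard.excluded`` are skipped.
    """
    out = []
    for monograph_id in sorted(standard.entries):
        out.append(
            prf(
                set(predictions.get(monograph_id, set())),
                standard.entries[monograph_id],
                monograph_id,
                tree=tree,
                hierarchical=hierarchical,
            )
        )
    return out


def summarize(per_monograph: Sequence[PerMonographMetrics]) -> EvaluationSummary:
    if not per_monograph:
        raise ValueError("no monographs to summarize")
    return EvaluationSummary(
        precision=_summarize([m.precision for m in per_monograph]),
        recall=_summarize([m.recall for m in per_monograph]),
        f_measure=_summarize([m.f_measure for m in per_monograph]),
        n_monographs=len(per_monograph),
    )


def macro_evaluate(
    results: Iterable[IdentificationResult],
    standard: ReferenceStandard,
    *,
    tree: DFTree | None = None,
    hierarchical: bool = False,
) -> EvaluationSummary:
    """Macro-averaged summary of identification results against a
    standard; raises on a standard with zero entries."""
    if not standard.entries:
        raise ValueError("reference standard has no entries")
    predictions = {r.monograph_id: r.dosage_forms for r in results}
    per = evaluate_monographs(
        predictions, standard, tree=tree, hierarchical=hierarchical
    )
    return summarize(per)
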