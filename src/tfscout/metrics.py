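"""Evaluation metrics for TF prediction.

Performance is the percentage of annotated TFs that were predicted;
accuracy (split into experimentally validated, EV, and putative, PU,
partitions of the predictions) is the percentage of predicted TFs that
agree with the reference annotation; precision/recall/F1 follow the
usual confusion-matrix definitions. "Agreement" is operationalized as a
normalized family-label match when both sides carry a family, else the
binary is-TF match; the comparator is a documented, swappable function.

Percentages are kept at full precision internally and rounded half-up
to 2 decimals only when a report is rendered. An undefined putative
accuracy (no putative TFs predicted) renders as the em-dash sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Optional

import pandas as pd

from .classifier import Prediction
from .database import normalize_family
from .errors import ConsistencyError, UndefinedMetricError

PU_SENTINEL = "—"  # em dash, printed when no putative TFs were predicted


def performance(predicted_tfs: int, annotated_tfs: int) -> float:
    """Percentage of annotated TFs recovered: 100 * predicted / annotated."""
    if annotated_tfs <= 0:
        raise UndefinedMetricError("performance undefined: no annotated TFs")
    return 100.0 * predicted_tfs / annotated_tfs


def accuracy_ev(predicted_correctly: int, predicted_tfs: int) -> float:
    """Percentage of predicted TFs agreeing with the reference annotation."""
    if predicted_tfs <= 0:
        raise UndefinedMetricError("accuracy undefined: no TFs predicted")
    return 100.0 * predicted_correctly / predicted_tfs


def accuracy_pu(putative_correct: int, putative_predicted: int) -> Optional[float]:
    """Putative-partition accuracy; None (rendered as a dash) when no
    putative TFs were predicted."""
    if putative_predicted <= 0:
        return None
    return 100.0 * putative_correct / putative_predicted


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Standard definitions; 0/0 cases return 0 by convention."""
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals, for report rendering only."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvalCounts:
    predicted_tfs: int = 0
    annotated_tfs: int = 0
    predicted_correctly: int = 0
    ev_predicted: int = 0
    ev_correct: int = 0
    putative_predicted: int = 0
    putative_correct: int = 0
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class EvalReport:
    counts: EvalCounts
    performance_pct: Optional[float]
    accuracy_ev_pct: Optional[float]
    accuracy_pu_pct: Optional[float]
    precision: float
    recall: float
    f1: float
    per_family: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        """Rendered metrics (2-decimal percentages, dash sentinel)."""
        def pct(v):
            return PU_SENTINEL if v is None else round2(v)

        c = self.counts
        return {
            "predicted_tfs": c.predicted_tfs,
            "annotated_tfs": c.annotated_tfs,
            "predicted_correctly": c.predicted_correctly,
            "putative_predicted": c.putative_predicted,
            "putative_correct": c.putative_correct,
            "performance_pct": pct(self.performance_pct),
            "accuracy_ev_pct": pct(self.accuracy_ev_pct),
            "accuracy_pu_pct": pct(self.accuracy_pu_pct),
            "precision": round(self.precision, 3),
            "recall": round(self.recall, 3),
            "f1": round(self.f1, 3),
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "tn": c.tn,
        }

    def to_json(self, path=None) -> str:
        payload = {
            "summary": self.summary(),
            "per_family": self.per_family.reset_index().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.summary().items():
                fh.write(f"{k}\t{v}\n")


def default_comparator(pred_family: Optional[str], ref_is_tf: bool, ref_family: str) -> bool:
    """A prediction is correct when the reference marks the query as a TF
    and, when both sides carry a family label, the normalized labels match."""
    if not ref_is_tf:
        return False
    if pred_family and ref_family:
        return normalize_family(pred_family) == normalize_family(ref_family)
    return True


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "tf")
    return bool(v)


def evaluate_against_reference(
    predictions: list[Prediction],
    reference: pd.DataFrame,
    comparator: Callable[[Optional[str], bool, str], bool] = default_comparator,
) -> EvalReport:
    """Score predictions against a reference annotation table.

    ``reference`` needs columns query_id, is_tf, family, evidence.
    Predictions fall into EV/PU partitions by the reference evidence of
    their query (EV when the query is absent from the reference or its
    evidence is unspecified); the partitions are disjoint and together
    cover all predicted TFs. A query predicted as a TF with the wrong
    family counts both as a false positive and as a missed annotation.
    """
    ref = reference.copy()
    for col in ("family", "evidence"):
        if col not in ref.columns:
            ref[col] = ""
    dup = ref["query_id"][ref["query_id"].duplicated()]
    if not dup.empty:
        raise ConsistencyError(f"duplicate query_ids in reference: {sorted(set(dup))[:5]}")
    ref_map = {
        str(row.query_id): (_as_bool(row.is_tf), str(row.family or ""), str(row.evidence or ""))
        for row in ref.itertuples()
    }

    counts = EvalCounts()
    counts.annotated_tfs = sum(1 for is_tf, _, _ in ref_map.values() if is_tf)
    correct_ref_ids: set[str] = set()
    fam_rows: dict[str, dict[str, int]] = {}

    def fam_counts(label: str) -> dict[str, int]:
        return fam_rows.setdefault(normalize_family(label) or "(none)", {"tp": 0, "fp": 0, "fn": 0})

    predicted_ids = set()
    for p in predictions:
        if p.call == "non-TF":
            continue
        predicted_ids.add(p.query_id)
        counts.predicted_tfs += 1
        is_tf, ref_family, evidence = ref_map.get(p.query_id, (False, "", ""))
        correct = comparator(p.family, is_tf, ref_family)
        putative = evidence.upper() == "PU"
        if putative:
            counts.putative_predicted += 1
            counts.putative_correct += int(correct)
        else:
            counts.ev_predicted += 1
            counts.ev_correct += int(correct)
        counts.predicted_correctly += int(correct)
        if correct:
            counts.tp += 1
            correct_ref_ids.add(p.query_id)
            if p.family:
                fam_counts(p.family)["tp"] += 1
        else:
            counts.fp += 1
            if p.family:
                fam_counts(p.family)["fp"] += 1

    for qid, (is_tf, ref_family, _) in ref_map.items():
        if is_tf and qid not in correct_ref_ids:
            counts.fn += 1
            if ref_family:
                fam_counts(ref_family)["fn"] += 1
    universe = predicted_ids | set(ref_map) | {p.query_id for p in predictions}
    positives = predicted_ids | {q for q, (t, _, _) in ref_map.items() if t}
    counts.tn = len(universe) - len(positives)

    precision, recall, f1 = precision_recall_f1(counts.tp, counts.fp, counts.fn)
    per_family = pd.DataFrame.from_dict(fam_rows, orient="index").sort_index()
    per_family.index.name = "family"
    return EvalReport(
        counts=counts,
        performance_pct=(
            performance(counts.predicted_tfs, counts.annotated_tfs)
            if counts.annotated_tfs > 0
            else None
        ),
        accuracy_ev_pct=(
            accuracy_ev(counts.ev_correct, counts.ev_predicted)
            if counts.ev_predicted > 0
            else None
        ),
        accuracy_pu_pct=accuracy_pu(counts.putative_correct, counts.putative_predicted),
        precision=precision,
        recall=recall,
        f1=f1,
        per_family=per_family,
    )
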