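"""Leave-one-subject-out evaluation and the SLSS/MLMS sensor-combo ablation.

Offline performance is measured window-level: for each sensor combination a
model is trained per LOSO fold, window predictions at threshold 0.5 are
pooled across folds (micro-average), and precision / recall / F1 / accuracy
are computed from the pooled confusion counts.  The whole procedure repeats
over several seeds (3 by default) and reports per-repeat metrics and their
mean.  "Leave-one-out" is leave-one-SUBJECT-out: per-window splits would
leak trials across train and test.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import DatasetIndex
from .transformer import TrainSpec, TransformerConfig, train
from .windowing import SensorCombo, WindowBatch, WindowingConfig, windows_from_index

__all__ = [
    "SLSS_COMBOS",
    "MLMS_COMBOS",
    "ALL_COMBOS",
    "MetricsReport",
    "AblationResult",
    "loso_splits",
    "compute_metrics",
    "evaluate_model",
    "run_ablation",
    "summarize_report",
    "round_half_up",
]

#: Single-location single-sensor baselines, in presentation order.
SLSS_COMBOS: tuple[str, ...] = ("wA", "hA", "wG", "hG")

#: The 11 multi-location/multi-sensor combinations, in presentation order.
MLMS_COMBOS: tuple[str, ...] = (
    "wA+wG",
    "hA+hG",
    "wA+hA",
    "wG+hG",
    "wA+hG",
    "hA+wG",
    "wA+hA+wG",
    "wA+hA+hG",
    "wA+wG+hG",
    "hA+wG+hG",
    "wA+wG+hA+hG",
)

ALL_COMBOS: tuple[str, ...] = SLSS_COMBOS + MLMS_COMBOS


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding used by the report tables (0.875 -> 0.88)."""
    factor = 10**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        m = compute_metrics(self.tp, self.fp, self.tn, self.fn, _raw=True)
        self.precision, self.recall, self.f1, self.accuracy = m

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


def compute_metrics(tp: int, fp: int, tn: int, fn: int, _raw: bool = False):
    """Precision, recall, F1 and accuracy from confusion counts.

    Undefined ratios (zero denominator) are reported as NaN with a warning,
    never silently as 0; all-zero counts are a degenerate error.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("degenerate confusion matrix: all counts are zero")
    if tp + fp == 0:
        warnings.warn("precision undefined (no positive predictions); reporting NaN")
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall undefined (no positive labels); reporting NaN")
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / total
    if _raw:
        return precision, recall, f1, accuracy
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


def loso_splits(index: DatasetIndex) -> list[tuple[list[str], str]]:
    """One fold per subject: (training subjects, held-out subject)."""
    subjects = index.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != test], test) for test in subjects]


def _confusion(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5):
    pred = probs > threshold
    pos = labels == 1
    return (
        int((pred & pos).sum()),
        int((pred & ~pos).sum()),
        int((~pred & ~pos).sum()),
        int((~pred & pos).sum()),
    )


def _subset_batch(batch: WindowBatch, subjects: set[str]) -> WindowBatch:
    idx = [i for i, (src, _) in enumerate(batch.provenance) if src.split("/")[0] in subjects]
    return WindowBatch(
        windows=batch.windows[idx],
        labels=batch.labels[idx],
        provenance=[batch.provenance[i] for i in idx],
    )


def evaluate_model(model, batch: WindowBatch, threshold: float = 0.5) -> MetricsReport:
    """Window-level metrics of a trained model on a labelled batch."""
    probs = model.predict_proba(batch.windows)
    tp, fp, tn, fn = _confusion(probs, batch.labels, threshold)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class ComboResult:
    combo: SensorCombo
    per_repeat: list[MetricsReport]

    @property
    def precision(self) -> float:
        return float(np.mean([m.precision for m in self.per_repeat]))

    @property
    def recall(self) -> float:
        return float(np.mean([m.recall for m in self.per_repeat]))

    @property
    def f1(self) -> float:
        return float(np.mean([m.f1 for m in self.per_repeat]))

    @property
    def accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.per_repeat]))


@dataclass
class AblationResult:
    results: dict[str, ComboResult]

    @property
    def slss(self) -> list[ComboResult]:
        return [self.results[c] for c in SLSS_COMBOS if c in self.results]

    @property
    def mlms(self) -> list[ComboResult]:
        return [self.results[c] for c in MLMS_COMBOS if c in self.results]

    @property
    def best_combo(self) -> ComboResult:
        return max(self.results.values(), key=lambda r: r.f1)


def run_ablation(
    index: DatasetIndex,
    combos: list[str | SensorCombo],
    spec: TrainSpec,
    config: TransformerConfig,
    windowing: WindowingConfig | None = None,
) -> AblationResult:
    """LOSO x repeats training for each sensor combination.

    Fold confusion counts are pooled (micro-average) into one metrics row
    per repeat; repeats use seeds ``spec.seed + r`` and are averaged
    arithmetically.  Deterministic given the cohort and seeds.
    """
    windowing = windowing or WindowingConfig()
    folds = loso_splits(index)
    results: dict[str, ComboResult] = {}
    for combo in combos:
        combo = combo if isinstance(combo, SensorCombo) else SensorCombo(combo)
        batch = windows_from_index(index, combo, windowing)
        per_repeat: list[MetricsReport] = []
        for r in range(spec.repeats):
            rspec = TrainSpec(
                epochs=spec.epochs,
                batch_size=spec.batch_size,
                learning_rate=spec.learning_rate,
                seed=spec.seed + r,
                repeats=1,
            )
            counts = np.zeros(4, dtype=int)
            for train_subjects, test_subject in folds:
                try:
                    train_b = _subset_batch(batch, set(train_subjects))
                    test_b = _subset_batch(batch, {test_subject})
                    model = train(train_b, rspec, config).model
                    probs = model.predict_proba(test_b.windows)
                    counts += np.array(_confusion(probs, test_b.labels))
                except Exception as exc:
                    raise RuntimeError(
                        f"ablation failed for combo {combo} on fold holding out "
                        f"{test_subject}: {exc}"
                    ) from exc
            per_repeat.append(MetricsReport(*map(int, counts)))
        results[combo.name] = ComboResult(combo=combo, per_repeat=per_repeat)
    return AblationResult(results=results)


def summarize_report(result: AblationResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Render the ablation as a CSV and a human-readable table.

    Rows are ordered SLSS first then MLMS, both in presentation order;
    values are rounded half-up to 2 decimals and the best F1 is starred.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = result.slss + result.mlms
    if not rows:
        raise ValueError("empty ablation result")
    best = result.best_combo.combo.name
    csv_path = out_dir / "ablation.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "combo", "precision", "recall", "f1", "accuracy", "best"])
        for r in rows:
            group = "SLSS" if r.combo.name in SLSS_COMBOS else "MLMS"
            writer.writerow(
                [
                    group,
                    r.combo.name,
                    f"{round_half_up(r.precision):.2f}",
                    f"{round_half_up(r.recall):.2f}",
                    f"{round_half_up(r.f1):.2f}",
                    f"{round_half_up(r.accuracy):.2f}",
                    "*" if r.combo.name == best else "",
                ]
            )
    txt_path = out_dir / "ablation.txt"
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(f"{'Training Data':<16}{'Precision':>10}{'Recall':>8}{'F1':>8}\n")
        for r in rows:
            star = " *" if r.combo.name == best else ""
            fh.write(
                f"{r.combo.name:<16}{round_half_up(r.precision):>10.2f}"
                f"{round_half_up(r.recall):>8.2f}{round_half_up(r.f1):>8.2f}{star}\n"
            )
    return csv_path, txt_path
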