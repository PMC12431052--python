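"""Feedback-driven retraining: merge TP/FP/TN/FN events into the base pool.

User-confirmed alarms (TP) and user-reported missed falls (FN) join the fall
class; rejected alarms (FP) and sampled quiet windows (TN) join the ADL
class.  Because most harvested data are TNs, a fraction knob (1, 1/2, 1/4 or
0 of the TNs) controls the class imbalance of the merged pool; fractional
pool sizes round half-up.  Retraining is always training from scratch on
the merged pool with the same architecture — never fine-tuning — so the
result does not depend on the previous model's weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FeedbackEvent, FeedbackKind
from .transformer import TrainSpec, TransformerConfig, TrainResult, train
from .windowing import SensorCombo, WindowBatch, WindowingConfig, windows_from_index

__all__ = ["RetrainSpec", "PoolReport", "subsample_pool", "merge_feedback", "retrain"]

TN_FRACTIONS = (1.0, 0.5, 0.25, 0.0)


def subsample_pool(pool_size: int, fraction: float) -> int:
    """Round-half-up share of a pool (23,179 at 1/2 -> 11,590)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return int(math.floor(pool_size * fraction + 0.5))


@dataclass
class RetrainSpec:
    base_batch: WindowBatch  # windows of the original cohort for the combo
    feedback: list[FeedbackEvent]
    tn_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tn_fraction not in TN_FRACTIONS:
            raise ValueError(f"tn_fraction must be one of {TN_FRACTIONS}")


@dataclass
class PoolReport:
    """Pool accounting in the convention of the feedback-retraining tables."""

    n_base_fall: int
    n_base_adl: int
    n_tp: int
    n_fn: int
    n_fp: int
    n_tn_total: int
    n_tn_kept: int

    @property
    def n_fall(self) -> int:
        return self.n_base_fall + self.n_tp + self.n_fn

    @property
    def n_adl(self) -> int:
        return self.n_base_adl + self.n_fp + self.n_tn_kept


def _event_windows(event: FeedbackEvent, window_size: int) -> list[np.ndarray]:
    """Cut an event payload into non-overlapping model windows.

    TP/FP/TN payloads are exactly one window; FN payloads span the window
    ending at the user's report plus the preceding window.
    """
    L = len(event.window_payload)
    if L < window_size:
        raise ValueError(
            f"feedback payload of {L} rows is shorter than a {window_size}-sample window"
        )
    return [
        event.window_payload[s : s + window_size]
        for s in range(0, L - window_size + 1, window_size)
    ]


def merge_feedback(
    spec: RetrainSpec, windowing: WindowingConfig | None = None
) -> tuple[WindowBatch, PoolReport]:
    """Assemble the retraining pool: base windows plus labelled feedback.

    The TN subsample is drawn uniformly without replacement with the spec's
    seed; the fall pool is base falls + TP + FN, the ADL pool base ADLs +
    FP + the kept TNs.  No deduplication of overlapping payloads is done,
    matching the additive pool accounting of the deployed system.
    """
    windowing = windowing or WindowingConfig()
    W = windowing.window_size
    base = spec.base_batch
    if len(base) and base.windows.shape[1] != W:
        raise ValueError("base batch window size does not match the windowing config")
    width = base.windows.shape[2] if len(base) else None

    by_kind: dict[FeedbackKind, list[FeedbackEvent]] = {k: [] for k in FeedbackKind}
    for ev in spec.feedback:
        if width is not None and ev.window_payload.shape[1] != width:
            raise ValueError(
                f"feedback payload width {ev.window_payload.shape[1]} does not match "
                f"the base combo width {width}"
            )
        by_kind[ev.kind].append(ev)

    tns = by_kind[FeedbackKind.TN]
    n_keep = subsample_pool(len(tns), spec.tn_fraction)
    rng = np.random.default_rng(spec.seed)
    kept_idx = sorted(rng.choice(len(tns), size=n_keep, replace=False)) if n_keep else []
    kept_tns = [tns[i] for i in kept_idx]

    windows = [base.windows] if len(base) else []
    labels = [base.labels] if len(base) else []
    provenance = list(base.provenance)
    for ev in by_kind[FeedbackKind.TP] + by_kind[FeedbackKind.FN] + by_kind[FeedbackKind.FP] + kept_tns:
        for w in _event_windows(ev, W):
            windows.append(w[None])
            labels.append(np.array([ev.retrain_label]))
            provenance.append((f"feedback/{ev.kind.value}/{ev.subject_id}", int(ev.timestamp_ms)))

    merged = WindowBatch(
        windows=np.concatenate(windows) if windows else np.zeros((0, W, width or 0)),
        labels=np.concatenate(labels) if labels else np.zeros(0, dtype=np.int64),
        provenance=provenance,
    )
    report = PoolReport(
        n_base_fall=int((base.labels == 1).sum()) if len(base) else 0,
        n_base_adl=int((base.labels == 0).sum()) if len(base) else 0,
        n_tp=len(by_kind[FeedbackKind.TP]),
        n_fn=len(by_kind[FeedbackKind.FN]),
        n_fp=len(by_kind[FeedbackKind.FP]),
        n_tn_total=len(tns),
        n_tn_kept=len(kept_tns),
    )
    return merged, report


def retrain(
    merged: WindowBatch,
    spec: TrainSpec,
    config: TransformerConfig,
) -> TrainResult:
    """Train a fresh model on the merged pool (full training, no fine-tuning)."""
    return train(merged, spec, config)
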