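"""Human-in-the-loop iterative fine-tuning scaffold.

Cycle: predict -> export masks for correction -> ingest corrected pairs ->
retrain -> evaluate on a frozen held-out test set -> stop once every
tracked metric clears its threshold. The test set is fixed at construction
and content-hashed; any attempt to feed a test image back into training is
rejected, and reports are append-only, JSON-serialisable records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

__all__ = ["CycleReport", "HITLLoop", "check_stop", "content_hash"]


def content_hash(image: np.ndarray) -> str:
    a = np.ascontiguousarray(np.asarray(image))
    return hashlib.sha256(a.tobytes() + str(a.shape).encode()).hexdigest()[:16]


@dataclass
class CycleReport:
    cycle_index: int
    n_train: int
    n_val: int
    n_test: int
    metrics: dict            # name -> value (e.g. accuracy/precision/recall/f1)
    stop_decision: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def check_stop(history, thresholds: dict) -> bool:
    """True iff, in the latest report, every tracked metric meets or
    exceeds its threshold (confluency convention 0.90, counting 0.95)."""
    if not history:
        raise ValueError("at least one cycle report is required")
    last = history[-1]
    metrics = last.metrics if isinstance(last, CycleReport) else last
    return all(metrics.get(k, 0.0) >= v for k, v in thresholds.items())


class HITLLoop:
    """Orchestrates correction-driven retraining.

    Parameters
    ----------
    train_fn : callable(train_pairs, val_pairs, seed) -> model
    eval_fn : callable(model, test_pairs) -> dict of metric name -> value
    thresholds : metric name -> required value for stopping
    test_set : frozen held-out (image, mask) pairs, never trained on
    """

    def __init__(self, train_fn: Callable, eval_fn: Callable, thresholds: dict,
                 train_set, val_set, test_set, seed: int = 0):
        self.train_fn = train_fn
        self.eval_fn = eval_fn
        self.thresholds = dict(thresholds)
        self.train_pool = list(train_set)
        self.val_pool = list(val_set)
        self.test_set = list(test_set)
        self.seed = seed
        self._test_hashes = {content_hash(im) for im, _ in self.test_set}
        for im, _ in list(self.train_pool) + list(self.val_pool):
            if content_hash(im) in self._test_hashes:
                raise ValueError("test-set image leaked into train/val pool")
        self.history: list[CycleReport] = []
        self.model = None

    def run_cycle(self, new_corrected_pairs=()) -> CycleReport:
        """Merge corrected pairs, retrain, evaluate on the frozen test set.

        Raises on a shape mismatch between an image and its corrected mask
        or on a test-set content-hash collision (leakage attempt)."""
        for im, mk in new_corrected_pairs:
            if np.asarray(im).shape[:2] != np.asarray(mk).shape[:2]:
                raise ValueError("corrected mask shape does not match its image")
            if content_hash(im) in self._test_hashes:
                raise ValueError("correction duplicates a held-out test image")
        self.train_pool.extend(new_corrected_pairs)
        cycle = len(self.history) + 1
        self.model = self.train_fn(self.train_pool, self.val_pool,
                                   self.seed + cycle)
        metrics = self.eval_fn(self.model, self.test_set)
        report = CycleReport(cycle, len(self.train_pool), len(self.val_pool),
                             len(self.test_set), dict(metrics),
                             stop_decision=all(
                                 metrics.get(k, 0.0) >= v
                                 for k, v in self.thresholds.items()))
        self.history.append(report)
        return report

    def should_stop(self) -> bool:
        return bool(self.history) and check_stop(self.history, self.thresholds)

    def dump_reports(self) -> str:
        """Reports as JSON lines; replaying them reproduces stop decisions."""
        return "\n".join(r.to_json() for r in self.history)
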