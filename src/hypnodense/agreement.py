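"""Epoch-level agreement between a reference and a test hypnogram.

Cohen's kappa for overall agreement, plus per-class F1 / sensitivity / PPV.
Per-class scores for stages absent from both stagings are reported as NaN
rather than 0, to avoid fabricating performance for absent stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import Hypnogram, StageSet

__all__ = [
    "ConfusionMatrix",
    "AgreementResult",
    "confusion",
    "cohens_kappa",
    "per_class_scores",
    "agreement",
]


@dataclass
class ConfusionMatrix:
    """K x K epoch counts; rows = reference stage, columns = test stage."""

    counts: np.ndarray
    stage_set: StageSet

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.stage_set)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementResult:
    kappa: float
    per_class: dict[str, dict[str, float]]  # stage -> {f1, sensitivity, ppv}
    n_epochs: int


def confusion(ref: Hypnogram, test: Hypnogram) -> ConfusionMatrix:
    if len(ref) != len(test):
        raise ValueError(f"length mismatch: {len(ref)} vs {len(test)}")
    if ref.stage_set != test.stage_set:
        raise ValueError("stagings use different stage sets")
    k = len(ref.stage_set)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ref.codes, test.codes), 1)
    return ConfusionMatrix(counts=counts, stage_set=ref.stage_set)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Returns NaN when expected agreement is 1 (a single class on both
    sides), where kappa is undefined.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / (n * n)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_scores(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-stage sensitivity, PPV and F1.

    Boundary conventions: a class absent from both reference and test gets
    NaN everywhere; sensitivity is NaN when the class never occurs in the
    reference, PPV is NaN when it is never predicted; F1 is 0 when
    sensitivity is 0 regardless of PPV definedness, NaN only when both
    components are undefined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    ref_totals = counts.sum(axis=1)  # TP + FN
    test_totals = counts.sum(axis=0)  # TP + FP
    out: dict[str, dict[str, float]] = {}
    for i, label in enumerate(cm.stage_set.labels):
        sens = tp[i] / ref_totals[i] if ref_totals[i] > 0 else float("nan")
        ppv = tp[i] / test_totals[i] if test_totals[i] > 0 else float("nan")
        if ref_totals[i] == 0 and test_totals[i] == 0:
            f1 = float("nan")
        elif tp[i] == 0:
            f1 = 0.0
        else:
            f1 = 2 * sens * ppv / (sens + ppv)
        out[label] = {"f1": float(f1), "sensitivity": float(sens),
                      "ppv": float(ppv)}
    return out


def agreement(ref: Hypnogram, test: Hypnogram) -> AgreementResult:
    """Kappa plus per-class scores for one reference/test pair."""
    cm = confusion(ref, test)
    return AgreementResult(
        kappa=cohens_kappa(cm),
        per_class=per_class_scores(cm),
        n_epochs=cm.total,
    )
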