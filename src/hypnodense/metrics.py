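"""Hypnodensity and hypnogram structure measures.

Ambiguity is the normalized Shannon entropy of one epoch's probability
vector (0 = one-hot, 1 = uniform).  Transition continuity is one minus the
total-variation distance between the probability vectors flanking a stage
transition.  Bouts are maximal same-stage runs of the hypnogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Hypnogram, Hypnodensity, Stage

__all__ = [
    "AmbiguitySeries",
    "Transition",
    "Bout",
    "ambiguity",
    "ambiguity_series",
    "detect_transitions",
    "transition_continuity",
    "annotate_transition_continuity",
    "extract_bouts",
    "continuity_tail_fractions",
]

_PROB_TOL = 1e-6


def _check_prob_vector(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("probability vector must be 1-D with K >= 2")
    if np.any(p < -_PROB_TOL) or np.any(p > 1 + _PROB_TOL):
        raise ValueError(f"probabilities outside [0, 1]: {p}")
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError(f"probability vector sums to {p.sum()}, not 1")
    return np.clip(p, 0.0, 1.0)


@dataclass
class AmbiguitySeries:
    """Per-epoch ambiguity paired with the staging used for grouping.

    ``classified_stage`` comes from the same method's own hypnogram (never
    the manual one), so stage-specific pooling groups epochs by what the
    classifier itself decided.
    """

    values: np.ndarray
    classified_stage: Hypnogram

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.classified_stage):
            raise ValueError("ambiguity series length != staging length")
        if np.any(self.values < -_PROB_TOL) or np.any(self.values > 1 + _PROB_TOL):
            raise ValueError("ambiguity values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def for_stage(self, label: str) -> np.ndarray:
        """Values at epochs the staging classified as ``label``."""
        code = self.classified_stage.stage_set.index(label)
        return self.values[self.classified_stage.codes == code]


@dataclass
class Transition:
    """A stage change between adjacent epochs ``boundary_index`` and ``+1``."""

    boundary_index: int
    from_stage: Stage
    to_stage: Stage
    continuity: float | None = None

    def __post_init__(self):
        if self.from_stage.label == self.to_stage.label:
            raise ValueError("transition requires differing stages")
        if self.boundary_index < 0:
            raise ValueError("boundary_index must be >= 0")


@dataclass
class Bout:
    """A maximal run of consecutive epochs in one stage."""

    stage: Stage
    start_epoch: int
    length_epochs: int
    duration: float  # minutes

    def __post_init__(self):
        if self.length_epochs < 1:
            raise ValueError("bout length must be >= 1 epoch")


def ambiguity(p) -> float:
    """Normalized Shannon entropy of a probability vector.

    Computes ``-(1/log K) * sum_i p_i log p_i`` with the 0*log(0) = 0
    convention; natural log throughout (the ratio is base-free).  Returns a
    value in [0, 1]: 0 for a one-hot vector, 1 for the uniform vector.
    """
    p = _check_prob_vector(p)
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    value = h / np.log(p.size)
    # guard float drift at the boundaries; + 0.0 folds -0.0 into 0.0
    return float(min(max(value, 0.0), 1.0)) + 0.0


def ambiguity_series(hd: Hypnodensity, staging: Hypnogram) -> AmbiguitySeries:
    """Per-epoch ambiguity of ``hd``, grouped by the paired ``staging``."""
    if len(hd) != len(staging):
        raise ValueError(
            f"hypnodensity length {len(hd)} != staging length {len(staging)}"
        )
    if hd.stage_set != staging.stage_set:
        raise ValueError("hypnodensity and staging use different stage sets")
    p = hd.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    values = -terms.sum(axis=1) / np.log(p.shape[1])
    return AmbiguitySeries(values=np.clip(values, 0.0, 1.0),
                           classified_stage=staging)


def detect_transitions(h: Hypnogram) -> list[Transition]:
    """All boundaries where adjacent epochs carry different stages, in order."""
    if len(h) < 2:
        raise ValueError("need at least 2 epochs to detect transitions")
    codes = h.codes
    boundaries = np.flatnonzero(codes[1:] != codes[:-1])
    out = []
    for t in boundaries:
        out.append(
            Transition(
                boundary_index=int(t),
                from_stage=h.stage_set.stage(h.stage_set.labels[codes[t]]),
                to_stage=h.stage_set.stage(h.stage_set.labels[codes[t + 1]]),
            )
        )
    return out


def transition_continuity(p_before, p_after) -> float:
    """1 minus the total-variation distance between two probability vectors.

    ``1 - 0.5 * sum_i |p_before_i - p_after_i|``; 1 when the distributions
    are identical, 0 when their supports are disjoint.
    """
    p_before = _check_prob_vector(p_before)
    p_after = _check_prob_vector(p_after)
    if p_before.size != p_after.size:
        raise ValueError("vectors must share K")
    value = 1.0 - 0.5 * float(np.abs(p_before - p_after).sum())
    return float(min(max(value, 0.0), 1.0))


def annotate_transition_continuity(
    hd: Hypnodensity, staging: Hypnogram
) -> list[Transition]:
    """Transitions of ``staging`` with continuity from the flanking hd rows.

    Continuity uses the epochs immediately before (t) and after (t+1) each
    boundary, matching the formula's superscripts.
    """
    if len(hd) != len(staging):
        raise ValueError("hypnodensity and staging lengths differ")
    transitions = detect_transitions(staging)
    for tr in transitions:
        t = tr.boundary_index
        tr.continuity = transition_continuity(hd.probs[t], hd.probs[t + 1])
    return transitions


def extract_bouts(h: Hypnogram) -> list[Bout]:
    """Run-length encode the hypnogram into bouts (durations in minutes).

    Runs at the recording start and end are counted, so total bout time
    equals the recording length.
    """
    codes = h.codes
    change = np.flatnonzero(codes[1:] != codes[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(codes)]))
    minutes_per_epoch = h.epoch_duration / 60.0
    bouts = []
    for s, e in zip(starts, ends):
        label = h.stage_set.labels[codes[s]]
        bouts.append(
            Bout(
                stage=h.stage_set.stage(label),
                start_epoch=int(s),
                length_epochs=int(e - s),
                duration=float((e - s) * minutes_per_epoch),
            )
        )
    return bouts


def continuity_tail_fractions(
    transitions: list[Transition], low: float = 0.05, high: float = 0.95
) -> tuple[float, float]:
    """Fractions of transitions with continuity < ``low`` and > ``high``."""
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    values = [tr.continuity for tr in transitions]
    if not values or any(v is None for v in values):
        raise ValueError("tail fractions need a non-empty annotated transition list")
    arr = np.asarray(values, dtype=float)
    return (
        float(np.mean(arr < low)),
        float(np.mean(arr > high)),
    )
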