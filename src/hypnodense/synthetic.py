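"""Synthetic cohorts of paired manual/automated stagings and hypnodensities.

A first-order Markov chain over the 4-stage set produces geometric bout
lengths; per-epoch probability vectors are Dirichlet draws around the true
stage whose spread (ambiguity), cross-transition blending (continuity),
REM-probability leakage towards N1+N2 and W, and manual-scorer disagreement
rate are all tunable per group.  Purpose: directional and property testing
of the downstream analysis with no data download — not physiological
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    FOUR_STAGE,
    Cohort,
    Hypnogram,
    Hypnodensity,
    StageSet,
    SubjectRecord,
    hypnogram_from_hypnodensity,
)

__all__ = [
    "GroupProfile",
    "rbd_like",
    "osa_like",
    "load_profile",
    "simulate_hypnogram",
    "simulate_hypnodensity",
    "simulate_manual",
    "simulate_cohort",
    "DEFAULT_METHOD_SCALES",
]

#: Constant additive Dirichlet floor: alpha = concentration * (1 - floor) *
#: one-hot + floor.  Every stage keeps a non-zero expected probability
#: (needed for ambiguity > 0.79 events at low concentration), yet the mean
#: sharpens towards the one-hot as concentration grows, so mean ambiguity is
#: strictly decreasing in concentration and vanishes in the limit.
UNIFORM_FLOOR = 0.05

#: Substream codes for the counter-based seeding scheme: the generator for
#: component ``c`` of subject ``j`` under global seed ``s`` is
#: ``default_rng([s, j, c])``, so cohorts are identical across runs and
#: platforms for a fixed seed.
_COMP_TRUTH = 0
_COMP_MANUAL = 1
_COMP_METHOD_BASE = 2

#: Automated-method concentration multipliers: the "exg"-like method keeps
#: the profile concentration (sharper, better agreement), the "hrvm"-like
#: method is a lower-information classifier.
DEFAULT_METHOD_SCALES: dict[str, float] = {"exg": 1.0, "hrvm": 0.25}


@dataclass
class GroupProfile:
    """Tunable generative parameters for one cohort group.

    ``transition_matrix`` rows are per-epoch Markov transition
    probabilities; the diagonal sets the expected bout length
    (geometric, mean 1/(1-diag)).  ``concentration`` scales the Dirichlet
    around the true stage (higher = lower ambiguity).  ``crossfade_epochs``
    linearly blends probability vectors across stage boundaries (longer =
    higher transition continuity).  ``rem_leak`` moves that fraction of each
    REM epoch's REM probability to N1+N2 and W (split 2:1), emulating
    RSWA-driven REM confusion.  ``manual_noise`` is the per-epoch
    probability that the simulated manual scorer deviates from the truth.
    """

    name: str
    transition_matrix: np.ndarray
    concentration: float = 10.0
    crossfade_epochs: int = 0
    rem_leak: float = 0.0
    manual_noise: float = 0.05
    stage_set: StageSet = field(default=FOUR_STAGE)

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.stage_set)
        if self.transition_matrix.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition probabilities must be non-negative")
        rowsums = self.transition_matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"transition matrix rows must sum to 1, got {rowsums}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.crossfade_epochs < 0:
            raise ValueError("crossfade_epochs must be >= 0")
        if not (0.0 <= self.rem_leak < 1.0):
            raise ValueError("rem_leak must lie in [0, 1)")
        if not (0.0 <= self.manual_noise < 1.0):
            raise ValueError("manual_noise must lie in [0, 1)")

    def replace(self, **kwargs) -> "GroupProfile":
        data = {
            "name": self.name,
            "transition_matrix": self.transition_matrix.copy(),
            "concentration": self.concentration,
            "crossfade_epochs": self.crossfade_epochs,
            "rem_leak": self.rem_leak,
            "manual_noise": self.manual_noise,
            "stage_set": self.stage_set,
        }
        data.update(kwargs)
        return GroupProfile(**data)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "transition_matrix": self.transition_matrix.tolist(),
            "concentration": self.concentration,
            "crossfade_epochs": self.crossfade_epochs,
            "rem_leak": self.rem_leak,
            "manual_noise": self.manual_noise,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroupProfile":
        return cls(
            name=data["name"],
            transition_matrix=np.asarray(data["transition_matrix"], dtype=float),
            concentration=float(data.get("concentration", 10.0)),
            crossfade_epochs=int(data.get("crossfade_epochs", 0)),
            rem_leak=float(data.get("rem_leak", 0.0)),
            manual_noise=float(data.get("manual_noise", 0.05)),
        )


def rbd_like() -> GroupProfile:
    """Preset with leaky, blended REM: elevated REM ambiguity, REM->N1+N2
    confusion, smoother stage transitions, noisier agreement."""
    return GroupProfile(
        name="rbd_like",
        transition_matrix=np.array(
            [
                [0.92, 0.070, 0.005, 0.005],
                [0.03, 0.910, 0.040, 0.020],
                [0.005, 0.065, 0.930, 0.000],
                [0.02, 0.040, 0.000, 0.940],
            ]
        ),
        concentration=8.0,
        crossfade_epochs=2,
        rem_leak=0.35,
        manual_noise=0.10,
    )


def osa_like() -> GroupProfile:
    """Preset with fragmented but crisply classified sleep: abrupt
    transitions, little REM leakage."""
    return GroupProfile(
        name="osa_like",
        transition_matrix=np.array(
            [
                [0.900, 0.090, 0.005, 0.005],
                [0.040, 0.900, 0.040, 0.020],
                [0.010, 0.060, 0.930, 0.000],
                [0.025, 0.045, 0.000, 0.930],
            ]
        ),
        concentration=14.0,
        crossfade_epochs=0,
        rem_leak=0.05,
        manual_noise=0.06,
    )


_PRESETS = {"rbd_like": rbd_like, "osa_like": osa_like}
_PRESET_DIR = Path(__file__).parent / "presets"


def load_profile(name_or_path: str | Path) -> GroupProfile:
    """Load a profile by preset name (``rbd_like``/``osa_like``) or YAML path."""
    key = str(name_or_path)
    if key in _PRESETS:
        return _PRESETS[key]()
    path = Path(name_or_path)
    if not path.exists():
        builtin = _PRESET_DIR / f"{key}.yaml"
        if builtin.exists():
            path = builtin
        else:
            raise FileNotFoundError(f"no profile preset or file named {key!r}")
    with open(path) as fh:
        return GroupProfile.from_dict(yaml.safe_load(fh))


def _rng(seed: int, subject_index: int, component: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(subject_index), int(component)])


def simulate_hypnogram(
    profile: GroupProfile,
    n_epochs: int,
    seed: int,
    subject_index: int = 0,
    epoch_duration: float = 30.0,
) -> Hypnogram:
    """First-order Markov stage chain started in W; reproducible per seed."""
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    rng = _rng(seed, subject_index, _COMP_TRUTH)
    k = len(profile.stage_set)
    codes = np.empty(n_epochs, dtype=np.intp)
    codes[0] = profile.stage_set.index("W")
    cum = np.cumsum(profile.transition_matrix, axis=1)
    draws = rng.random(n_epochs - 1)
    for t in range(1, n_epochs):
        codes[t] = np.searchsorted(cum[codes[t - 1]], draws[t - 1], side="right")
        if codes[t] >= k:  # guard float edge at cum ~ 1.0
            codes[t] = k - 1
    return Hypnogram(codes, profile.stage_set, epoch_duration)


def _alphas(profile: GroupProfile) -> np.ndarray:
    """Per-stage Dirichlet parameter rows (one row per true stage)."""
    k = len(profile.stage_set)
    return (
        profile.concentration * (1.0 - UNIFORM_FLOOR) * np.eye(k)
        + UNIFORM_FLOOR
    )


def _target_means(profile: GroupProfile) -> np.ndarray:
    """Per-stage Dirichlet mean vectors, with rem_leak applied to the REM
    row (2/3 to N1+N2, 1/3 to W)."""
    alphas = _alphas(profile)
    means = alphas / alphas.sum(axis=1, keepdims=True)
    if profile.rem_leak > 0:
        r = profile.stage_set.index("R")
        means[r] = _apply_rem_leak_row(means[r], profile)
    return means


def _apply_rem_leak_row(p: np.ndarray, profile: GroupProfile) -> np.ndarray:
    r = profile.stage_set.index("R")
    n12 = profile.stage_set.index("N1+N2")
    w = profile.stage_set.index("W")
    moved = profile.rem_leak * p[r]
    out = p.copy()
    out[r] -= moved
    out[n12] += moved * (2.0 / 3.0)
    out[w] += moved * (1.0 / 3.0)
    return out


def simulate_hypnodensity(
    truth: Hypnogram,
    profile: GroupProfile,
    seed: int,
    subject_index: int = 0,
    component: int = _COMP_METHOD_BASE,
) -> Hypnodensity:
    """Dirichlet probability vectors around the true stage.

    Per epoch t with true stage s: draw p ~ Dirichlet(alpha_s) with
    alpha_s = concentration * (1 - eps) * one-hot(s) + eps; for REM epochs
    move ``rem_leak`` of the REM coordinate to N1+N2 and W (2:1).  Within
    ``crossfade_epochs`` of each stage boundary the draw is replaced by the
    linear blend of the flanking stages' mean target distributions, so the
    per-transition distributional jump shrinks as the window grows.
    """
    if profile.stage_set != truth.stage_set:
        raise ValueError("profile and truth use different stage sets")
    rng = _rng(seed, subject_index, component)
    k = len(truth.stage_set)
    codes = truth.codes
    n = len(codes)
    alphas = _alphas(profile)[codes]
    probs = np.empty((n, k), dtype=float)
    for t in range(n):
        probs[t] = rng.dirichlet(alphas[t])
    # RSWA-like REM leakage, applied to the sampled vectors
    if profile.rem_leak > 0:
        rem_code = truth.stage_set.index("R")
        rem_rows = np.flatnonzero(codes == rem_code)
        for t in rem_rows:
            probs[t] = _apply_rem_leak_row(probs[t], profile)
    # cross-fade: deterministic linear blend of flanking target means
    c = profile.crossfade_epochs
    if c > 0:
        target = _target_means(profile)
        boundaries = np.flatnonzero(codes[1:] != codes[:-1])
        run_start = np.zeros(n, dtype=np.intp)
        run_end = np.full(n, n - 1, dtype=np.intp)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries, [n - 1]))
        for s, e in zip(starts, ends):
            run_start[s : e + 1] = s
            run_end[s : e + 1] = e
        for t in boundaries:
            m_from = target[codes[t]]
            m_to = target[codes[t + 1]]
            lo = max(t - c + 1, run_start[t])
            hi = min(t + c, run_end[t + 1])
            for u in range(lo, hi + 1):
                w_to = (u - (t - c + 1) + 1) / (2 * c + 1)
                probs[u] = (1.0 - w_to) * m_from + w_to * m_to
    probs /= probs.sum(axis=1, keepdims=True)
    return Hypnodensity(probs, truth.stage_set, truth.epoch_duration)


def simulate_manual(
    truth: Hypnogram,
    profile: GroupProfile,
    seed: int,
    subject_index: int = 0,
) -> Hypnogram:
    """Simulated single human scorer: with probability ``manual_noise`` an
    epoch's true stage is replaced by a uniform draw over the other stages."""
    rng = _rng(seed, subject_index, _COMP_MANUAL)
    k = len(truth.stage_set)
    codes = truth.codes.copy()
    flip = rng.random(len(codes)) < profile.manual_noise
    if flip.any():
        # uniform over the k-1 other stages via an offset in 1..k-1
        offsets = rng.integers(1, k, size=int(flip.sum()))
        codes[flip] = (codes[flip] + offsets) % k
    return Hypnogram(codes, truth.stage_set, truth.epoch_duration)


def simulate_cohort(
    profiles: dict[str, GroupProfile],
    n_subjects: int,
    n_epochs: int,
    seed: int,
    method_scales: dict[str, float] | None = None,
    epoch_duration: float = 30.0,
    name: str = "synthetic",
) -> Cohort:
    """Simulate a multi-group cohort of paired stagings.

    Per subject: a truth chain, a "manual" hypnogram, and one staging per
    automated method (default an "exg"-like sharp classifier and an
    "hrvm"-like diffuse one, via concentration scaling), each carrying a
    hypnodensity plus its argmax hypnogram.  Deterministic per
    (seed, subject index, component).
    """
    if method_scales is None:
        method_scales = dict(DEFAULT_METHOD_SCALES)
    records = []
    subject_index = 0
    for group, profile in profiles.items():
        for j in range(n_subjects):
            truth = simulate_hypnogram(
                profile, n_epochs, seed, subject_index, epoch_duration
            )
            manual = simulate_manual(truth, profile, seed, subject_index)
            stagings: dict[str, tuple[Hypnogram, Hypnodensity | None]] = {
                "manual": (manual, None)
            }
            for mi, (method, scale) in enumerate(sorted(method_scales.items())):
                mprofile = profile.replace(
                    concentration=profile.concentration * scale
                )
                hd = simulate_hypnodensity(
                    truth, mprofile, seed, subject_index,
                    component=_COMP_METHOD_BASE + mi,
                )
                stagings[method] = (hypnogram_from_hypnodensity(hd), hd)
            records.append(
                SubjectRecord(
                    subject_id=f"{group}_{j:03d}",
                    group=group,
                    stagings=stagings,
                )
            )
            subject_index += 1
    return Cohort(records=records, name=name)
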