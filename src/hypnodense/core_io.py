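"""Domain types and file I/O for hypnograms, hypnodensities and cohorts.

Stage alphabets are declared :class:`StageSet` instances; all containers are
validated against a declared set, and mixing sets in one container is an
error.  Files are plain text (one label per line), CSV, and a JSON/YAML
cohort manifest.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "StageSet",
    "Stage",
    "FIVE_STAGE",
    "FOUR_STAGE",
    "DEFAULT_ALIASES",
    "Hypnogram",
    "Hypnodensity",
    "SubjectRecord",
    "Cohort",
    "read_hypnogram",
    "read_hypnodensity",
    "write_hypnogram",
    "write_hypnodensity",
    "collapse_to_4stage",
    "hypnogram_from_hypnodensity",
    "write_report_table",
    "read_report_table",
    "load_cohort",
    "save_cohort",
]

#: Renormalize hypnodensity rows whose sum deviates by at most this much.
ROW_SUM_STRICT_TOL = 1e-6
#: Reject rows whose sum deviates by more than this (CSV rounding vs corruption).
ROW_SUM_REJECT_TOL = 1e-3


class StageSet:
    """An ordered alphabet of sleep-stage labels.

    The ordinal position of a label doubles as the argmax tie-break
    priority: the earlier label wins.
    """

    def __init__(self, labels: Sequence[str], name: str = ""):
        if len(labels) < 2:
            raise ValueError("a stage set needs at least two stages")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate stage labels: {labels}")
        self.labels: tuple[str, ...] = tuple(labels)
        self.name = name or "/".join(labels)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StageSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"StageSet({list(self.labels)!r})"

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"unknown stage label {label!r} for stage set {self.name}"
            ) from None

    def stage(self, label: str) -> "Stage":
        return Stage(label=label, index=self.index(label), stage_set=self)


@dataclass(frozen=True)
class Stage:
    """A stage label bound to its position in a declared :class:`StageSet`."""

    label: str
    index: int
    stage_set: StageSet

    def __post_init__(self):
        if self.stage_set.labels[self.index] != self.label:
            raise ValueError(
                f"stage {self.label!r} does not sit at index {self.index} "
                f"of {self.stage_set}"
            )

    def __str__(self) -> str:
        return self.label


FIVE_STAGE = StageSet(("W", "N1", "N2", "N3", "R"), name="5-stage")
FOUR_STAGE = StageSet(("W", "N1+N2", "N3", "R"), name="4-stage")

#: Built-in label aliases; extensible via the ``aliases`` reader argument.
DEFAULT_ALIASES: dict[str, str] = {
    "WAKE": "W",
    "REM": "R",
    "N12": "N1+N2",
    "N1N2": "N1+N2",
}


def _resolve_label(raw: str, stage_set: StageSet, aliases: Mapping[str, str]) -> str:
    label = raw.strip()
    if label in stage_set:
        return label
    upper = label.upper()
    if upper in stage_set:
        return upper
    if upper in aliases and aliases[upper] in stage_set:
        return aliases[upper]
    raise KeyError(label)


@dataclass
class Hypnogram:
    """A sequence of stage codes, one per fixed-duration epoch.

    Stages are stored as integer codes into ``stage_set``; ``labels`` and
    ``stages`` expose the symbolic view.
    """

    codes: np.ndarray
    stage_set: StageSet
    epoch_duration: float = 30.0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.codes.ndim != 1 or len(self.codes) < 1:
            raise ValueError("hypnogram must be a non-empty 1-D sequence")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        k = len(self.stage_set)
        if self.codes.min() < 0 or self.codes.max() >= k:
            raise ValueError(
                f"stage codes out of range for {self.stage_set} (K={k})"
            )

    @classmethod
    def from_labels(
        cls,
        labels: Iterable[str],
        stage_set: StageSet,
        epoch_duration: float = 30.0,
    ) -> "Hypnogram":
        codes = np.array([stage_set.index(lab) for lab in labels], dtype=np.intp)
        return cls(codes=codes, stage_set=stage_set, epoch_duration=epoch_duration)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def labels(self) -> list[str]:
        return [self.stage_set.labels[c] for c in self.codes]

    @property
    def stages(self) -> list[Stage]:
        return [
            Stage(self.stage_set.labels[c], int(c), self.stage_set)
            for c in self.codes
        ]

    def truncated(self, n: int) -> "Hypnogram":
        return Hypnogram(self.codes[:n], self.stage_set, self.epoch_duration)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.stage_set == other.stage_set
            and self.epoch_duration == other.epoch_duration
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class Hypnodensity:
    """Per-epoch probability vectors over a stage set (rows sum to 1)."""

    probs: np.ndarray
    stage_set: StageSet
    epoch_duration: float = 30.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] < 1:
            raise ValueError("hypnodensity must be a non-empty T x K matrix")
        if self.probs.shape[1] != len(self.stage_set):
            raise ValueError(
                f"expected {len(self.stage_set)} columns for {self.stage_set}, "
                f"got {self.probs.shape[1]}"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        dev = np.abs(sums - 1.0)
        bad = dev > ROW_SUM_STRICT_TOL
        if np.any(bad):
            rows = np.flatnonzero(bad)
            raise ValueError(
                f"rows {rows[:5].tolist()} sum to {sums[rows[:5]].tolist()} "
                f"(deviation > {ROW_SUM_STRICT_TOL})"
            )
        # exact renormalization of sub-tolerance float drift
        self.probs = self.probs / sums[:, None]

    def __len__(self) -> int:
        return self.probs.shape[0]

    def truncated(self, n: int) -> "Hypnodensity":
        return Hypnodensity(self.probs[:n], self.stage_set, self.epoch_duration)


@dataclass
class SubjectRecord:
    """Per-subject stagings keyed by method name, with group and metadata.

    Each staging is a ``(Hypnogram, Hypnodensity | None)`` pair; the manual
    method carries no hypnodensity (single human scorer).
    """

    subject_id: str
    group: str
    stagings: dict[str, tuple[Hypnogram, Hypnodensity | None]]
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.stagings:
            raise ValueError(f"subject {self.subject_id}: no stagings")
        durations = {hg.epoch_duration for hg, _ in self.stagings.values()}
        if len(durations) != 1:
            raise ValueError(
                f"subject {self.subject_id}: mixed epoch durations {durations}"
            )
        for method, (hg, hd) in self.stagings.items():
            if hd is not None and len(hd) != len(hg):
                raise ValueError(
                    f"subject {self.subject_id}, method {method}: hypnogram "
                    f"length {len(hg)} != hypnodensity length {len(hd)}"
                )

    @property
    def methods(self) -> list[str]:
        return list(self.stagings)

    def hypnogram(self, method: str) -> Hypnogram:
        return self.stagings[method][0]

    def hypnodensity(self, method: str) -> Hypnodensity | None:
        return self.stagings[method][1]


@dataclass
class Cohort:
    records: list[SubjectRecord]
    name: str = "cohort"

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == group]


# ---------------------------------------------------------------------------
# readers / writers


def read_hypnogram(
    path: str | Path,
    stage_set: StageSet,
    epoch_duration: float = 30.0,
    aliases: Mapping[str, str] | None = None,
) -> Hypnogram:
    """Read a hypnogram from plain text (one label/line) or CSV ``epoch,stage``.

    CSV epoch indices must be 1-based and contiguous.  Unknown labels are
    reported with their line numbers.
    """
    path = Path(path)
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.upper(): v for k, v in aliases.items()})

    with open(path, newline="") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"{path}: empty hypnogram file")

    is_csv = "," in lines[0]
    labels: list[str] = []
    errors: list[str] = []
    if is_csv:
        header = [c.strip().lower() for c in lines[0].split(",")]
        if header[:2] != ["epoch", "stage"]:
            raise ValueError(f"{path}: expected header 'epoch,stage', got {lines[0]!r}")
        expected = 1
        for lineno, ln in enumerate(lines[1:], start=2):
            cells = [c.strip() for c in ln.split(",")]
            if len(cells) < 2:
                errors.append(f"line {lineno}: malformed row {ln!r}")
                continue
            idx = int(cells[0])
            if idx != expected:
                raise ValueError(
                    f"{path}: non-contiguous epoch index {idx} at line {lineno} "
                    f"(expected {expected})"
                )
            expected += 1
            try:
                labels.append(_resolve_label(cells[1], stage_set, alias_map))
            except KeyError:
                errors.append(f"line {lineno}: unknown label {cells[1]!r}")
    else:
        for lineno, ln in enumerate(lines, start=1):
            try:
                labels.append(_resolve_label(ln, stage_set, alias_map))
            except KeyError:
                errors.append(f"line {lineno}: unknown label {ln!r}")

    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return Hypnogram.from_labels(labels, stage_set, epoch_duration)


def read_hypnodensity(
    path: str | Path,
    stage_set: StageSet,
    epoch_duration: float = 30.0,
) -> Hypnodensity:
    """Read a hypnodensity CSV with header ``epoch,<stage columns>``.

    Row sums off by at most ``ROW_SUM_STRICT_TOL`` are silently
    renormalized; deviations up to ``ROW_SUM_REJECT_TOL`` are renormalized
    with a log entry (CSV rounding); anything larger is an error.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty hypnodensity file") from None
        header = [c.strip() for c in header]
        if header[0].lower() != "epoch":
            raise ValueError(f"{path}: first column must be 'epoch'")
        cols = header[1:]
        missing = [lab for lab in stage_set.labels if lab not in cols]
        if missing:
            raise ValueError(f"{path}: missing stage columns {missing}")
        order = [cols.index(lab) for lab in stage_set.labels]
        rows: list[list[float]] = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue
            vals = [float(cells[1 + j]) for j in order]
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}: negative probability at line {lineno}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    probs = np.array(rows, dtype=float)
    sums = probs.sum(axis=1)
    dev = np.abs(sums - 1.0)
    if np.any(dev > ROW_SUM_REJECT_TOL):
        bad = np.flatnonzero(dev > ROW_SUM_REJECT_TOL)
        raise ValueError(
            f"{path}: row sums deviate beyond {ROW_SUM_REJECT_TOL} at data rows "
            f"{(bad + 1).tolist()[:5]} (sums {sums[bad][:5].tolist()})"
        )
    soft = np.flatnonzero(dev > ROW_SUM_STRICT_TOL)
    if soft.size:
        logger.info(
            "%s: renormalized %d rows with sum deviation in (%g, %g]",
            path, soft.size, ROW_SUM_STRICT_TOL, ROW_SUM_REJECT_TOL,
        )
    probs = probs / sums[:, None]
    return Hypnodensity(probs, stage_set, epoch_duration)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write as CSV ``epoch,stage`` (1-based) or plain text, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "stage"])
            for i, lab in enumerate(h.labels, start=1):
                w.writerow([i, lab])
    else:
        path.write_text("\n".join(h.labels) + "\n")


def write_hypnodensity(hd: Hypnodensity, path: str | Path, digits: int = 8) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", *hd.stage_set.labels])
        for i, row in enumerate(hd.probs, start=1):
            w.writerow([i, *(format(v, f".{digits}f") for v in row)])


# ---------------------------------------------------------------------------
# stage-set operations

_FIVE_TO_FOUR = {"W": "W", "N1": "N1+N2", "N2": "N1+N2", "N3": "N3", "R": "R"}


def collapse_to_4stage(obj: Hypnogram | Hypnodensity) -> Hypnogram | Hypnodensity:
    """Collapse a 5-stage container to 4 stages by merging N1 and N2.

    For hypnograms both labels map to ``N1+N2``; for hypnodensities the
    ``N1+N2`` column is the elementwise sum of the N1 and N2 columns, so row
    sums are preserved.
    """
    if obj.stage_set == FOUR_STAGE:
        raise ValueError("input is already 4-stage")
    if obj.stage_set != FIVE_STAGE:
        raise ValueError(f"collapse expects the 5-stage set, got {obj.stage_set}")
    if isinstance(obj, Hypnogram):
        mapping = np.array(
            [FOUR_STAGE.index(_FIVE_TO_FOUR[lab]) for lab in FIVE_STAGE.labels],
            dtype=np.intp,
        )
        return Hypnogram(mapping[obj.codes], FOUR_STAGE, obj.epoch_duration)
    probs = np.empty((len(obj), 4), dtype=float)
    p = obj.probs
    probs[:, FOUR_STAGE.index("W")] = p[:, FIVE_STAGE.index("W")]
    probs[:, FOUR_STAGE.index("N1+N2")] = (
        p[:, FIVE_STAGE.index("N1")] + p[:, FIVE_STAGE.index("N2")]
    )
    probs[:, FOUR_STAGE.index("N3")] = p[:, FIVE_STAGE.index("N3")]
    probs[:, FOUR_STAGE.index("R")] = p[:, FIVE_STAGE.index("R")]
    return Hypnodensity(probs, FOUR_STAGE, obj.epoch_duration)


def hypnogram_from_hypnodensity(hd: Hypnodensity) -> Hypnogram:
    """Per-epoch argmax staging; ties go to the earlier stage-set index.

    With the 4-stage set this is the fixed priority W > N1+N2 > N3 > R.
    """
    codes = np.argmax(hd.probs, axis=1)  # first max wins = priority order
    return Hypnogram(codes, hd.stage_set, hd.epoch_duration)


# ---------------------------------------------------------------------------
# report tables


def _flatten(record: Mapping, prefix: str = "") -> dict:
    out: dict = {}
    for key, val in record.items():
        name = f"{prefix}{key}"
        if isinstance(val, Mapping):
            out.update(_flatten(val, prefix=f"{name}."))
        else:
            out[name] = val
    return out


def write_report_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write tabular records as CSV (default) or JSON, by file extension.

    Nested mappings are flattened with dotted keys; column order is
    first-seen and therefore deterministic for a fixed row sequence.
    """
    path = Path(path)
    flat = [_flatten(r) for r in rows]
    columns: list[str] = []
    for r in flat:
        for k in r:
            if k not in columns:
                columns.append(k)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(flat, fh, indent=2, default=str)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=columns)
        w.writeheader()
        for r in flat:
            w.writerow(r)


def read_report_table(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)
    with open(path, newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh)]


# ---------------------------------------------------------------------------
# cohort manifest

_STAGE_SETS = {"4": FOUR_STAGE, "5": FIVE_STAGE, 4: FOUR_STAGE, 5: FIVE_STAGE}


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a JSON/YAML manifest.

    The manifest lists ``subjects`` with ``subject_id``, ``group``, optional
    ``metadata`` and per-method file paths (relative to the manifest).
    Stagings of unequal length within a subject are truncated to the common
    minimum, with a log entry.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        if manifest_path.suffix.lower() in (".yaml", ".yml"):
            spec = yaml.safe_load(fh)
        else:
            spec = json.load(fh)
    base = manifest_path.parent
    stage_set = _STAGE_SETS[spec.get("stage_set", 4)]
    epoch_duration = float(spec.get("epoch_duration", 30.0))
    records = []
    for subj in spec["subjects"]:
        stagings: dict[str, tuple[Hypnogram, Hypnodensity | None]] = {}
        for method, files in subj["stagings"].items():
            hd = None
            if "hypnodensity" in files:
                hd = read_hypnodensity(base / files["hypnodensity"], stage_set,
                                       epoch_duration)
            if "hypnogram" in files:
                hg = read_hypnogram(base / files["hypnogram"], stage_set,
                                    epoch_duration)
            elif hd is not None:
                hg = hypnogram_from_hypnodensity(hd)
            else:
                raise ValueError(
                    f"subject {subj['subject_id']}, method {method}: "
                    "neither hypnogram nor hypnodensity given"
                )
            stagings[method] = (hg, hd)
        n_min = min(
            min(len(hg), len(hd) if hd is not None else len(hg))
            for hg, hd in stagings.values()
        )
        for method, (hg, hd) in list(stagings.items()):
            if len(hg) > n_min or (hd is not None and len(hd) > n_min):
                logger.info(
                    "subject %s: truncating method %s to %d epochs",
                    subj["subject_id"], method, n_min,
                )
                stagings[method] = (
                    hg.truncated(n_min),
                    hd.truncated(n_min) if hd is not None else None,
                )
        records.append(
            SubjectRecord(
                subject_id=str(subj["subject_id"]),
                group=str(subj["group"]),
                stagings=stagings,
                metadata=dict(subj.get("metadata", {})),
            )
        )
    return Cohort(records=records, name=str(spec.get("name", "cohort")))


def save_cohort(cohort: Cohort, out_dir: str | Path, fmt: str = "json") -> Path:
    """Write a cohort directory: per-subject CSVs plus a manifest.

    Returns the manifest path.  ``fmt`` selects the manifest flavour
    (``json`` or ``yaml``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    stage_set = None
    epoch_duration = None
    for rec in cohort.records:
        entry: dict = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "stagings": {},
        }
        if rec.metadata:
            entry["metadata"] = rec.metadata
        for method, (hg, hd) in rec.stagings.items():
            stage_set = hg.stage_set
            epoch_duration = hg.epoch_duration
            files: dict[str, str] = {}
            hg_name = f"{rec.subject_id}_{method}_hypnogram.csv"
            write_hypnogram(hg, out_dir / hg_name)
            files["hypnogram"] = hg_name
            if hd is not None:
                hd_name = f"{rec.subject_id}_{method}_hypnodensity.csv"
                write_hypnodensity(hd, out_dir / hd_name)
                files["hypnodensity"] = hd_name
            entry["stagings"][method] = files
        subjects.append(entry)
    manifest = {
        "name": cohort.name,
        "stage_set": len(stage_set) if stage_set is not None else 4,
        "epoch_duration": epoch_duration,
        "subjects": subjects,
    }
    if fmt == "yaml":
        manifest_path = out_dir / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    else:
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
    return manifest_path
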