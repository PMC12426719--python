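"""End-to-end cohort analysis: agreement, bouts, ambiguity/continuity,
with every queued p-value adjusted in one joint Benjamini-Hochberg family.

Each stage returns tidy tables plus a list of pending :class:`TestResult`;
``run_all`` pools the tests, adjusts them at the configured FDR and writes
``agreement.csv``, ``bouts.csv``, ``ambiguity.csv``, ``continuity.csv``,
``tests.csv`` and ``run.log``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics
from .agreement import AgreementResult, agreement as compute_agreement
from .core_io import Cohort, write_report_table
from .stats import ComparisonReport, TestResult, friedman, mann_whitney, welch_t

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "StageOutput",
    "run_agreement_stage",
    "run_bout_stage",
    "run_hypnodensity_stage",
    "run_all",
]


@dataclass
class AnalysisConfig:
    methods: list[str] | None = None  # automated methods; None = autodetect
    reference_method: str = "manual"
    fdr: float = 0.10
    continuity_tails: tuple[float, float] = (0.05, 0.95)
    pooled_kappa: bool = False  # pooled-epoch kappa instead of per-subject
    output_dir: Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        low, high = self.continuity_tails
        if not (0 <= low < high <= 1):
            raise ValueError("continuity_tails must satisfy 0 <= low < high <= 1")


@dataclass
class StageOutput:
    tables: dict[str, list[dict]] = field(default_factory=dict)
    tests: list[TestResult] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _automated_methods(cohort: Cohort, config: AnalysisConfig) -> list[str]:
    if config.methods is not None:
        return list(config.methods)
    methods: set[str] = set()
    for rec in cohort.records:
        methods.update(m for m in rec.methods if m != config.reference_method)
    return sorted(methods)


def _check_reference(cohort: Cohort, config: AnalysisConfig) -> None:
    for rec in cohort.records:
        if config.reference_method not in rec.stagings:
            raise ValueError(
                f"subject {rec.subject_id} lacks reference method "
                f"{config.reference_method!r}"
            )


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def run_agreement_stage(cohort: Cohort, config: AnalysisConfig) -> StageOutput:
    """Per-subject kappa and per-class scores vs the reference staging,
    plus group-difference tests (t for kappa, U for per-class F1) and a
    between-method kappa t-test per group."""
    _check_reference(cohort, config)
    methods = _automated_methods(cohort, config)
    groups = cohort.groups()
    out = StageOutput()
    rows: list[dict] = []
    # subject -> method -> AgreementResult
    per_subject: dict[str, dict[str, AgreementResult]] = {}
    stage_labels: list[str] = []
    for rec in cohort.records:
        ref = rec.hypnogram(config.reference_method)
        per_subject[rec.subject_id] = {}
        for method in methods:
            if method not in rec.stagings:
                logger.info("subject %s: method %s absent, skipped",
                            rec.subject_id, method)
                continue
            res = compute_agreement(ref, rec.hypnogram(method))
            per_subject[rec.subject_id][method] = res
            stage_labels = list(res.per_class)
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "method": method,
                "kappa": res.kappa,
                "n_epochs": res.n_epochs,
            }
            for stage, scores in res.per_class.items():
                for metric, value in scores.items():
                    row[f"{stage}.{metric}"] = value
            rows.append(row)
    out.tables["agreement"] = rows
    out.counts["agreement_rows"] = len(rows)

    def kappas(group: str, method: str) -> np.ndarray:
        return np.array(
            [
                per_subject[r.subject_id][method].kappa
                for r in cohort.by_group(group)
                if method in per_subject[r.subject_id]
            ]
        )

    def f1s(group: str, method: str, stage: str) -> np.ndarray:
        vals = np.array(
            [
                per_subject[r.subject_id][method].per_class[stage]["f1"]
                for r in cohort.by_group(group)
                if method in per_subject[r.subject_id]
            ]
        )
        return vals[~np.isnan(vals)]

    summary: list[dict] = []
    for method in methods:
        for group in groups:
            ks = kappas(group, method)
            if ks.size == 0:
                continue
            row = {
                "method": method,
                "group": group,
                "kappa_mean": float(np.mean(ks)),
                "kappa_sd": float(np.std(ks, ddof=1)) if ks.size > 1 else 0.0,
                "n_subjects": int(ks.size),
            }
            for stage in stage_labels:
                vals = f1s(group, method, stage)
                if vals.size:
                    med, iqr = _median_iqr(vals)
                    row[f"{stage}.f1_median"] = med
                    row[f"{stage}.f1_iqr"] = iqr
            summary.append(row)
    out.tables["agreement_summary"] = summary

    if len(groups) == 2:
        g1, g2 = groups
        for method in methods:
            k1, k2 = kappas(g1, method), kappas(g2, method)
            if k1.size >= 2 and k2.size >= 2:
                out.tests.append(
                    welch_t(k1, k2, label=f"kappa:{method}:{g1}-vs-{g2}")
                )
            for stage in stage_labels:
                v1, v2 = f1s(g1, method, stage), f1s(g2, method, stage)
                if v1.size and v2.size:
                    out.tests.append(
                        mann_whitney(
                            v1, v2, label=f"f1:{method}:{stage}:{g1}-vs-{g2}"
                        )
                    )
    else:
        logger.info("agreement stage: %d groups, group tests skipped", len(groups))
    if len(methods) == 2:
        m1, m2 = methods
        for group in groups:
            k1, k2 = kappas(group, m1), kappas(group, m2)
            if k1.size >= 2 and k2.size >= 2:
                out.tests.append(
                    welch_t(k1, k2, label=f"kappa:{group}:{m1}-vs-{m2}")
                )
    return out


def run_bout_stage(cohort: Cohort, config: AnalysisConfig) -> StageOutput:
    """Pooled bout-duration distributions per stage/method/group with group
    U tests within method and a Friedman-then-post-hoc-U method comparison."""
    _check_reference(cohort, config)
    methods = [config.reference_method] + _automated_methods(cohort, config)
    groups = cohort.groups()
    out = StageOutput()
    rows: list[dict] = []
    # (method, group, stage) -> pooled durations; (method, subject) -> durations
    pooled: dict[tuple[str, str, str], list[float]] = {}
    per_subject: dict[tuple[str, str], list[float]] = {}
    for rec in cohort.records:
        for method in methods:
            if method not in rec.stagings:
                continue
            for bout in metrics.extract_bouts(rec.hypnogram(method)):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "method": method,
                        "stage": bout.stage.label,
                        "start_epoch": bout.start_epoch,
                        "length_epochs": bout.length_epochs,
                        "duration_min": bout.duration,
                    }
                )
                pooled.setdefault((method, rec.group, bout.stage.label), []).append(
                    bout.duration
                )
                per_subject.setdefault((method, rec.subject_id), []).append(
                    bout.duration
                )
    out.tables["bouts"] = rows
    out.counts["bouts"] = len(rows)

    stage_labels = sorted({k[2] for k in pooled})
    summary = []
    for method in methods:
        for group in groups:
            for stage in stage_labels:
                durs = np.array(pooled.get((method, group, stage), []))
                if durs.size == 0:
                    continue
                med, iqr = _median_iqr(durs)
                summary.append(
                    {
                        "method": method,
                        "group": group,
                        "stage": stage,
                        "n_bouts": int(durs.size),
                        "duration_median": med,
                        "duration_iqr": iqr,
                    }
                )
    out.tables["bout_summary"] = summary

    if len(groups) == 2:
        g1, g2 = groups
        for method in methods:
            for stage in stage_labels:
                d1 = np.array(pooled.get((method, g1, stage), []))
                d2 = np.array(pooled.get((method, g2, stage), []))
                if d1.size and d2.size:
                    out.tests.append(
                        mann_whitney(
                            d1, d2, label=f"bout:{method}:{stage}:{g1}-vs-{g2}"
                        )
                    )
    # method comparison: Friedman on per-subject median bout duration
    # (subjects as matched blocks), then post-hoc pairwise U on pooled bouts
    if len(methods) >= 3:
        subjects = [
            r.subject_id
            for r in cohort.records
            if all((m, r.subject_id) in per_subject for m in methods)
        ]
        if len(subjects) >= 3:
            blocks = [
                np.array([float(np.median(per_subject[(m, s)])) for s in subjects])
                for m in methods
            ]
            out.tests.append(friedman(blocks, label="bout:methods:friedman"))
            for i in range(len(methods)):
                for j in range(i + 1, len(methods)):
                    di = np.concatenate(
                        [per_subject[(methods[i], s)] for s in subjects]
                    )
                    dj = np.concatenate(
                        [per_subject[(methods[j], s)] for s in subjects]
                    )
                    out.tests.append(
                        mann_whitney(
                            di, dj,
                            label=f"bout:{methods[i]}-vs-{methods[j]}:posthoc",
                        )
                    )
    return out


def run_hypnodensity_stage(cohort: Cohort, config: AnalysisConfig) -> StageOutput:
    """Ambiguity and transition-continuity tables and tests.

    Stage-specific ambiguity is grouped by each method's own staging, never
    the reference.  Continuity is evaluated at each method's own
    transitions; tail fractions use the configured thresholds.
    """
    _check_reference(cohort, config)
    methods = _automated_methods(cohort, config)
    groups = cohort.groups()
    low, high = config.continuity_tails
    out = StageOutput()
    amb_rows: list[dict] = []
    cont_rows: list[dict] = []
    # pools keyed (method, group[, stage])
    amb_pool: dict[tuple[str, str], list[np.ndarray]] = {}
    amb_stage_pool: dict[tuple[str, str, str], list[np.ndarray]] = {}
    cont_pool: dict[tuple[str, str], list[float]] = {}
    n_epochs_total = 0
    for rec in cohort.records:
        for method in methods:
            if method not in rec.stagings:
                continue
            hd = rec.hypnodensity(method)
            if hd is None:
                logger.info("subject %s: method %s has no hypnodensity, skipped",
                            rec.subject_id, method)
                continue
            staging = rec.hypnogram(method)
            series = metrics.ambiguity_series(hd, staging)
            n_epochs_total += len(series)
            labels = staging.labels
            for t, val in enumerate(series.values):
                amb_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "method": method,
                        "epoch": t,
                        "stage": labels[t],
                        "ambiguity": float(val),
                    }
                )
            amb_pool.setdefault((method, rec.group), []).append(series.values)
            for stage in staging.stage_set.labels:
                vals = series.for_stage(stage)
                if vals.size:
                    amb_stage_pool.setdefault(
                        (method, rec.group, stage), []
                    ).append(vals)
            transitions = metrics.annotate_transition_continuity(hd, staging)
            for tr in transitions:
                cont_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "method": method,
                        "boundary_index": tr.boundary_index,
                        "from_stage": tr.from_stage.label,
                        "to_stage": tr.to_stage.label,
                        "continuity": tr.continuity,
                    }
                )
                cont_pool.setdefault((method, rec.group), []).append(tr.continuity)
    out.tables["ambiguity"] = amb_rows
    out.tables["continuity"] = cont_rows
    out.counts["epochs"] = n_epochs_total
    out.counts["transitions"] = len(cont_rows)

    stage_labels = sorted({k[2] for k in amb_stage_pool})
    summary = []
    for method in methods:
        for group in groups:
            pools = amb_pool.get((method, group))
            if not pools:
                continue
            allvals = np.concatenate(pools)
            med, iqr = _median_iqr(allvals)
            row = {
                "method": method,
                "group": group,
                "n_epochs": int(allvals.size),
                "ambiguity_median": med,
                "ambiguity_iqr": iqr,
            }
            for stage in stage_labels:
                sp = amb_stage_pool.get((method, group, stage))
                if sp:
                    smed, siqr = _median_iqr(np.concatenate(sp))
                    row[f"{stage}.ambiguity_median"] = smed
                    row[f"{stage}.ambiguity_iqr"] = siqr
            conts = np.array(cont_pool.get((method, group), []))
            if conts.size:
                cmed, ciqr = _median_iqr(conts)
                row["continuity_median"] = cmed
                row["continuity_iqr"] = ciqr
                row["continuity_n"] = int(conts.size)
                row[f"continuity_frac_below_{low}"] = float(np.mean(conts < low))
                row[f"continuity_frac_above_{high}"] = float(np.mean(conts > high))
            summary.append(row)
    out.tables["hypnodensity_summary"] = summary

    if len(groups) == 2:
        g1, g2 = groups
        for method in methods:
            p1 = amb_pool.get((method, g1))
            p2 = amb_pool.get((method, g2))
            if p1 and p2:
                out.tests.append(
                    mann_whitney(
                        np.concatenate(p1), np.concatenate(p2),
                        label=f"ambiguity:{method}:overall:{g1}-vs-{g2}",
                    )
                )
            for stage in stage_labels:
                s1 = amb_stage_pool.get((method, g1, stage))
                s2 = amb_stage_pool.get((method, g2, stage))
                if s1 and s2:
                    out.tests.append(
                        mann_whitney(
                            np.concatenate(s1), np.concatenate(s2),
                            label=f"ambiguity:{method}:{stage}:{g1}-vs-{g2}",
                        )
                    )
            c1 = cont_pool.get((method, g1))
            c2 = cont_pool.get((method, g2))
            if c1 and c2:
                out.tests.append(
                    mann_whitney(
                        np.array(c1), np.array(c2),
                        label=f"continuity:{method}:{g1}-vs-{g2}",
                    )
                )
    if len(methods) == 2:
        m1, m2 = methods
        for group in groups:
            a1 = amb_pool.get((m1, group))
            a2 = amb_pool.get((m2, group))
            if a1 and a2:
                out.tests.append(
                    mann_whitney(
                        np.concatenate(a1), np.concatenate(a2),
                        label=f"ambiguity:{group}:{m1}-vs-{m2}",
                    )
                )
            c1 = cont_pool.get((m1, group))
            c2 = cont_pool.get((m2, group))
            if c1 and c2:
                out.tests.append(
                    mann_whitney(
                        np.array(c1), np.array(c2),
                        label=f"continuity:{group}:{m1}-vs-{m2}",
                    )
                )
    return out


def run_all(
    cohort: Cohort, config: AnalysisConfig
) -> tuple[ComparisonReport, dict[str, list[dict]]]:
    """Run every stage, adjust all p-values in one joint BH family, and
    write the output tables when ``config.output_dir`` is set."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    stages = [
        run_agreement_stage(cohort, config),
        run_bout_stage(cohort, config),
        run_hypnodensity_stage(cohort, config),
    ]
    report = ComparisonReport(fdr=config.fdr)
    tables: dict[str, list[dict]] = {}
    counts: dict[str, int] = {}
    for stage in stages:
        report.extend(stage.tests)
        tables.update(stage.tables)
        counts.update(stage.counts)
    report.adjust()
    tables["tests"] = report.to_rows()
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report_table(tables["agreement"], out_dir / "agreement.csv")
        write_report_table(tables["agreement_summary"],
                           out_dir / "agreement_summary.csv")
        write_report_table(tables["bouts"], out_dir / "bouts.csv")
        write_report_table(tables["bout_summary"], out_dir / "bout_summary.csv")
        write_report_table(tables["ambiguity"], out_dir / "ambiguity.csv")
        write_report_table(tables["continuity"], out_dir / "continuity.csv")
        write_report_table(tables["hypnodensity_summary"],
                           out_dir / "hypnodensity_summary.csv")
        write_report_table(tables["tests"], out_dir / "tests.csv")
        log_lines = [
            f"cohort: {cohort.name}",
            f"subjects: {len(cohort)}",
            f"groups: {', '.join(cohort.groups())}",
            f"fdr: {config.fdr}",
            f"tests: {report.m}",
        ] + [f"{k}: {v}" for k, v in sorted(counts.items())]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("analysed %s: %s; %d tests in one BH family at fdr=%g",
                cohort.name, counts, report.m, config.fdr)
    return report, tables
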