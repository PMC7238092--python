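"""End-to-end study evaluation: cohort CSV in, full table set out.

Reads lesion-level records (real-format or synthetic), applies both fusion
rules and both reading modes, and emits the study table set — per-mode
contingency tables and metric panels, paired McNemar and correlated-AUC
comparisons, reader agreement, and the management decision-change audit.

The cohort CSV schema (UTF-8, header row):

    lesion_id, pathology, plane_call_long, plane_call_trans,
    plane_call_obl_a, plane_call_obl_b, <reader>_without[, <reader>_combined]

with pathology in {malignant, benign}, plane calls in {M, B} (the two
oblique columns optional — cross-planes only), and reader columns holding
BI-RADS labels in {3, 4A, 4B, 4C, 5}.  When a ``<reader>_combined`` column
is absent, the combined-CAD category is derived mechanically by the
quadri-planes adjustment rule.

A packaged fixture ships the published study's printed summary tables
(512 lesions, 39.1% malignant) so the reported numbers are reproducible
without any download; see :func:`reproduce_study`.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    CROSS_PLANES,
    QUADRI_PLANES,
    BiradsCategory,
    BinaryVerdict,
    FusionRule,
    Plane,
    PlaneCallSet,
    adjust_category,
    cad_standalone_verdict,
    dichotomize_category,
)
from .diagnostics import (
    AgreementResult,
    ContingencyTable2x2,
    DiagnosticMetrics,
    PairedAgreementTable,
    TestResult,
    cohen_kappa,
    compare_auc_paired,
    compare_proportions,
    empirical_roc,
    estimate_paired_auc_correlation,
    mcnemar_test,
    metrics_from_table,
)

__all__ = [
    "CohortRecord",
    "StudyReport",
    "DecisionChangeAudit",
    "read_cohort_csv",
    "records_from_frame",
    "mode_verdicts",
    "evaluate_modes",
    "decision_change_audit",
    "write_report",
    "load_published_tables",
    "reproduce_study",
]

REPORT_SCHEMA_VERSION = "1"

_PLANE_FIELDS = {
    "plane_call_long": Plane.LONGITUDINAL,
    "plane_call_trans": Plane.TRANSVERSE,
    "plane_call_obl_a": Plane.OBLIQUE_A,
    "plane_call_obl_b": Plane.OBLIQUE_B,
}
_READER_COL = re.compile(r"^(?P<reader>[A-Za-z][A-Za-z0-9]*)_(?P<mode>without|combined)$")
_PATHOLOGY_VALUES = {"malignant", "benign"}


@dataclass(frozen=True)
class CohortRecord:
    """One lesion: pathology truth, CAD plane calls, reader categories."""

    lesion_id: str
    pathology: str  # 'malignant' | 'benign'
    plane_calls: PlaneCallSet  # 2 or 4 planes
    reader_categories: dict[str, dict[str, BiradsCategory]]  # reader -> mode -> cat

    @property
    def is_malignant(self) -> bool:
        return self.pathology == "malignant"


@dataclass(frozen=True)
class DecisionChangeAudit:
    """Lesions whose category crossed the 4A/4B management boundary.

    Upgrades (4A -> 4B) are correct iff the lesion is malignant; downgrades
    (4B -> 4A) are correct iff benign.  ``n_changed`` is the sum of the
    four cells.
    """

    upgrade_correct: int
    upgrade_incorrect: int
    downgrade_correct: int
    downgrade_incorrect: int

    @property
    def n_changed(self) -> int:
        return (
            self.upgrade_correct
            + self.upgrade_incorrect
            + self.downgrade_correct
            + self.downgrade_incorrect
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_changed": self.n_changed,
            "upgrade_correct": self.upgrade_correct,
            "upgrade_incorrect": self.upgrade_incorrect,
            "downgrade_correct": self.downgrade_correct,
            "downgrade_incorrect": self.downgrade_incorrect,
        }


@dataclass
class StudyReport:
    """Everything the evaluation computes, keyed by diagnostic mode."""

    n_lesions: int
    n_malignant: int
    n_benign: int
    contingency: dict[str, ContingencyTable2x2]
    metrics: dict[str, DiagnosticMetrics]
    roc_auc: dict[str, dict[str, float]]
    mcnemar: dict[str, TestResult]
    auc_comparisons: dict[str, TestResult]
    agreement: dict[str, AgreementResult]
    decision_changes: dict[str, DecisionChangeAudit]

    def to_dict(self) -> dict:
        def test_dict(t: TestResult) -> dict:
            return {
                "statistic": t.statistic,
                "p_value": t.p_value,
                "method": t.method,
            }

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_lesions": self.n_lesions,
            "n_malignant": self.n_malignant,
            "n_benign": self.n_benign,
            "contingency": {
                m: {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
                for m, t in self.contingency.items()
            },
            "metrics_percent": {
                m: v.as_percent_strings() for m, v in self.metrics.items()
            },
            "roc_auc": self.roc_auc,
            "mcnemar": {k: test_dict(v) for k, v in self.mcnemar.items()},
            "auc_comparisons": {
                k: test_dict(v) for k, v in self.auc_comparisons.items()
            },
            "agreement": {
                k: {
                    "kappa": v.kappa,
                    "kappa_rounded": v.kappa_rounded,
                    "observed_agreement": v.observed_agreement,
                    "chance_agreement": v.chance_agreement,
                    "band": v.band,
                }
                for k, v in self.agreement.items()
            },
            "decision_changes": {
                k: v.as_dict() for k, v in self.decision_changes.items()
            },
        }


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _parse_row(
    row: dict[str, str], row_no: int, plane_cols: list[str], reader_cols: list[str]
) -> CohortRecord:
    def fail(msg: str):
        raise ValueError(f"row {row_no}: {msg}")

    lesion_id = (row.get("lesion_id") or "").strip()
    if not lesion_id:
        fail("empty lesion_id")
    pathology = (row.get("pathology") or "").strip().lower()
    if pathology not in _PATHOLOGY_VALUES:
        fail(f"pathology {row['pathology']!r} not in {sorted(_PATHOLOGY_VALUES)}")
    try:
        calls = PlaneCallSet.from_codes(
            lesion_id, [row[c].strip() for c in plane_cols]
        )
    except ValueError as e:
        fail(f"field {plane_cols}: {e}")
    cats: dict[str, dict[str, BiradsCategory]] = {}
    for col in reader_cols:
        m = _READER_COL.match(col)
        try:
            cat = BiradsCategory.from_label(row[col])
        except ValueError as e:
            fail(f"field {col!r}: {e}")
        cats.setdefault(m["reader"], {})[m["mode"]] = cat
    return CohortRecord(lesion_id, pathology, calls, cats)


def read_cohort_csv(path) -> list[CohortRecord]:
    """Parse a cohort CSV with strict, row-numbered schema validation."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise ValueError(f"{path}: missing header row")
        for required in ("lesion_id", "pathology"):
            if required not in header:
                raise ValueError(f"{path}: missing required column {required!r}")
        plane_cols = [c for c in header if c in _PLANE_FIELDS]
        ordered = [c for c in _PLANE_FIELDS if c in plane_cols]
        if ordered[:2] != ["plane_call_long", "plane_call_trans"]:
            raise ValueError(
                f"{path}: plane columns must include plane_call_long and "
                "plane_call_trans"
            )
        reader_cols = [c for c in header if _READER_COL.match(c)]
        records = [
            _parse_row(row, i, ordered, reader_cols)
            for i, row in enumerate(reader, start=2)
        ]
    ids = [r.lesion_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate lesion_id values {dupes[:5]}")
    return records


def records_from_frame(frame) -> list[CohortRecord]:
    """Records from an in-memory DataFrame in the cohort CSV schema."""
    header = list(frame.columns)
    plane_cols = [c for c in _PLANE_FIELDS if c in header]
    reader_cols = [c for c in header if _READER_COL.match(c)]
    return [
        _parse_row(
            {k: str(v) for k, v in row.items()}, i, plane_cols, reader_cols
        )
        for i, row in enumerate(frame.to_dict("records"), start=2)
    ]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _mode_requires(records: Sequence[CohortRecord], n_planes: int, what: str) -> None:
    missing = [r.lesion_id for r in records if r.plane_calls.n_planes < n_planes]
    if missing:
        raise ValueError(
            f"{what} needs {n_planes} plane-call columns; absent for "
            f"{len(missing)} lesions (e.g. {missing[:3]}); expected columns "
            f"{list(_PLANE_FIELDS)[:n_planes]}"
        )


def decision_change_audit(
    reader_cats: Sequence[BiradsCategory],
    adjusted_cats: Sequence[BiradsCategory],
    pathology: Sequence[bool],
) -> DecisionChangeAudit:
    """Audit category changes crossing the 4A/4B management boundary."""
    if not (len(reader_cats) == len(adjusted_cats) == len(pathology)):
        raise ValueError("sequences must be aligned")
    up_ok = up_bad = down_ok = down_bad = 0
    thr = BiradsCategory.C4B
    for before, after, malignant in zip(reader_cats, adjusted_cats, pathology):
        if before < thr <= after:  # crossed upward: 4A -> 4B management change
            if malignant:
                up_ok += 1
            else:
                up_bad += 1
        elif after < thr <= before:  # crossed downward: 4B -> 4A
            if malignant:
                down_bad += 1
            else:
                down_ok += 1
    return DecisionChangeAudit(up_ok, up_bad, down_ok, down_bad)


def _build_vectors(records: Sequence[CohortRecord], combined_cross: bool):
    records = list(records)
    truth = np.array([r.is_malignant for r in records], dtype=bool)
    n_mal = int(truth.sum())
    n_ben = int((~truth).sum())
    if n_mal == 0 or n_ben == 0:
        raise ValueError("cohort must contain both malignant and benign lesions")

    has_quadri = all(r.plane_calls.n_planes == 4 for r in records)
    readers = sorted({name for r in records for name in r.reader_categories})

    verdicts: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}

    # --- CAD standalone -------------------------------------------------
    _mode_requires(records, 2, "CAD cross-planes")
    cross_sets = [
        r.plane_calls.subset({Plane.LONGITUDINAL, Plane.TRANSVERSE})
        for r in records
    ]
    verdicts["cad_cross"] = np.array(
        [bool(cad_standalone_verdict(s, CROSS_PLANES)) for s in cross_sets]
    )
    scores["cad_cross"] = np.array([s.n_malignant for s in cross_sets], dtype=float)
    if has_quadri:
        verdicts["cad_quadri"] = np.array(
            [bool(cad_standalone_verdict(r.plane_calls, QUADRI_PLANES)) for r in records]
        )
        scores["cad_quadri"] = np.array(
            [r.plane_calls.n_malignant for r in records], dtype=float
        )

    # --- readers --------------------------------------------------------
    without_cats: dict[str, list[BiradsCategory]] = {}
    combined_cats: dict[str, list[BiradsCategory]] = {}
    for reader in readers:
        cats = [r.reader_categories[reader].get("without") for r in records]
        if any(c is None for c in cats):
            raise ValueError(f"reader {reader!r}: missing without-mode categories")
        without_cats[reader] = cats
        verdicts[f"{reader}_without"] = np.array(
            [bool(dichotomize_category(c)) for c in cats]
        )
        scores[f"{reader}_without"] = np.array([c.rank for c in cats], dtype=float)

        explicit = [r.reader_categories[reader].get("combined") for r in records]
        if all(c is not None for c in explicit):
            adj = explicit
        elif has_quadri:
            adj = [
                adjust_category(c, r.plane_calls, QUADRI_PLANES)
                for c, r in zip(cats, records)
            ]
        else:
            adj = None
        if adj is not None:
            combined_cats[reader] = adj
            verdicts[f"{reader}_combined"] = np.array(
                [bool(dichotomize_category(c)) for c in adj]
            )
            scores[f"{reader}_combined"] = np.array(
                [c.rank for c in adj], dtype=float
            )
        if combined_cross:
            adj_x = [
                adjust_category(c, s, CROSS_PLANES)
                for c, s in zip(cats, cross_sets)
            ]
            verdicts[f"{reader}_combined_cross"] = np.array(
                [bool(dichotomize_category(c)) for c in adj_x]
            )
            scores[f"{reader}_combined_cross"] = np.array(
                [c.rank for c in adj_x], dtype=float
            )

    return verdicts, scores, truth, without_cats, combined_cats, readers, has_quadri


def mode_verdicts(
    records: Sequence[CohortRecord],
    combined_cross: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Lesion-level dichotomous verdicts and ordinal scores per mode.

    Returns ``(verdicts, scores, truth)``: boolean verdict vectors and
    ordinal score vectors (plane counts for CAD, category ranks for
    readers) keyed by diagnostic mode, plus the pathology truth vector.
    """
    verdicts, scores, truth, *_ = _build_vectors(records, combined_cross)
    return verdicts, scores, truth


def evaluate_modes(
    records: Sequence[CohortRecord],
    combined_cross: bool = False,
) -> StudyReport:
    """Evaluate every available diagnostic mode against pathology.

    Builds CAD cross-planes and quadri-planes standalone verdicts, each
    reader's without-CAD verdict, and each reader's combined-CAD verdict
    (mechanical quadri-planes adjustment of the without-CAD category unless
    an explicit ``<reader>_combined`` column was supplied).  Populates
    metric panels, plane-count and category ROC AUCs with paired
    comparisons, within-reader McNemar tests, reader-vs-reader agreement,
    and the decision-change audit.  Deterministic given the input.

    ``combined_cross`` additionally evaluates the combined mode under the
    cross-planes rule (methodological comparison; off by default).
    """
    (
        verdicts,
        scores,
        truth,
        without_cats,
        combined_cats,
        readers,
        has_quadri,
    ) = _build_vectors(records, combined_cross)
    n_mal = int(truth.sum())
    n_ben = int((~truth).sum())

    # --- tables, metrics, ROC -------------------------------------------
    contingency = {
        mode: ContingencyTable2x2.from_verdicts(v, truth)
        for mode, v in verdicts.items()
    }
    metrics = {mode: metrics_from_table(t) for mode, t in contingency.items()}
    roc = {mode: empirical_roc(s, truth) for mode, s in scores.items()}
    roc_auc = {
        mode: {
            "auc": r.auc,
            "se": r.se_auc,
            "youden_j": r.youden_j,
            "optimal_cutoff": r.optimal_cutoff,
        }
        for mode, r in roc.items()
    }

    # --- paired comparisons ----------------------------------------------
    mcnemar: dict[str, TestResult] = {}
    auc_cmp: dict[str, TestResult] = {}

    def paired(name: str, mode1: str, mode2: str) -> None:
        v1, v2 = verdicts[mode1], verdicts[mode2]
        b = int(np.sum(v1 & ~v2))
        c = int(np.sum(~v1 & v2))
        mcnemar[name] = mcnemar_test(b, c)
        r = estimate_paired_auc_correlation(scores[mode1], scores[mode2], truth)
        auc_cmp[name] = compare_auc_paired(
            roc[mode1].auc, roc[mode2].auc, roc[mode1].se_auc, roc[mode2].se_auc, r
        )

    if has_quadri:
        paired("cad_cross_vs_cad_quadri", "cad_cross", "cad_quadri")
    for reader in readers:
        if f"{reader}_combined" in verdicts:
            paired(
                f"{reader}_without_vs_combined",
                f"{reader}_without",
                f"{reader}_combined",
            )

    # --- agreement and audit ---------------------------------------------
    agreement: dict[str, AgreementResult] = {}
    for i, r1 in enumerate(readers):
        for r2 in readers[i + 1 :]:
            for mode2 in ("without", "combined"):
                key2 = f"{r2}_{mode2}"
                if key2 not in verdicts:
                    continue
                table = PairedAgreementTable.from_verdicts(
                    verdicts[f"{r1}_without"], verdicts[key2]
                )
                agreement[f"{r1}_without_vs_{key2}"] = cohen_kappa(table)

    decision_changes = {
        reader: decision_change_audit(
            without_cats[reader], combined_cats[reader], truth
        )
        for reader in readers
        if reader in combined_cats
    }

    return StudyReport(
        n_lesions=int(truth.size),
        n_malignant=n_mal,
        n_benign=n_ben,
        contingency=contingency,
        metrics=metrics,
        roc_auc=roc_auc,
        mcnemar=mcnemar,
        auc_comparisons=auc_cmp,
        agreement=agreement,
        decision_changes=decision_changes,
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_report(report: StudyReport, out_dir) -> list[Path]:
    """Write a report as versioned JSON plus human-readable CSV tables.

    Emits ``report.json`` and CSVs mirroring the study's table layout:
    contingency tables, the metric panel, decision changes and agreement.
    Output is byte-identical for identical inputs (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    with json_path.open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(json_path)

    cont_path = out / "contingency.csv"
    with cont_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mode", "tp", "fp", "fn", "tn"])
        for mode, t in report.contingency.items():
            w.writerow([mode, t.tp, t.fp, t.fn, t.tn])
    written.append(cont_path)

    met_path = out / "metrics.csv"
    with met_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        names = ["sensitivity", "specificity", "ppv", "npv", "accuracy"]
        w.writerow(["mode"] + [f"{n}_pct" for n in names] + ["auc"])
        for mode, m in report.metrics.items():
            pcts = m.as_percent_strings()
            auc = report.roc_auc.get(mode, {}).get("auc")
            w.writerow(
                [mode]
                + [pcts[n] for n in names]
                + [f"{auc:.4f}" if auc is not None else ""]
            )
    written.append(met_path)

    if report.decision_changes:
        dc_path = out / "decision_changes.csv"
        with dc_path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "reader",
                    "n_changed",
                    "upgrade_correct",
                    "upgrade_incorrect",
                    "downgrade_correct",
                    "downgrade_incorrect",
                ]
            )
            for reader, audit in report.decision_changes.items():
                d = audit.as_dict()
                w.writerow([reader] + [d[k] for k in list(d)])
        written.append(dc_path)

    if report.agreement:
        ag_path = out / "agreement.csv"
        with ag_path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pairing", "kappa", "kappa_rounded", "band"])
            for key, a in report.agreement.items():
                w.writerow([key, f"{a.kappa:.6f}", f"{a.kappa_rounded:.2f}", a.band])
        written.append(ag_path)

    return written


# ---------------------------------------------------------------------------
# Published-study reproduction
# ---------------------------------------------------------------------------

def load_published_tables() -> dict:
    """Packaged printed summary tables of the published reader study."""
    text = (
        resources.files("cadfusion").joinpath("data/published_study.json").read_text()
    )
    return json.loads(text)


def reproduce_study() -> dict:
    """Recompute every desk-reproducible published quantity from the fixture.

    Feeds the printed contingency counts through the metric panel, the
    printed agreement tables through Cohen's kappa, and the printed
    decision-change counts through the proportion comparisons.  Returns a
    nested dict; values are computed, never transcribed, so discrepancies
    between printed and computed figures (e.g. a specificity printed as
    93.0 where the counts give 92.9) surface honestly.
    """
    tables = load_published_tables()
    out: dict = {
        "n_lesions": tables["n_lesions"],
        "prevalence_percent": 100.0 * tables["n_malignant"] / tables["n_lesions"],
    }

    metrics: dict[str, dict[str, str]] = {}
    for mode, cells in tables["contingency"].items():
        table = ContingencyTable2x2(**cells)
        metrics[mode] = metrics_from_table(table).as_percent_strings()
    out["metrics_percent"] = metrics

    agreement = {}
    for key, cells in tables["agreement"].items():
        res = cohen_kappa(PairedAgreementTable(**cells))
        agreement[key] = {
            "kappa": res.kappa,
            "kappa_rounded": res.kappa_rounded,
            "band": res.band,
        }
    out["agreement"] = agreement

    dc = tables["decision_changes"]
    nov, exp = dc["novice"], dc["experienced"]
    n = tables["n_lesions"]
    changes = {
        "novice_changed_percent": 100.0 * nov["n_changed"] / n,
        "experienced_changed_percent": 100.0 * exp["n_changed"] / n,
        "changed_rate_test": compare_proportions(
            nov["n_changed"], n, exp["n_changed"], n
        ).p_value,
    }
    for cell in (
        "upgrade_correct",
        "upgrade_incorrect",
        "downgrade_correct",
        "downgrade_incorrect",
    ):
        changes[f"novice_{cell}_percent"] = (
            100.0 * nov[cell] / nov["n_changed"]
        )
        changes[f"experienced_{cell}_percent"] = (
            100.0 * exp[cell] / exp["n_changed"]
        )
        changes[f"{cell}_test"] = compare_proportions(
            nov[cell], nov["n_changed"], exp[cell], exp["n_changed"]
        ).p_value
    out["decision_changes"] = changes
    return out
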