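"""Report generation: cohort performance tables and group-comparison tables.

Two entry points:

* :func:`build_report` runs the full pipeline on sessions (score per
  operating mode, stratify by age and rest, cluster-corrected statistics,
  bootstrap FAR intervals) and renders a performance table per stratum.
* :func:`cells_from_counts` computes the desk-scale cells (sensitivity,
  cluster-corrected sensitivity under a unit design effect, precision,
  FAR) directly from aggregate counts, for cross-checking published
  summary tables.

Values are kept at full precision internally and rounded half-to-even
only at render time (2 decimal places).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Optional, Sequence

from .cluster_stats import (
    BootstrapConfig,
    IntervalEstimate,
    clustered_diff_test,
    corrected_sensitivity,
    far_bootstrap_ci,
    far_ratio_test,
    precision_estimate,
)
from .core import AgeGroup, ClusterOutcome, Mode, RecordingSession, TimeInterval
from .scoring import (
    CohortScore,
    cluster_outcomes,
    latency_summary,
    pooled_far,
    pooled_sensitivity,
    score_cohort,
    stratify_by_rest,
)


def round_half_even(value: float, ndigits: int = 2) -> float:
    """Deterministic banker's rounding for rendered cells."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def _singleton_outcomes(n: int, x: int) -> list[ClusterOutcome]:
    """n clusters of size 1 with x detected: the unit-design-effect layout."""
    return [ClusterOutcome(f"c{i}", 1, 1 if i < x else 0) for i in range(n)]


def cells_from_counts(
    n_cs: int,
    n_detected: int,
    n_false_alarms: int,
    hours: float,
    confidence: float = 0.95,
) -> dict:
    """Performance cells computable from aggregate counts alone.

    The cluster-corrected sensitivity is evaluated at design effect 1
    (per-patient cluster sizes are not recoverable from pooled counts);
    precision switches to the Laplace rule of succession when there are
    no false alarms.
    """
    cells: dict = {
        "n_cs": n_cs,
        "n_detected": n_detected,
        "n_false_alarms": n_false_alarms,
        "hours": hours,
        "far": 24.0 * n_false_alarms / hours if hours > 0 else None,
    }
    if n_cs >= 1:
        cells["sensitivity"] = n_detected / n_cs
        csens = corrected_sensitivity(_singleton_outcomes(n_cs, n_detected), confidence)
        cells["csensitivity"] = csens
    else:
        cells["sensitivity"] = None
        cells["csensitivity"] = None
    if n_detected + n_false_alarms >= 1:
        cells["precision"] = precision_estimate(n_detected, n_false_alarms, confidence)
    else:
        cells["precision"] = None
    return cells


def far_reduction_percent(fa_reference: int, fa_alternative: int) -> float:
    """Percent reduction in false alarms of an alternative operating mode."""
    if fa_reference <= 0:
        raise ValueError("reference false-alarm count must be positive")
    return 100.0 * (1.0 - fa_alternative / fa_reference)


# ---------------------------------------------------------------------------
# full-pipeline report
# ---------------------------------------------------------------------------

_STRATA = ("overall", "pediatric", "adult")


def _age_split(
    sessions: Sequence[RecordingSession],
) -> dict[str, list[RecordingSession]]:
    return {
        "overall": list(sessions),
        "pediatric": [s for s in sessions if s.age_group is AgeGroup.PEDIATRIC],
        "adult": [s for s in sessions if s.age_group is AgeGroup.ADULT],
    }


def _stratum_stats(
    cohort: CohortScore,
    n_patients: int,
    bootstrap: Optional[BootstrapConfig],
    confidence: float,
) -> dict:
    out: dict = {
        "n_patients": n_patients,
        "n_patients_with_cs": sum(1 for s in cohort.sessions if s.n_seizures > 0),
        "hours": cohort.hours,
        "n_cs": cohort.n_seizures,
        "n_detected": cohort.n_detected,
        "n_false_alarms": cohort.n_false_alarms,
    }
    if cohort.hours > 0:
        # pooled ratio and mean of per-patient values differ on
        # heterogeneous cohorts; report both
        out["avg_hours_per_patient"] = cohort.hours / max(n_patients, 1)
        per_patient = [s.hours for s in cohort.sessions if s.hours > 0]
        if per_patient:
            out["avg_hours_per_patient_mean"] = sum(per_patient) / len(per_patient)
        out["far"] = pooled_far(cohort)
        if bootstrap is not None and len(cohort.sessions) > 1:
            out["far_ci"] = far_bootstrap_ci(cohort.sessions, bootstrap)
    if cohort.n_seizures >= 1:
        out["sensitivity"] = pooled_sensitivity(cohort)
        out["csensitivity"] = corrected_sensitivity(
            cluster_outcomes(cohort), confidence
        )
        mean_d, sd_d = cohort.duration_summary()
        out["cs_duration_mean_s"] = mean_d
        out["cs_duration_sd_s"] = sd_d
    if cohort.n_detected >= 1:
        lat = latency_summary(cohort)
        out["latency_mean_s"] = lat.mean_s
        out["latency_sd_s"] = lat.sd_s
        out["latency_median_s"] = lat.median_s
    if cohort.n_detected + cohort.n_false_alarms >= 1:
        out["precision"] = precision_estimate(
            cohort.n_detected, cohort.n_false_alarms, confidence
        )
    return out


def build_report(
    sessions: Sequence[RecordingSession],
    rest_by_patient: Optional[Mapping[str, Sequence[TimeInterval]]] = None,
    modes: Sequence[Mode] = (Mode.FDA_CLEARED, Mode.ACTIVE),
    bootstrap: Optional[BootstrapConfig] = None,
    confidence: float = 0.95,
) -> dict:
    """Nested report: {condition: {stratum: {mode: stats}}}.

    Conditions are ``all_data`` and (when rest intervals are supplied)
    ``rest``; strata are overall/pediatric/adult.
    """
    by_age = _age_split(sessions)
    report: dict = {"all_data": {}, "rest": {}}
    for stratum, strat_sessions in by_age.items():
        report["all_data"][stratum] = {}
        report["rest"][stratum] = {}
        for mode in modes:
            cohort = score_cohort(strat_sessions, mode)
            report["all_data"][stratum][Mode(mode).value] = _stratum_stats(
                cohort, len(strat_sessions), bootstrap, confidence
            )
            if rest_by_patient is not None:
                strata = stratify_by_rest(strat_sessions, mode, rest_by_patient)
                rest_cohort = strata["rest"]
                n_rest_pat = sum(1 for s in rest_cohort.sessions if s.hours > 0)
                report["rest"][stratum][Mode(mode).value] = _stratum_stats(
                    rest_cohort, n_rest_pat, bootstrap, confidence
                )
    if rest_by_patient is None:
        report.pop("rest")
    return report


# ---------------------------------------------------------------------------
# group-comparison (between-strata) tests
# ---------------------------------------------------------------------------

def format_p(p: float, floor: float = 1e-3) -> str:
    """Render a p-value, using the ``<10^-3`` convention below the floor."""
    if p < floor:
        return "<10^-3"
    return f"{p:.3f}"


def group_tests(
    outcomes_a: Sequence[ClusterOutcome],
    outcomes_b: Sequence[ClusterOutcome],
    far_a: tuple[float, float],
    far_b: tuple[float, float],
    label: str,
) -> dict:
    """cSensitivity difference test + FAR ratio test for one comparison."""
    out: dict = {"comparison": label}
    if outcomes_a and outcomes_b:
        diff, p = clustered_diff_test(outcomes_a, outcomes_b)
        out["csensitivity_diff"] = diff
        out["csensitivity_p"] = p
    else:
        out["note"] = "cSensitivity comparison skipped: empty stratum"
    res = far_ratio_test(far_a, far_b)
    out["far_ratio_p"] = res.p_value
    return out


def group_tests_from_report(
    sessions: Sequence[RecordingSession],
    rest_by_patient: Optional[Mapping[str, Sequence[TimeInterval]]],
    modes: Sequence[Mode] = (Mode.FDA_CLEARED, Mode.ACTIVE),
) -> list[dict]:
    """Children-vs-adults and rest-vs-active comparisons per operating mode."""
    rows: list[dict] = []
    by_age = _age_split(sessions)
    for mode in modes:
        ped = score_cohort(by_age["pediatric"], mode)
        adu = score_cohort(by_age["adult"], mode)
        row = group_tests(
            cluster_outcomes(ped),
            cluster_outcomes(adu),
            (ped.n_false_alarms, ped.hours),
            (adu.n_false_alarms, adu.hours),
            label="children_vs_adults",
        )
        row["mode"] = Mode(mode).value
        rows.append(row)
        if rest_by_patient is not None:
            strata = stratify_by_rest(sessions, mode, rest_by_patient)
            rest, active = strata["rest"], strata["active"]
            row = group_tests(
                cluster_outcomes(rest),
                cluster_outcomes(active),
                (rest.n_false_alarms, rest.hours),
                (active.n_false_alarms, active.hours),
                label="rest_vs_active",
            )
            row["mode"] = Mode(mode).value
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt(value, nd: int = 2) -> str:
    if value is None:
        return ""
    if isinstance(value, IntervalEstimate):
        return (
            f"{round_half_even(value.estimate, nd):.{nd}f} "
            f"[{round_half_even(value.lower, nd):.{nd}f}, "
            f"{round_half_even(value.upper, nd):.{nd}f}]"
        )
    if isinstance(value, int):
        return str(value)
    return f"{round_half_even(float(value), nd):.{nd}f}"


_ROW_ORDER = [
    ("n_patients", "Patients", 0),
    ("n_patients_with_cs", "Patients with CS", 0),
    ("hours", "Total hours", 0),
    ("n_cs", "Total CS", 0),
    ("cs_duration_mean_s", "Mean CS duration [s]", 2),
    ("n_detected", "Detected CS", 0),
    ("latency_mean_s", "Mean delay [s]", 2),
    ("sensitivity", "Sensitivity", 2),
    ("csensitivity", "cSensitivity [95% CI]", 2),
    ("precision", "Precision [95% CI]", 2),
    ("n_false_alarms", "Total false alarms", 0),
    ("far", "FAR", 2),
    ("far_ci", "FAR [95% CI]", 2),
]


def render_markdown(report: dict) -> str:
    lines: list[str] = []
    for condition, strata in report.items():
        for stratum, modes in strata.items():
            if not modes:
                continue
            lines.append(f"## {condition} / {stratum}\n")
            mode_names = list(modes)
            header = "| metric | " + " | ".join(mode_names) + " |"
            sep = "|---" * (len(mode_names) + 1) + "|"
            lines.append(header)
            lines.append(sep)
            for key, label, nd in _ROW_ORDER:
                cells = [
                    _fmt(modes[m].get(key), nd if nd else 0) for m in mode_names
                ]
                if any(cells):
                    lines.append(f"| {label} | " + " | ".join(cells) + " |")
            lines.append("")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, IntervalEstimate):
        return {
            "estimate": obj.estimate,
            "lower": obj.lower,
            "upper": obj.upper,
            "confidence": obj.confidence,
            "method": obj.method.value,
            "flags": list(obj.flags),
        }
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(_jsonable(report), indent=1, sort_keys=True) + "\n"
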