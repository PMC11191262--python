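"""Domain types and file I/O for trial subjects, longitudinal measurements and rule reports.

The package works on two plain-CSV schemas:

``subjects.csv``
    one row per enrolled participant — ``subject_id, arm, hla_dr3, hla_dr4,
    hla_a2, age_at_onset`` plus any number of extra numeric baseline-covariate
    columns.

``measurements.csv``
    long format, one row per observed value — ``subject_id, endpoint, week,
    value``.  Missing visits are absent rows, never sentinel numbers.

Visits follow the fixed trial schedule (weeks −4, 0, 6, 12, 18, 24); week 0 is
the randomization (baseline) visit.  Files are comma-separated, UTF-8, ``.``
decimal, header required; reals are written with 12 significant digits so a
write/read round-trip is exact to that precision.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

#: Scheduled visit weeks; −4 is screening, 0 is randomization/baseline.
VISIT_WEEKS: tuple[int, ...] = (-4, 0, 6, 12, 18, 24)
BASELINE_WEEK: int = 0
#: Fixed weeks→months conversion used wherever a per-month rate meets a
#: week-indexed visit schedule (one convention for the whole package).
WEEKS_PER_MONTH: float = 4.345


class TrialError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TrialError):
    """A file does not conform to the expected schema."""


class ValidationError(TrialError):
    """Parsed data violates a domain invariant."""


class ConfigError(TrialError):
    """A configuration object is internally inconsistent."""


class OracleScopeError(TrialError):
    """A brute-force oracle was asked to run outside its intended tiny scale."""


class Arm(str, enum.Enum):
    """Randomization arm: placebo or one of three escalating active doses."""

    placebo = "placebo"
    doseA = "doseA"
    doseB = "doseB"
    doseC = "doseC"


#: Active (treatment) arms in escalation order.
ACTIVE_ARMS: tuple[Arm, ...] = (Arm.doseA, Arm.doseB, Arm.doseC)
#: The pooled post hoc grouping: placebo + dose A vs dose B + dose C.
TREATED_ARMS: frozenset[Arm] = frozenset({Arm.doseB, Arm.doseC})
UNTREATED_ARMS: frozenset[Arm] = frozenset({Arm.placebo, Arm.doseA})


@dataclass(frozen=True)
class Visit:
    """One scheduled visit, identified by its week offset from randomization."""

    week: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.week not in VISIT_WEEKS:
            raise ValidationError(
                f"week {self.week} is not in the visit schedule {VISIT_WEEKS}"
            )


@dataclass
class SubjectRecord:
    """One enrolled (real or synthetic) participant.

    Inclusion requires DR3 and/or DR4 positivity, so ``hla_dr3 or hla_dr4``
    must hold.  ``baseline_covariates`` is an open-ended map of numeric
    baseline characteristics (e.g. baseline insulin dose per kg).
    """

    subject_id: str
    arm: Arm
    hla_dr3: bool
    hla_dr4: bool
    hla_a2: bool
    age_at_onset: float
    baseline_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.arm, Arm):
            self.arm = Arm(self.arm)
        if not (self.hla_dr3 or self.hla_dr4):
            raise ValidationError(
                f"subject {self.subject_id}: must be HLA DR3+ and/or DR4+"
            )
        if not (self.age_at_onset > 0 and math.isfinite(self.age_at_onset)):
            raise ValidationError(
                f"subject {self.subject_id}: age_at_onset must be a positive real"
            )

    @property
    def treated(self) -> bool:
        """True for the pooled treated group (dose B + dose C)."""
        return self.arm in TREATED_ARMS


@dataclass
class MeasurementSeries:
    """Longitudinal values of one endpoint for one subject.

    ``values`` maps visit week → value; missing visits are simply absent keys.
    """

    subject_id: str
    endpoint_name: str
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for week, value in self.values.items():
            Visit(week)
            if not math.isfinite(value):
                raise ValidationError(
                    f"{self.subject_id}/{self.endpoint_name}: non-finite value "
                    f"at week {week}"
                )

    def value_at(self, week: int) -> float | None:
        return self.values.get(week)


@dataclass
class RuleReport:
    """An ordered list of scored rules plus the provenance needed to re-derive it."""

    rules: list[Any]
    provenance: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SUBJECT_REQUIRED = ("subject_id", "arm", "hla_dr3", "hla_dr4", "age_at_onset")
_MEAS_REQUIRED = ("subject_id", "endpoint", "week", "value")

_BOOL_STRINGS = {"0": False, "1": True, "false": False, "true": True}


def _parse_bool(raw: Any, column: str) -> bool:
    text = str(raw).strip().lower()
    if text not in _BOOL_STRINGS:
        raise FormatError(f"column {column}: cannot parse boolean from {raw!r}")
    return _BOOL_STRINGS[text]


def _fmt(x: float) -> str:
    """Canonical 12-significant-digit formatting for byte-stable files."""
    return format(float(x), ".12g")


def read_subjects(path: str) -> list[SubjectRecord]:
    """Read a subjects CSV; any column beyond the fixed schema becomes a covariate."""
    frame = pd.read_csv(path, dtype=str)
    for col in _SUBJECT_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"subjects file is missing required column '{col}'")
    has_a2 = "hla_a2" in frame.columns
    covariate_cols = [
        c for c in frame.columns if c not in _SUBJECT_REQUIRED and c != "hla_a2"
    ]
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        row_d = row._asdict()
        sid = str(row_d["subject_id"])
        if sid in seen:
            raise ValidationError(f"duplicate subject_id '{sid}'")
        seen.add(sid)
        try:
            arm = Arm(str(row_d["arm"]))
        except ValueError:
            raise FormatError(f"subject {sid}: unknown arm {row_d['arm']!r}") from None
        covs: dict[str, float] = {}
        for c in covariate_cols:
            raw = row_d[c]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            try:
                covs[c] = float(raw)
            except ValueError:
                raise FormatError(
                    f"subject {sid}: non-numeric covariate '{c}' = {raw!r}"
                ) from None
        try:
            age = float(row_d["age_at_onset"])
        except ValueError:
            raise FormatError(
                f"subject {sid}: non-numeric age_at_onset {row_d['age_at_onset']!r}"
            ) from None
        records.append(
            SubjectRecord(
                subject_id=sid,
                arm=arm,
                hla_dr3=_parse_bool(row_d["hla_dr3"], "hla_dr3"),
                hla_dr4=_parse_bool(row_d["hla_dr4"], "hla_dr4"),
                hla_a2=_parse_bool(row_d["hla_a2"], "hla_a2") if has_a2 else False,
                age_at_onset=age,
                baseline_covariates=covs,
            )
        )
    return records


def write_subjects(subjects: Sequence[SubjectRecord], path: str) -> None:
    cov_names = sorted({k for s in subjects for k in s.baseline_covariates})
    lines = ["subject_id,arm,hla_dr3,hla_dr4,hla_a2,age_at_onset"
             + "".join("," + c for c in cov_names)]
    for s in subjects:
        cells = [
            s.subject_id,
            s.arm.value,
            str(int(s.hla_dr3)),
            str(int(s.hla_dr4)),
            str(int(s.hla_a2)),
            _fmt(s.age_at_onset),
        ]
        for c in cov_names:
            v = s.baseline_covariates.get(c)
            cells.append("" if v is None else _fmt(v))
        lines.append(",".join(cells))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_measurements(path: str) -> list[MeasurementSeries]:
    """Read a long-format measurements CSV into one series per (subject, endpoint)."""
    frame = pd.read_csv(path, dtype=str)
    for col in _MEAS_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"measurements file is missing required column '{col}'")
    series: dict[tuple[str, str], MeasurementSeries] = {}
    for row in frame.itertuples(index=False):
        row_d = row._asdict()
        sid = str(row_d["subject_id"])
        endpoint = str(row_d["endpoint"])
        try:
            week = int(str(row_d["week"]))
        except ValueError:
            raise FormatError(f"non-integer week {row_d['week']!r}") from None
        if week not in VISIT_WEEKS:
            raise ValidationError(
                f"{sid}/{endpoint}: week {week} not in visit schedule {VISIT_WEEKS}"
            )
        try:
            value = float(str(row_d["value"]))
        except ValueError:
            raise FormatError(
                f"{sid}/{endpoint}: non-numeric value {row_d['value']!r}"
            ) from None
        key = (sid, endpoint)
        if key not in series:
            series[key] = MeasurementSeries(sid, endpoint, {})
        if week in series[key].values:
            raise ValidationError(
                f"duplicate measurement for ({sid}, {endpoint}, week {week})"
            )
        if not math.isfinite(value):
            raise ValidationError(
                f"{sid}/{endpoint}: non-finite value at week {week}"
            )
        series[key].values[week] = value
    return list(series.values())


def write_measurements(series: Iterable[MeasurementSeries], path: str) -> None:
    lines = ["subject_id,endpoint,week,value"]
    for s in series:
        for week in sorted(s.values):
            lines.append(f"{s.subject_id},{s.endpoint_name},{week},{_fmt(s.values[week])}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Rule report output
# ---------------------------------------------------------------------------

def _descriptor_set_str(descs: Iterable[Any]) -> str:
    parts = sorted(f"{d.name}={d.category}" for d in descs)
    return " & ".join(parts)


def rule_sort_key(scored: Any) -> tuple:
    """Total order on scored rules: lift desc, support desc, then lexicographic."""
    m = scored.metrics
    return (
        -m.lift,
        -m.support,
        _descriptor_set_str(scored.rule.antecedent),
        _descriptor_set_str(scored.rule.consequent),
    )


def write_rule_report(rules: Sequence[Any], path: str, format: str = "tsv") -> None:
    """Write scored rules as TSV or JSON, deterministically ordered.

    Rules are sorted by descending lift, then descending support, then
    lexicographically by antecedent/consequent, so the same rule set always
    produces byte-identical output regardless of input order.
    """
    ordered = sorted(rules, key=rule_sort_key)
    if format == "tsv":
        lines = ["antecedent\tconsequent\tsupport\tconfidence\tlift\tp_fisher\tp_mww\tn_total"]
        for sr in ordered:
            m = sr.metrics
            lines.append(
                "\t".join(
                    [
                        _descriptor_set_str(sr.rule.antecedent),
                        _descriptor_set_str(sr.rule.consequent),
                        str(m.support),
                        _fmt(m.confidence),
                        _fmt(m.lift),
                        _fmt(m.p_fisher),
                        "" if m.p_mww is None else _fmt(m.p_mww),
                        str(m.n_effective),
                    ]
                )
            )
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "json":
        payload = [
            {
                "antecedent": _descriptor_set_str(sr.rule.antecedent),
                "consequent": _descriptor_set_str(sr.rule.consequent),
                "support": sr.metrics.support,
                "confidence": float(_fmt(sr.metrics.confidence)),
                "lift": float(_fmt(sr.metrics.lift)),
                "p_fisher": float(_fmt(sr.metrics.p_fisher)),
                "p_mww": None if sr.metrics.p_mww is None else float(_fmt(sr.metrics.p_mww)),
                "n_total": sr.metrics.n_effective,
            }
            for sr in ordered
        ]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ConfigError(f"unknown report format {format!r} (expected tsv or json)")
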