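"""Endpoint derivations feeding the formal context.

Three derivations turn longitudinal measurements into categorical
descriptors:

* **delta ratios** — relative change from the randomization visit,
  ``(v_n − v_base) / v_base``, discretized as increasing (> 0), stable (= 0)
  or decreasing (< 0); a configurable tolerance widens the "stable" band for
  continuous assays where exact zeros never occur (default 0, i.e. strict);
* **tertile bins** — baseline characteristics split into low/medium/high by
  equal-frequency, rank-based tertiles;
* **clinical response** — observed normalized AUC C-peptide minus the value
  expected under the population decline (−0.0245 pmol/mL/month by default),
  and the model-based quantitative response (QR) on the log scale.

Missing visits and zero baselines are signals, not pipeline-aborting errors:
the affected descriptor is simply absent for that subject, and the context
records the variable as unmeasured there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .synthetic_cohort import AUC_ENDPOINT, months
from .trial_data import (
    BASELINE_WEEK,
    ConfigError,
    MeasurementSeries,
    SubjectRecord,
    TrialError,
    VISIT_WEEKS,
)

log = logging.getLogger(__name__)

INCREASING = "increasing"
STABLE = "stable"
DECREASING = "decreasing"
LOW, MEDIUM, HIGH = "low", "medium", "high"
IMPROVED, AS_EXPECTED, WORSE = "improved", "as_expected", "worse"


class InsufficientDataError(TrialError):
    """Fewer values than a derivation needs (e.g. < 3 for tertiles)."""


class DegenerateDataError(TrialError):
    """All values identical — the variable carries no tertile information."""


@dataclass(frozen=True)
class DeltaRatio:
    """Relative change of one endpoint between two visits (dimensionless)."""

    subject_id: str
    endpoint_name: str
    from_week: int
    to_week: int
    value: float


@dataclass(frozen=True)
class Descriptor:
    """One binary context column: a variable name plus a category level."""

    name: str
    category: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.name}={self.category}"


@dataclass
class ClinicalResponseConfig:
    """Expected-decline and QR model parameters.

    ``qr_coefficients`` maps ``intercept``, ``coef_log_baseline_auc`` and
    ``coef_age`` for the published quantitative-response model; there is no
    built-in default — supply the published values.
    """

    expected_slope_per_month: float = -0.0245
    slope_ci: tuple[float, float] | None = (-0.0271, -0.0215)
    qr_coefficients: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.slope_ci is not None:
            lo, hi = self.slope_ci
            if not (lo <= self.expected_slope_per_month <= hi):
                raise ConfigError(
                    "expected_slope_per_month must lie within slope_ci"
                )


def compute_delta_ratio(
    series: MeasurementSeries,
    baseline_week: int = BASELINE_WEEK,
    target_week: int = 24,
) -> DeltaRatio | None:
    """Relative change ``(v_n − v_base)/v_base``; ``None`` when undefined.

    Returns ``None`` (a missing-data / undefined-delta signal) when either
    visit is absent or the baseline value is zero; callers exclude such
    subject×descriptor cells from the context rather than aborting.
    """
    v_base = series.value_at(baseline_week)
    v_n = series.value_at(target_week)
    if v_base is None or v_n is None:
        return None
    if v_base == 0.0:
        log.debug(
            "undefined delta for %s/%s: zero baseline at week %d",
            series.subject_id, series.endpoint_name, baseline_week,
        )
        return None
    return DeltaRatio(
        subject_id=series.subject_id,
        endpoint_name=series.endpoint_name,
        from_week=baseline_week,
        to_week=target_week,
        value=(v_n - v_base) / v_base,
    )


def discretize_delta(value: float, zero_tolerance: float = 0.0) -> str:
    """Trichotomize a delta ratio: increasing / stable / decreasing.

    With the default tolerance 0 the "stable" category is the literal zero;
    a positive tolerance classifies ``|delta| ≤ tol`` as stable.
    """
    if zero_tolerance < 0:
        raise ConfigError("zero_tolerance must be ≥ 0")
    if not math.isfinite(value):
        raise ConfigError("delta value must be finite")
    if abs(value) <= zero_tolerance:
        return STABLE
    return INCREASING if value > 0 else DECREASING


def tertile_bin(values: Sequence[tuple[str, float]]) -> dict[str, str]:
    """Equal-frequency tertile binning: low / medium / high.

    Rank-based: with n values the target bin sizes are as equal as possible,
    remainder assigned bottom-up (low first, then medium).  Tied values never
    straddle a bin boundary — the boundary moves to the nearest rank position
    where adjacent sorted values differ, and on an equidistant tie to the
    higher position so the tied run lands in the lower bin.
    """
    if len(values) < 3:
        raise InsufficientDataError(
            f"tertile binning needs ≥ 3 values, got {len(values)}"
        )
    ordered = sorted(values, key=lambda kv: (kv[1], kv[0]))
    vals = [v for _, v in ordered]
    n = len(vals)
    if vals[0] == vals[-1]:
        raise DegenerateDataError("all values identical; variable is uninformative")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    raw_bounds = [sizes[0], sizes[0] + sizes[1]]
    # rank positions where a boundary may legally sit (adjacent values differ)
    gaps = [i for i in range(1, n) if vals[i - 1] != vals[i]]
    gaps = [0] + gaps + [n]
    bounds: list[int] = []
    for rb in raw_bounds:
        best = min(gaps, key=lambda g: (abs(g - rb), -g))
        bounds.append(best)
    b1, b2 = bounds
    if b2 < b1:
        b2 = b1
    out: dict[str, str] = {}
    for i, (sid, _) in enumerate(ordered):
        out[sid] = LOW if i < b1 else (MEDIUM if i < b2 else HIGH)
    return out


def expected_auc_response(
    baseline_auc: float,
    observed_auc: float,
    elapsed_months: float,
    config: ClinicalResponseConfig | None = None,
) -> float:
    """Observed minus expected AUC under the population decline slope.

    ``observed − (baseline + slope × elapsed_months)``; positive values mean
    better-than-expected disease evolution.
    """
    if elapsed_months <= 0:
        raise ConfigError("elapsed_months must be > 0")
    cfg = config or ClinicalResponseConfig()
    expected = baseline_auc + cfg.expected_slope_per_month * elapsed_months
    return observed_auc - expected


def qr_response(
    observed_auc: float,
    baseline_auc: float,
    age_at_onset: float,
    config: ClinicalResponseConfig,
) -> float:
    """Quantitative response: observed minus model-expected log AUC.

    ``log(observed+1) − (intercept + b·log(baseline+1) + c·age)``, with the
    coefficients of the published C-peptide expectation model supplied via
    ``config.qr_coefficients``.
    """
    coefs = config.qr_coefficients
    if not coefs:
        raise ConfigError(
            "qr_coefficients missing: supply the published model coefficients "
            "{intercept, coef_log_baseline_auc, coef_age}"
        )
    for key in ("intercept", "coef_log_baseline_auc", "coef_age"):
        if key not in coefs:
            raise ConfigError(f"qr_coefficients missing entry '{key}'")
    expected = (
        coefs["intercept"]
        + coefs["coef_log_baseline_auc"] * math.log(baseline_auc + 1.0)
        + coefs["coef_age"] * age_at_onset
    )
    return math.log(observed_auc + 1.0) - expected


# ---------------------------------------------------------------------------
# Descriptor table
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Knobs for descriptor-table construction."""

    clinical: ClinicalResponseConfig = field(default_factory=ClinicalResponseConfig)
    zero_tolerance: float = 0.0
    auc_endpoint: str = AUC_ENDPOINT
    delta_baseline_week: int = BASELINE_WEEK
    #: weeks for which delta / response descriptors are derived (None = every
    #: scheduled post-baseline visit).
    target_weeks: tuple[int, ...] | None = None
    include_hla_a2: bool = True

    def resolved_target_weeks(self) -> tuple[int, ...]:
        if self.target_weeks is not None:
            return self.target_weeks
        return tuple(w for w in VISIT_WEEKS if w > self.delta_baseline_week)


@dataclass
class DescriptorTable:
    """Sparse subject × descriptor table plus the metadata the miner needs.

    ``measured`` records, per source variable, which subjects actually have a
    value — distinguishing "category absent because negative" from
    "category absent because unmeasured".  ``numeric`` keeps the underlying
    continuous value behind each discretized variable so rule statistics can
    run rank tests on the original scale.
    """

    entries: list[tuple[str, Descriptor]] = field(default_factory=list)
    variables: dict[str, tuple[str, ...]] = field(default_factory=dict)
    measured: dict[str, set[str]] = field(default_factory=dict)
    numeric: dict[str, dict[str, float]] = field(default_factory=dict)
    subject_ids: list[str] = field(default_factory=list)

    def add(self, sid: str, var: str, category: str, categories: tuple[str, ...]) -> None:
        self.variables.setdefault(var, categories)
        self.measured.setdefault(var, set()).add(sid)
        self.entries.append((sid, Descriptor(var, category)))

    def descriptors_of(self, var: str) -> list[Descriptor]:
        return [Descriptor(var, c) for c in self.variables.get(var, ())]


ARM_VAR = "arm"
DR3_VAR = "hla_dr3"
DR4_VAR = "hla_dr4"
A2_VAR = "hla_a2"
GROUP_VAR = "treatment_group"

SUBJECT_LEVEL_CATEGORIES: dict[str, tuple[str, ...]] = {
    ARM_VAR: ("placebo", "doseA", "doseB", "doseC"),
    DR3_VAR: ("DR3+", "DR3-"),
    DR4_VAR: ("DR4+", "DR4-"),
    A2_VAR: ("A2+", "A2-"),
    GROUP_VAR: ("treated", "untreated"),
}

DELTA_CATEGORIES = (INCREASING, STABLE, DECREASING)
TERTILE_CATEGORIES = (LOW, MEDIUM, HIGH)
RESPONSE_CATEGORIES = (IMPROVED, AS_EXPECTED, WORSE)


def delta_variable(endpoint: str, from_week: int, to_week: int) -> str:
    return f"delta:{endpoint}:w{from_week}-w{to_week}"


def response_variable(endpoint: str, to_week: int) -> str:
    return f"response:{endpoint}:w{to_week}"


def baseline_variable(covariate: str) -> str:
    return f"baseline:{covariate}"


def build_descriptor_table(
    subjects: Sequence[SubjectRecord],
    measurements: Sequence[MeasurementSeries],
    config: PreprocessConfig | None = None,
) -> DescriptorTable:
    """Derive the full descriptor table for a trial.

    Emits, per subject: arm, HLA (explicit positive *and* negative
    categories), pooled treated/untreated group, tertile categories for age
    at onset and every numeric baseline covariate, delta categories for every
    endpoint × (baseline→visit) pair with both visits observed, and
    expected-AUC response categories for the AUC endpoint.  A subject lacking
    the inputs for a derived value simply lacks that descriptor.
    """
    cfg = config or PreprocessConfig()
    table = DescriptorTable()
    table.subject_ids = [s.subject_id for s in subjects]

    for s in subjects:
        table.add(s.subject_id, ARM_VAR, s.arm.value, SUBJECT_LEVEL_CATEGORIES[ARM_VAR])
        table.add(s.subject_id, DR3_VAR, "DR3+" if s.hla_dr3 else "DR3-",
                  SUBJECT_LEVEL_CATEGORIES[DR3_VAR])
        table.add(s.subject_id, DR4_VAR, "DR4+" if s.hla_dr4 else "DR4-",
                  SUBJECT_LEVEL_CATEGORIES[DR4_VAR])
        if cfg.include_hla_a2:
            table.add(s.subject_id, A2_VAR, "A2+" if s.hla_a2 else "A2-",
                      SUBJECT_LEVEL_CATEGORIES[A2_VAR])
        table.add(s.subject_id, GROUP_VAR, "treated" if s.treated else "untreated",
                  SUBJECT_LEVEL_CATEGORIES[GROUP_VAR])

    # tertiles of baseline characteristics
    baseline_vars: dict[str, list[tuple[str, float]]] = {
        baseline_variable("age_at_onset"): [
            (s.subject_id, s.age_at_onset) for s in subjects
        ]
    }
    for s in subjects:
        for cov, value in s.baseline_covariates.items():
            baseline_vars.setdefault(baseline_variable(cov), []).append(
                (s.subject_id, value)
            )
    for var, pairs in sorted(baseline_vars.items()):
        try:
            bins = tertile_bin(pairs)
        except DegenerateDataError:
            log.warning("dropping degenerate baseline variable %s", var)
            continue
        except InsufficientDataError:
            log.warning("dropping baseline variable %s: fewer than 3 values", var)
            continue
        table.numeric[var] = dict(pairs)
        for sid, category in bins.items():
            table.add(sid, var, category, TERTILE_CATEGORIES)

    ages = {s.subject_id: s.age_at_onset for s in subjects}
    target_weeks = cfg.resolved_target_weeks()

    for series in measurements:
        for to_week in target_weeks:
            delta = compute_delta_ratio(series, cfg.delta_baseline_week, to_week)
            if delta is None:
                continue
            var = delta_variable(series.endpoint_name, cfg.delta_baseline_week, to_week)
            table.numeric.setdefault(var, {})[series.subject_id] = delta.value
            table.add(series.subject_id, var,
                      discretize_delta(delta.value, cfg.zero_tolerance),
                      DELTA_CATEGORIES)
        if series.endpoint_name == cfg.auc_endpoint:
            v_base = series.value_at(cfg.delta_baseline_week)
            if v_base is None:
                continue
            for to_week in target_weeks:
                v_obs = series.value_at(to_week)
                if v_obs is None:
                    continue
                elapsed = months(to_week - cfg.delta_baseline_week)
                r = expected_auc_response(v_base, v_obs, elapsed, cfg.clinical)
                var = response_variable(series.endpoint_name, to_week)
                table.numeric.setdefault(var, {})[series.subject_id] = r
                if abs(r) <= cfg.zero_tolerance:
                    category = AS_EXPECTED
                else:
                    category = IMPROVED if r > 0 else WORSE
                table.add(series.subject_id, var, category, RESPONSE_CATEGORIES)
    return table


def export_descriptor_table(table: DescriptorTable, path: str) -> None:
    """Audit export: TSV of subject_id, descriptor name, category."""
    rows = sorted(
        (sid, d.name, d.category) for sid, d in table.entries
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id\tdescriptor\tcategory\n")
        for sid, name, category in rows:
            fh.write(f"{sid}\t{name}\t{category}\n")
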