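"""Synthetic trial generator emulating a small phase 1b T1D immunotherapy study.

The generator reproduces the statistical skeleton the downstream analysis
assumes rather than any mechanistic immunology:

* 41 subjects randomized 3:1 (active:placebo), actives split across three
  escalating doses, by deterministic largest-remainder block allocation;
* HLA strata over {DR3 only, DR4 only, DR3/DR4} with DR4-only the most common
  type, plus an independent HLA-A2:01 flag;
* normalized AUC C-peptide declining linearly at −0.0245 pmol/mL/month on
  average (per-subject slope jitter), with companion clinical endpoints
  coupled to the same trajectory (fasting C-peptide/glucose ratio positively,
  daily insulin dose per kg negatively);
* phenomenological immune-marker trajectories with per-arm mean fold-changes;
* plantable treatment×HLA → outcome associations: a matching subject's AUC
  decline slope is multiplied by a configured effect (0 = halted decline)
  with a configured penetrance.

Everything is driven by one ``numpy`` generator seeded from the config, so a
given config reproduces its trial bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .trial_data import (
    ACTIVE_ARMS,
    Arm,
    ConfigError,
    MeasurementSeries,
    SubjectRecord,
    VISIT_WEEKS,
    WEEKS_PER_MONTH,
    write_measurements,
    write_subjects,
)

#: Endpoint names used by the default generator roster.
AUC_ENDPOINT = "cpep_auc"
RATIO_ENDPOINT = "cpep_glucose_ratio"
INSULIN_ENDPOINT = "insulin_dose_per_kg"

#: Default per-arm mean fold-changes (baseline → week 24) for the
#: phenomenological immune markers: treatment-specific cytolytic CD4+
#: (granzyme B+) cells rise under doses B/C; disease-specific perforin+ CD8+
#: cells rise under dose B and fall under dose C; IL-17+ CD4+ cells rise
#: modestly under doses B/C.
DEFAULT_IMMUNE_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "cd4_gzmb_specific": {"placebo": 1.0, "doseA": 1.1, "doseB": 1.6, "doseC": 1.6},
    "cd8_perforin_disease": {"placebo": 1.0, "doseA": 1.0, "doseB": 1.4, "doseC": 0.7},
    "cd4_il17_specific": {"placebo": 1.0, "doseA": 1.0, "doseB": 1.3, "doseC": 1.3},
}


def months(week: float) -> float:
    """Convert a visit week offset to months using the package-wide convention."""
    return week / WEEKS_PER_MONTH


@dataclass
class PlantedRule:
    """A treatment×HLA → outcome association planted into the generator.

    The antecedent is a conjunction of arm/HLA conditions (``None`` = no
    condition).  For each matching subject, with probability ``penetrance``
    the decline slope of ``affected_endpoint`` is multiplied by ``effect``
    (0 halts the decline, −1 reverses it, 1 leaves it unchanged).
    """

    arm: Arm | None = None
    treated_group: bool | None = None
    hla_dr3: bool | None = None
    hla_dr4: bool | None = None
    affected_endpoint: str = AUC_ENDPOINT
    effect: float = 0.0
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.arm is not None and not isinstance(self.arm, Arm):
            self.arm = Arm(self.arm)
        if not (0.0 <= self.penetrance <= 1.0):
            raise ConfigError("penetrance must lie in [0, 1]")

    def matches(self, subject: SubjectRecord) -> bool:
        if self.arm is not None and subject.arm != self.arm:
            return False
        if self.treated_group is not None and subject.treated != self.treated_group:
            return False
        if self.hla_dr3 is not None and subject.hla_dr3 != self.hla_dr3:
            return False
        if self.hla_dr4 is not None and subject.hla_dr4 != self.hla_dr4:
            return False
        return True


@dataclass
class SimulationConfig:
    """All generator knobs.  Defaults reproduce the study conditions."""

    n_subjects: int = 41
    #: active:placebo allocation ratio; actives are split as evenly as
    #: possible across the three doses.
    allocation_ratio: tuple[int, int] = (3, 1)
    #: probabilities over (DR3 only, DR4 only, DR3/DR4); DR4-only 46.3% is
    #: the reported most-common stratum, the remainder split is a generator
    #: choice.
    hla_frequencies: tuple[float, float, float] = (0.244, 0.463, 0.293)
    p_hla_a2: float = 0.634
    cpep_slope_per_month: float = -0.0245
    cpep_slope_sd: float = 0.005
    baseline_auc_range: tuple[float, float] = (0.4, 1.2)
    age_at_onset_range: tuple[float, float] = (18.0, 40.0)
    noise_sd: float = 0.01
    #: change in companion endpoint per unit change in AUC from baseline.
    coupling_ratio: float = 0.5
    coupling_insulin: float = -0.8
    immune_fold_changes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_IMMUNE_FOLD_CHANGES.items()}
    )
    immune_baseline_range: tuple[float, float] = (1.0, 5.0)
    immune_noise_sd: float = 0.05
    planted_rules: list[PlantedRule] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 8:
            raise ConfigError("n_subjects must be ≥ 8 (two subjects per arm)")
        freqs = self.hla_frequencies
        if any(not (0.0 <= f <= 1.0) for f in freqs):
            raise ConfigError("hla_frequencies must lie in [0, 1]")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ConfigError("hla_frequencies must sum to 1 within 1e-12")
        if not (0.0 <= self.p_hla_a2 <= 1.0):
            raise ConfigError("p_hla_a2 must lie in [0, 1]")
        if self.cpep_slope_sd < 0 or self.noise_sd < 0 or self.immune_noise_sd < 0:
            raise ConfigError("standard deviations must be ≥ 0")
        a, b = self.baseline_auc_range
        if not (0 < a <= b):
            raise ConfigError("baseline_auc_range must be a positive interval")
        r_active, r_placebo = self.allocation_ratio
        if r_active <= 0 or r_placebo <= 0:
            raise ConfigError("allocation_ratio parts must be positive")
        roster = {AUC_ENDPOINT, RATIO_ENDPOINT, INSULIN_ENDPOINT, *self.immune_fold_changes}
        for rule in self.planted_rules:
            if rule.affected_endpoint not in roster:
                raise ConfigError(
                    f"planted rule targets unknown endpoint '{rule.affected_endpoint}'"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        for rule in d["planted_rules"]:
            if rule["arm"] is not None:
                rule["arm"] = str(Arm(rule["arm"]).value)
        d["allocation_ratio"] = list(self.allocation_ratio)
        d["hla_frequencies"] = list(self.hla_frequencies)
        d["baseline_auc_range"] = list(self.baseline_auc_range)
        d["age_at_onset_range"] = list(self.age_at_onset_range)
        d["immune_baseline_range"] = list(self.immune_baseline_range)
        return d


def allocate_arms(n_subjects: int, ratio: tuple[int, int] = (3, 1)) -> list[Arm]:
    """Deterministic largest-remainder allocation closest to the target ratio.

    Quotas: placebo gets ``n·p/(a+p)``; each dose gets a third of the active
    quota.  Seats left after flooring go to the largest fractional remainders,
    ties broken toward the higher dose (C before B before A before placebo) —
    the escalation design favoured a larger dose-C group.
    """
    r_active, r_placebo = ratio
    total = r_active + r_placebo
    quotas = {
        Arm.placebo: n_subjects * r_placebo / total,
        Arm.doseA: n_subjects * r_active / (total * 3),
        Arm.doseB: n_subjects * r_active / (total * 3),
        Arm.doseC: n_subjects * r_active / (total * 3),
    }
    counts = {arm: int(np.floor(q)) for arm, q in quotas.items()}
    leftover = n_subjects - sum(counts.values())
    tie_order = [Arm.doseC, Arm.doseB, Arm.doseA, Arm.placebo]
    by_remainder = sorted(
        tie_order, key=lambda arm: (-(quotas[arm] - counts[arm]), tie_order.index(arm))
    )
    for arm in by_remainder[:leftover]:
        counts[arm] += 1
    arms: list[Arm] = []
    for arm in (Arm.placebo, Arm.doseA, Arm.doseB, Arm.doseC):
        arms.extend([arm] * counts[arm])
    return arms


def generate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate subject records: arms by block allocation, HLA by sampling."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms = allocate_arms(config.n_subjects, config.allocation_ratio)
    width = max(2, len(str(config.n_subjects)))
    subjects: list[SubjectRecord] = []
    strata = rng.choice(3, size=config.n_subjects, p=list(config.hla_frequencies))
    a2 = rng.random(config.n_subjects) < config.p_hla_a2
    ages = rng.uniform(*config.age_at_onset_range, size=config.n_subjects)
    ins0 = rng.uniform(0.2, 0.8, size=config.n_subjects)
    cpep0 = rng.uniform(0.3, 0.9, size=config.n_subjects)
    for i, arm in enumerate(arms):
        stratum = int(strata[i])  # 0: DR3 only, 1: DR4 only, 2: DR3/DR4
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                arm=arm,
                hla_dr3=stratum in (0, 2),
                hla_dr4=stratum in (1, 2),
                hla_a2=bool(a2[i]),
                age_at_onset=float(ages[i]),
                baseline_covariates={
                    "baseline_insulin_dose_per_kg": float(ins0[i]),
                    "baseline_fasting_cpep": float(cpep0[i]),
                },
            )
        )
    return subjects


def _truncate(x: float) -> float:
    return x if x > 0.0 else 0.0


def simulate_trajectories(
    cohort: Sequence[SubjectRecord], config: SimulationConfig
) -> list[MeasurementSeries]:
    """Simulate all endpoint series for a cohort.

    The AUC C-peptide trajectory is a noisy line,
    ``baseline + slope_i · months(week)``, where ``slope_i`` is the population
    slope with per-subject Gaussian jitter, multiplied by any matching planted
    effect.  Companion clinical endpoints track the subject's AUC excursion
    from baseline through linear couplings; immune markers interpolate a
    per-arm fold-change across the treatment period.  Values that must be
    nonnegative are truncated at zero.
    """
    if not cohort:
        raise ConfigError("cohort must be nonempty")
    config.validate()
    # independent stream from the cohort's so trajectories do not perturb
    # cohort sampling; offset keeps the derived seed below 2**31.
    rng = np.random.default_rng((config.seed * 2 + 1) % (2**31))
    series: list[MeasurementSeries] = []
    post_weeks = [w for w in VISIT_WEEKS]
    for subject in cohort:
        base_auc = float(rng.uniform(*config.baseline_auc_range))
        slope = config.cpep_slope_per_month + float(rng.normal(0.0, config.cpep_slope_sd))
        for rule in config.planted_rules:
            hit = rng.random() < rule.penetrance  # always drawn: keeps the stream aligned
            if rule.matches(subject) and hit and rule.affected_endpoint == AUC_ENDPOINT:
                slope *= rule.effect
        ratio_base = base_auc * 0.8 + 0.1
        insulin_base = subject.baseline_covariates.get("baseline_insulin_dose_per_kg", 0.4)

        auc_values: dict[int, float] = {}
        ratio_values: dict[int, float] = {}
        insulin_values: dict[int, float] = {}
        for w in post_weeks:
            line = base_auc + slope * months(w)
            auc = _truncate(line + float(rng.normal(0.0, config.noise_sd)))
            excursion = line - base_auc
            ratio = _truncate(
                ratio_base
                + config.coupling_ratio * excursion
                + float(rng.normal(0.0, config.noise_sd))
            )
            insulin = _truncate(
                insulin_base
                + config.coupling_insulin * excursion
                + float(rng.normal(0.0, config.noise_sd))
            )
            auc_values[w] = auc
            ratio_values[w] = ratio
            insulin_values[w] = insulin
        series.append(MeasurementSeries(subject.subject_id, AUC_ENDPOINT, auc_values))
        series.append(MeasurementSeries(subject.subject_id, RATIO_ENDPOINT, ratio_values))
        series.append(MeasurementSeries(subject.subject_id, INSULIN_ENDPOINT, insulin_values))

        for marker, per_arm in sorted(config.immune_fold_changes.items()):
            fc = per_arm.get(subject.arm.value, 1.0)
            m_base = float(rng.uniform(*config.immune_baseline_range))
            values: dict[int, float] = {}
            for w in post_weeks:
                frac = 0.0 if w <= 0 else min(w / 24.0, 1.0)
                level = m_base * (1.0 + (fc - 1.0) * frac)
                values[w] = _truncate(level + float(rng.normal(0.0, config.immune_noise_sd * m_base)))
            series.append(MeasurementSeries(subject.subject_id, marker, values))
    return series


def generate_trial(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], list[MeasurementSeries]]:
    """Convenience: cohort + trajectories in one call."""
    cohort = generate_cohort(config)
    return cohort, simulate_trajectories(cohort, config)


def emit_trial(config: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write subjects.csv, measurements.csv and a provenance YAML to ``out_dir``.

    The directory must already exist; reruns with the same config are
    byte-identical.
    """
    if not os.path.isdir(out_dir):
        raise IOError(f"output directory does not exist: {out_dir}")
    cohort, series = generate_trial(config)
    paths = {
        "subjects": os.path.join(out_dir, "subjects.csv"),
        "measurements": os.path.join(out_dir, "measurements.csv"),
        "provenance": os.path.join(out_dir, "provenance.yaml"),
    }
    write_subjects(cohort, paths["subjects"])
    write_measurements(series, paths["measurements"])
    with open(paths["provenance"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(
            {"generator": "trialfca.synthetic_cohort", "config": config.to_dict()},
            fh,
            sort_keys=True,
        )
    return paths
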