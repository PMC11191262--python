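"""Rule quality measures, exact tests, selection filters and dose-focus logic.

Every candidate rule X → Y is scored with five measures over its
complete-case subjects (those measured for every source variable the rule
touches):

* **support** — number of subjects carrying X ∧ Y (a config switch counts
  X-subjects instead, since either reading fits a "patients for whom the
  association was identified" definition);
* **confidence** — P(Y | X) = |ext(X∪Y)| / |ext(X)|;
* **lift** — confidence / P(Y); lift 1 means X carries no information on Y;
* **Fisher p** — two-sided exact test on the X-membership × Y-membership 2×2
  table, summing hypergeometric probabilities ≤ the observed table's
  (minimum-likelihood convention), in exact rational arithmetic;
* **MWW p** — two-sided Mann–Whitney–Wilcoxon comparing the numeric parent
  of the consequent between X and not-X subjects; exact tie-free
  distribution when min(n1, n2) ≤ 8, normal approximation with tie
  correction otherwise.

Selection keeps rules meeting all of support ≥ 4, confidence ≥ 0.75,
lift ≥ 1.25 and p ≤ 0.05 (defaults; p is the minimum of the available
p-values, a switch requires both).  No multiple-testing correction is
applied — the report carries the number of rules tested so users can
post-correct.  The dose-focus analysis keeps rules where a dose descriptor
is *sufficient* (the rule passes as stated) and *necessary* (removing the
dose descriptor breaks confidence or lift).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

from scipy import stats

from .preprocessing import Descriptor
from .rule_mining import CandidateRule, FormalContext
from .trial_data import ConfigError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleMetrics:
    support: int
    confidence: float
    lift: float
    p_fisher: float
    p_mww: float | None
    n_effective: int
    #: extent sizes over the complete-case subjects, kept for identities/audit
    n_antecedent: int = 0
    n_consequent: int = 0


@dataclass(frozen=True)
class ScoredRule:
    rule: CandidateRule
    metrics: RuleMetrics
    #: metrics of the dose-reduced rule, attached by the dose-focus analysis
    reduced_metrics: RuleMetrics | None = None


@dataclass
class QualityThresholds:
    """The selection filters (defaults as used for the headline analysis)."""

    min_support: int = 4
    min_lift: float = 1.25
    min_confidence: float = 0.75
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if self.min_support < 1 or self.min_lift <= 0 or self.max_p <= 0:
            raise ConfigError("thresholds must be positive")
        if not (0 < self.min_confidence <= 1):
            raise ConfigError("min_confidence must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 table, by exact rational summation.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than the observed table's probability.  A zero
    row or column margin makes the table degenerate: p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        log.debug("degenerate 2x2 margin; Fisher p = 1")
        return 1.0
    # all tables with these margins share the denominator C(n, c1), so the
    # two-sided sum works on integer hypergeometric weights
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    w_obs = weights[a]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(tail, comb(n, c1)))


def mann_whitney_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided MWW p for tie-free samples: symmetric-tail counting.

    p = P(|U − n1·n2/2| ≥ |u_obs − n1·n2/2|) under the uniform distribution
    over all C(n1+n2, n1) rank splits, from the exact U distribution.
    """
    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)
    if len(set(pooled)) != len(pooled):
        raise ValidationError("exact branch requires tie-free samples")
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    r1 = sum(ranks[v] for v in x)
    u_obs = r1 - n1 * (n1 + 1) // 2
    m = n1 * n2
    total = comb(n1 + n2, n1)
    dist = _u_distribution(n1, n2)
    dev = abs(2 * u_obs - m)  # doubled deviation from the center m/2, integer
    tail = sum(c for u, c in enumerate(dist) if abs(2 * u - m) >= dev)
    return float(Fraction(tail, total))


@lru_cache(maxsize=512)
def _u_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """Exact null distribution of the MWW U statistic as split counts.

    ``f(i, j, u)`` = number of ways to interleave i group-1 and j group-2
    observations producing U = u; standard recurrence
    f(i, j, u) = f(i−1, j, u−j) + f(i, j−1, u).
    """
    m = n1 * n2
    prev = [[0] * (m + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1  # i = 0
    for i in range(1, n1 + 1):
        cur = [[0] * (m + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1
        for j in range(1, n2 + 1):
            for u in range(m + 1):
                val = prev[j][u - j] if u - j >= 0 else 0
                val += cur[j - 1][u]
                cur[j][u] = val
        prev = cur
    return tuple(prev[n2])


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided MWW p: exact when tie-free and min(n1, n2) ≤ 8, else normal
    approximation with tie correction."""
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs ≥ 2 values")
    pooled = list(x) + list(y)
    has_ties = len(set(pooled)) != len(pooled)
    if not has_ties and min(n1, n2) <= 8:
        return mann_whitney_exact_p(x, y)
    if len(set(pooled)) == 1:
        return 1.0  # no location information at all
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Rule scoring
# ---------------------------------------------------------------------------

def rule_metrics(
    rule: CandidateRule,
    context: FormalContext,
    numeric_values: Mapping[str, Mapping[str, float]] | None = None,
    support_mode: str = "joint",
) -> RuleMetrics | None:
    """Score one rule over its complete-case subjects; ``None`` if unscorable.

    Unscorable cases (empty complete-case set, empty antecedent extent, empty
    consequent extent → undefined lift) are logged and dropped rather than
    raised, so scoring a rule list never aborts.
    """
    if support_mode not in ("joint", "antecedent"):
        raise ConfigError("support_mode must be 'joint' or 'antecedent'")
    variables = {d.name for d in rule.antecedent | rule.consequent}
    case = context.case_mask(variables)
    n_eff = case.bit_count()
    if n_eff == 0:
        log.debug("rule %s: no complete-case subjects", rule)
        return None
    ext_x = context.extent_mask(rule.antecedent, within=case)
    ext_y = context.extent_mask(rule.consequent, within=case)
    nx, ny = ext_x.bit_count(), ext_y.bit_count()
    if nx == 0:
        log.debug("rule %s: empty antecedent extent", rule)
        return None
    if ny == 0:
        log.debug("rule %s: empty consequent extent, lift undefined; dropped", rule)
        return None
    nxy = (ext_x & ext_y).bit_count()
    confidence = nxy / nx
    # single integer division so the lift identity lift·nx·ny = n·support
    # holds exactly in floating point
    lift = (nxy * n_eff) / (nx * ny)
    p_fisher = fisher_exact_two_sided(
        [[nxy, nx - nxy], [ny - nxy, n_eff - nx - ny + nxy]]
    )
    p_mww = _rule_mww_p(rule, context, numeric_values, case, ext_x)
    support = nxy if support_mode == "joint" else nx
    return RuleMetrics(
        support=support,
        confidence=confidence,
        lift=lift,
        p_fisher=p_fisher,
        p_mww=p_mww,
        n_effective=n_eff,
        n_antecedent=nx,
        n_consequent=ny,
    )


def _rule_mww_p(
    rule: CandidateRule,
    context: FormalContext,
    numeric_values: Mapping[str, Mapping[str, float]] | None,
    case_mask: int,
    ext_x: int,
) -> float | None:
    """MWW p on the consequent's numeric parent, X vs not-X; None if not applicable."""
    if numeric_values is None:
        return None
    cons_vars = {d.name for d in rule.consequent}
    if len(cons_vars) != 1:
        return None  # no single numeric parent to compare on
    (var,) = cons_vars
    parent = numeric_values.get(var)
    if parent is None:
        return None
    in_x: list[float] = []
    out_x: list[float] = []
    for i, sid in enumerate(context.subjects):
        if not (case_mask >> i & 1) or sid not in parent:
            continue
        (in_x if ext_x >> i & 1 else out_x).append(parent[sid])
    if len(in_x) < 2 or len(out_x) < 2:
        log.debug("rule %s: MWW group too small, metric absent", rule)
        return None
    return mann_whitney_p(in_x, out_x)


def score_rules(
    rules: Sequence[CandidateRule],
    context: FormalContext,
    numeric_values: Mapping[str, Mapping[str, float]] | None = None,
    support_mode: str = "joint",
) -> list[ScoredRule]:
    scored = []
    for rule in rules:
        m = rule_metrics(rule, context, numeric_values, support_mode)
        if m is not None:
            scored.append(ScoredRule(rule, m))
    return scored


# ---------------------------------------------------------------------------
# Selection and dose focus
# ---------------------------------------------------------------------------

def rule_p_value(metrics: RuleMetrics, p_mode: str = "min") -> float:
    """The p-value used for filtering: min of the available tests, or both."""
    if p_mode == "min":
        return metrics.p_fisher if metrics.p_mww is None else min(
            metrics.p_fisher, metrics.p_mww
        )
    if p_mode == "both":
        return metrics.p_fisher if metrics.p_mww is None else max(
            metrics.p_fisher, metrics.p_mww
        )
    raise ConfigError("p_mode must be 'min' or 'both'")


def passes(metrics: RuleMetrics, thresholds: QualityThresholds, p_mode: str = "min") -> bool:
    return (
        metrics.support >= thresholds.min_support
        and metrics.lift >= thresholds.min_lift
        and metrics.confidence >= thresholds.min_confidence
        and rule_p_value(metrics, p_mode) <= thresholds.max_p
    )


def filter_rules(
    scored: Sequence[ScoredRule],
    thresholds: QualityThresholds | None = None,
    p_mode: str = "min",
) -> list[ScoredRule]:
    """Apply the selection filters; no multiple-testing correction."""
    th = thresholds or QualityThresholds()
    return [sr for sr in scored if passes(sr.metrics, th, p_mode)]


def dose_focus(
    scored: Sequence[ScoredRule],
    dose_descriptors: frozenset[Descriptor],
    context: FormalContext,
    thresholds: QualityThresholds | None = None,
    numeric_values: Mapping[str, Mapping[str, float]] | None = None,
    support_mode: str = "joint",
) -> list[ScoredRule]:
    """Keep rules where a dose descriptor is necessary and sufficient.

    Sufficiency: the rule, as stated (dose descriptor in the antecedent),
    passes the thresholds.  Necessity: the reduced rule — the antecedent with
    dose descriptors removed — fails confidence or lift (or cannot be formed
    or scored at all).  Both versions' metrics are reported.
    """
    th = thresholds or QualityThresholds()
    out: list[ScoredRule] = []
    for sr in scored:
        dose_part = sr.rule.antecedent & dose_descriptors
        if not dose_part:
            continue
        if not passes(sr.metrics, th):
            continue
        reduced_ant = sr.rule.antecedent - dose_descriptors
        if not reduced_ant:
            out.append(ScoredRule(sr.rule, sr.metrics, None))
            continue
        reduced = CandidateRule(reduced_ant, sr.rule.consequent)
        rm = rule_metrics(reduced, context, numeric_values, support_mode)
        necessary = rm is None or not (
            rm.confidence >= th.min_confidence and rm.lift >= th.min_lift
        )
        if necessary:
            out.append(ScoredRule(sr.rule, sr.metrics, rm))
    return out
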