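"""Quality measures, exact Fisher/MWW tests, filtering and dose focus."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from trialfca import (
    CandidateRule,
    QualityThresholds,
    ValidationError,
    build_context,
    dose_focus,
    filter_rules,
    fisher_exact_two_sided,
    mann_whitney_p,
    rule_metrics,
    score_rules,
)
from trialfca.preprocessing import Descriptor, DescriptorTable
from trialfca.rule_stats import (
    RuleMetrics,
    ScoredRule,
    mann_whitney_exact_p,
    rule_p_value,
)

from conftest import random_context


def d(name, cat="x"):
    return Descriptor(name, cat)


def _context(rows: dict[str, list[str]]):
    table = DescriptorTable()
    table.subject_ids = list(rows)
    names = sorted({n for descs in rows.values() for n in descs})
    for sid, descs in rows.items():
        for name in descs:
            table.add(sid, name, "x", ("x",))
    for name in names:
        table.measured[name] = set(rows)
    return build_context(table)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_on_constructed_eight_subject_context():
    """|ext(X)|=4, |ext(Y)|=4, |ext(X∧Y)|=3 → support 3, confidence .75, lift 1.5."""
    rows = {
        "s1": ["X", "Y"], "s2": ["X", "Y"], "s3": ["X", "Y"], "s4": ["X"],
        "s5": ["Y"], "s6": [], "s7": [], "s8": [],
    }
    ctx = _context(rows)
    m = rule_metrics(CandidateRule(frozenset({d("X")}), frozenset({d("Y")})), ctx)
    assert m.support == 3
    assert m.confidence == pytest.approx(0.75)
    assert m.lift == pytest.approx(1.5)
    assert m.n_effective == 8
    # alternative support reading counts antecedent subjects
    m2 = rule_metrics(
        CandidateRule(frozenset({d("X")}), frozenset({d("Y")})), ctx,
        support_mode="antecedent",
    )
    assert m2.support == 4


def test_universal_consequent_gives_lift_one():
    rows = {f"s{i}": ["Y"] + (["X"] if i < 3 else []) for i in range(8)}
    ctx = _context(rows)
    m = rule_metrics(CandidateRule(frozenset({d("X")}), frozenset({d("Y")})), ctx)
    assert m.confidence == 1.0
    assert m.lift == pytest.approx(1.0)


def test_independent_antecedent_consequent_lift_one():
    # ext(X)=4, ext(Y)=4, ext(XY)=2 over n=8 → conf .5 = P(Y) → lift 1
    rows = {
        "s1": ["X", "Y"], "s2": ["X", "Y"], "s3": ["X"], "s4": ["X"],
        "s5": ["Y"], "s6": ["Y"], "s7": [], "s8": [],
    }
    m = rule_metrics(CandidateRule(frozenset({d("X")}), frozenset({d("Y")})),
                     _context(rows))
    assert m.lift == pytest.approx(1.0)


def test_empty_consequent_extent_drops_rule():
    rows = {"s1": ["X"], "s2": ["X"], "s3": []}
    table = DescriptorTable()
    table.subject_ids = list(rows)
    for sid, descs in rows.items():
        for name in descs:
            table.add(sid, name, "x", ("x",))
    table.variables["Y"] = ("x",)
    table.measured["Y"] = set(rows)
    table.measured["X"] = set(rows)
    ctx = build_context(table)
    assert rule_metrics(CandidateRule(frozenset({d("X")}), frozenset({d("Y")})), ctx) is None


def test_metric_identity_on_random_contexts(rng):
    """lift·|ext(X)|·|ext(Y)| == n·support exactly, for every scored rule."""
    from trialfca.rule_mining import brute_force_rules

    for _ in range(30):
        ctx = random_context(rng, with_missing=bool(rng.integers(0, 2)))
        for rule, _ in brute_force_rules(ctx, 1, 2):
            m = rule_metrics(rule, ctx)
            if m is None:
                continue
            lhs = Fraction(m.support, m.n_antecedent) / Fraction(m.n_consequent, m.n_effective)
            assert float(lhs) == pytest.approx(m.lift, abs=1e-12)
            assert lhs * m.n_antecedent * m.n_consequent == m.n_effective * m.support


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _fisher_oracle(a, b, c, g):
    """Independent enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + g, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    total = Fraction(0)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), comb(n, c1))
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))
        if p_k <= p_obs:
            total += p_k
    return total


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[3, 1], [1, 3]], Fraction(34, 70)),
        ([[4, 0], [0, 4]], Fraction(2, 70)),
        ([[0, 4], [4, 0]], Fraction(2, 70)),
    ],
)
def test_fisher_known_tables(table, expected):
    assert fisher_exact_two_sided(table) == pytest.approx(float(expected), abs=1e-15)


def test_fisher_degenerate_margins():
    assert fisher_exact_two_sided([[0, 3], [0, 5]]) == 1.0
    assert fisher_exact_two_sided([[0, 0], [2, 3]]) == 1.0


def test_fisher_matches_scipy_sample(rng):
    for _ in range(200):
        a, b, c, g = rng.integers(0, 10, size=4)
        table = [[int(a), int(b)], [int(c), int(g)]]
        if sum(table[0]) + sum(table[1]) == 0:
            continue
        ours = fisher_exact_two_sided(table)
        theirs = stats.fisher_exact(table, alternative="two-sided")[1]
        assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-9)


def test_fisher_exhaustive_oracle_small():
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    g = n - a - b - c
                    assert fisher_exact_two_sided([[a, b], [c, g]]) == pytest.approx(
                        float(_fisher_oracle(a, b, c, g)), abs=1e-14
                    )


# ---------------------------------------------------------------------------
# Mann–Whitney–Wilcoxon
# ---------------------------------------------------------------------------

def _mww_oracle(x, y):
    """All-rank-splits permutation oracle (symmetric tail)."""
    pooled = sorted(x + y)
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) // 2
    m = n1 * len(y)
    dev = abs(Fraction(u_obs) - Fraction(m, 2))
    hits = total = 0
    idx = list(range(len(pooled)))
    for chosen in combinations(idx, n1):
        u = sum(i + 1 for i in chosen) - n1 * (n1 + 1) // 2
        total += 1
        if abs(Fraction(u) - Fraction(m, 2)) >= dev:
            hits += 1
    return Fraction(hits, total)


def test_mww_separated_groups():
    assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-15)


def test_mww_identical_groups_p_one():
    assert mann_whitney_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert mann_whitney_p([2.0, 2.0], [2.0, 2.0]) == 1.0


def test_mww_small_group_raises():
    with pytest.raises(ValidationError):
        mann_whitney_p([1.0], [2.0, 3.0])


def test_mww_exact_requires_tie_free():
    with pytest.raises(ValidationError):
        mann_whitney_exact_p([1.0, 1.0], [2.0, 3.0])


def test_mww_exact_matches_permutation_oracle(rng):
    for _ in range(60):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 7 - min(n1, 4) + 4))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
        x, y = list(vals[:n1]), list(vals[n1:])
        assert mann_whitney_exact_p(x, y) == pytest.approx(
            float(_mww_oracle(x, y)), abs=1e-14
        )


def test_mww_tie_branch_uses_corrected_normal():
    x, y = [1.0, 2.0, 2.0, 3.0, 8.0], [2.0, 4.0, 5.0, 6.0, 7.0]
    ours = mann_whitney_p(x, y)
    theirs = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert ours == pytest.approx(float(theirs), abs=1e-12)


# ---------------------------------------------------------------------------
# filtering + dose focus
# ---------------------------------------------------------------------------

def _mk(support, conf, lift, p_fisher, p_mww=None):
    rule = CandidateRule(frozenset({d("A")}), frozenset({d("B")}))
    return ScoredRule(rule, RuleMetrics(support, conf, lift, p_fisher, p_mww, 20, 5, 5))


def test_filter_threshold_logic():
    th = QualityThresholds()
    assert filter_rules([_mk(3, 1.0, 2.0, 0.01)], th) == []      # support
    kept = filter_rules([_mk(5, 0.8, 1.3, 0.04)], th)
    assert len(kept) == 1
    assert filter_rules([], th) == []
    assert filter_rules([_mk(5, 0.8, 1.3, 0.2)], th) == []       # p
    assert filter_rules([_mk(5, 0.6, 1.3, 0.04)], th) == []      # confidence
    assert filter_rules([_mk(5, 0.8, 1.1, 0.04)], th) == []      # lift


def test_p_value_modes():
    m = _mk(5, 0.8, 1.3, 0.2, p_mww=0.03).metrics
    assert rule_p_value(m, "min") == 0.03
    assert rule_p_value(m, "both") == 0.2
    assert filter_rules([_mk(5, 0.8, 1.3, 0.2, 0.03)]) != []
    assert filter_rules([_mk(5, 0.8, 1.3, 0.2, 0.03)], p_mode="both") == []


def test_filter_is_antitone_in_thresholds(rng):
    """Raising any threshold never adds a rule."""
    pool = [
        _mk(int(s), float(c), float(l), float(p))
        for s, c, l, p in zip(
            rng.integers(1, 10, 40), rng.uniform(0.3, 1.0, 40),
            rng.uniform(0.5, 3.0, 40), rng.uniform(0.0, 0.4, 40),
        )
    ]
    base = QualityThresholds()
    kept = {id(sr) for sr in filter_rules(pool, base)}
    tighter = [
        QualityThresholds(min_support=5),
        QualityThresholds(min_lift=1.5),
        QualityThresholds(min_confidence=0.9),
        QualityThresholds(max_p=0.01),
    ]
    for th in tighter:
        assert {id(sr) for sr in filter_rules(pool, th)} <= kept


def _dose_context():
    # dose ∧ marker → outcome strongly; marker alone is weak
    rows = {}
    for i in range(4):       # dose + marker + outcome
        rows[f"a{i}"] = ["dose", "marker", "out"]
    for i in range(4):       # marker alone, outcome rare
        rows[f"b{i}"] = ["marker"] + (["out"] if i == 0 else [])
    for i in range(4):
        rows[f"c{i}"] = []
    return _context(rows)


def test_dose_focus_keeps_necessary_and_sufficient():
    ctx = _dose_context()
    rule = CandidateRule(frozenset({d("dose"), d("marker")}), frozenset({d("out")}))
    scored = score_rules([rule], ctx)
    kept = dose_focus(scored, frozenset({d("dose")}), ctx)
    assert len(kept) == 1
    assert kept[0].reduced_metrics is not None
    assert kept[0].reduced_metrics.confidence < 0.75  # dose was necessary


def test_dose_focus_drops_rules_without_dose():
    ctx = _dose_context()
    rule = CandidateRule(frozenset({d("marker")}), frozenset({d("out")}))
    scored = score_rules([rule], ctx)
    assert dose_focus(scored, frozenset({d("dose")}), ctx) == []


def test_dose_focus_drops_when_reduced_rule_still_passes():
    # outcome follows marker perfectly; dose adds nothing
    rows = {f"a{i}": ["dose", "marker", "out"] for i in range(4)}
    rows.update({f"b{i}": ["marker", "out"] for i in range(4)})
    rows.update({f"c{i}": [] for i in range(4)})
    ctx = _context(rows)
    rule = CandidateRule(frozenset({d("dose"), d("marker")}), frozenset({d("out")}))
    scored = score_rules([rule], ctx)
    assert scored and scored[0].metrics.confidence == 1.0
    assert dose_focus(scored, frozenset({d("dose")}), ctx) == []
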