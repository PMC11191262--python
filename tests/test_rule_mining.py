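"""Galois closure laws, Close-by-One enumeration and the brute-force oracle."""

from itertools import combinations

import numpy as np
import pytest

from trialfca import (
    CandidateRule,
    MiningConstraints,
    ValidationError,
    brute_force_rules,
    build_context,
    closure,
    enumerate_closed_itemsets,
    generate_rules,
)
from trialfca.preprocessing import Descriptor, DescriptorTable
from trialfca.rule_mining import ContextError, minimal_generators
from trialfca.trial_data import OracleScopeError

from conftest import random_context


def _context_from_rows(rows: dict[str, list[str]], categories=("x",)):
    """Context where each listed descriptor name is a one-category variable."""
    table = DescriptorTable()
    table.subject_ids = list(rows)
    names = sorted({n for descs in rows.values() for n in descs})
    for sid, descs in rows.items():
        for name in names:
            table.measured.setdefault(name, set()).add(sid)
        for name in descs:
            table.add(sid, name, "x", ("x",))
    # table.add also marks measured; ensure full measurement for all vars
    for name in names:
        table.variables.setdefault(name, ("x",))
        table.measured[name] = set(rows)
    return build_context(table)


def _staircase_context():
    # subject i carries descriptors d1..di
    return _context_from_rows(
        {f"s{i}": [f"d{j}" for j in range(1, i + 1)] for i in range(1, 5)}
    )


def d(name):
    return Descriptor(name, "x")


def test_closure_of_empty_set_is_common_descriptors():
    ctx = _staircase_context()
    assert closure([], ctx) == {d("d1")}  # d1 held by every subject


def test_closure_on_staircase_toy():
    ctx = _staircase_context()
    assert closure([d("d2")], ctx) == {d("d1"), d("d2")}
    assert closure([d("d4")], ctx) == {d("d1"), d("d2"), d("d3"), d("d4")}


def test_closure_unknown_descriptor_raises():
    ctx = _staircase_context()
    with pytest.raises(ContextError):
        closure([Descriptor("zz", "x")], ctx)


def test_galois_laws_on_random_contexts(rng):
    """Extensivity, monotonicity, idempotence over ≥ 500 random contexts."""
    for _ in range(500):
        ctx = random_context(rng)
        descs = list(ctx.descriptors)
        k = int(rng.integers(0, min(4, len(descs)) + 1))
        s = frozenset(rng.choice(len(descs), size=k, replace=False).tolist())
        S = frozenset(descs[i] for i in s)
        clS = ctx.closure(S)
        assert S <= clS  # extensive
        assert ctx.closure(clS) == clS  # idempotent
        extra = int(rng.integers(0, len(descs)))
        assert clS <= ctx.closure(S | {descs[extra]})  # monotone


def test_concept_count_matches_distinct_closures(rng):
    """CbO finds exactly the distinct closures of all attribute subsets."""
    for _ in range(25):
        ctx = random_context(rng, n_subjects=8, n_descriptors=8)
        descs = list(ctx.descriptors)
        assert len(descs) <= 10
        all_closures = set()
        for r in range(len(descs) + 1):
            for combo in combinations(descs, r):
                all_closures.add(ctx.closure(combo))
        concepts = enumerate_closed_itemsets(ctx, min_support=1)
        mined = {c.intent for c in concepts}
        # closures with empty extent are only reachable if some subset has
        # empty common-object set; CbO prunes below min_support=1
        reachable = {cl for cl in all_closures if ctx.extent_mask(cl).bit_count() >= 1}
        assert mined == reachable


def test_concept_closure_fixed_point(rng):
    ctx = random_context(rng, n_subjects=10, n_descriptors=10)
    for c in enumerate_closed_itemsets(ctx, min_support=1):
        assert ctx.closure(c.intent) == c.intent
        assert ctx.subjects_from_mask(ctx.extent_mask(c.intent)) == c.extent


def test_uniform_context_single_concept():
    ctx = _context_from_rows({f"s{i}": ["d1", "d2", "d3"] for i in range(4)})
    concepts = enumerate_closed_itemsets(ctx, min_support=1)
    assert len(concepts) == 1
    assert concepts[0].intent == {d("d1"), d("d2"), d("d3")}
    assert len(concepts[0].extent) == 4


def test_diagonal_context_concepts_by_brute_force():
    ctx = _context_from_rows({"s1": ["d1"], "s2": ["d2"], "s3": ["d3"]})
    concepts = enumerate_closed_itemsets(ctx, min_support=1)
    intents = {c.intent for c in concepts}
    # brute force: distinct closures with nonempty extent = empty set + singletons
    assert intents == {
        frozenset(),
        frozenset({d("d1")}),
        frozenset({d("d2")}),
        frozenset({d("d3")}),
    }


def test_min_support_above_n_yields_nothing():
    ctx = _staircase_context()
    assert enumerate_closed_itemsets(ctx, min_support=10) == []
    with pytest.raises(ValidationError):
        enumerate_closed_itemsets(ctx, min_support=0)


def test_enumeration_deterministic(rng):
    ctx = random_context(rng, n_subjects=12, n_descriptors=10)
    a = enumerate_closed_itemsets(ctx, min_support=2)
    b = enumerate_closed_itemsets(ctx, min_support=2)
    assert a == b


def test_minimal_generators_reproduce_extent():
    ctx = _staircase_context()
    intent = ctx.closure([d("d3")])
    gens = minimal_generators(intent, ctx)
    assert frozenset({d("d3")}) in gens
    target = ctx.extent_mask(intent)
    for g in gens:
        assert ctx.extent_mask(g) == target
        for item in g:  # minimality
            assert ctx.extent_mask(g - {item}) != target


def test_single_concept_context_yields_no_rules():
    ctx = _context_from_rows({"s1": ["d1"], "s2": ["d1"]})
    concepts = enumerate_closed_itemsets(ctx, min_support=1)
    rules = generate_rules(concepts, ctx)
    assert rules == []


def test_diagonal_context_no_confident_cross_rules():
    ctx = _context_from_rows({"s1": ["d1"], "s2": ["d2"], "s3": ["d3"]})
    for rule, (support, conf, lift, n) in brute_force_rules(ctx, min_support=1):
        # disjoint singletons never co-occur, so no rule reaches the oracle
        raise AssertionError(f"unexpected scored rule {rule}")


def test_consequent_vocab_constraint():
    ctx = _staircase_context()
    concepts = enumerate_closed_itemsets(ctx, min_support=1)
    vocab = frozenset({d("d3")})
    rules = generate_rules(concepts, ctx, MiningConstraints(consequent_vocab=vocab))
    assert rules
    for r in rules:
        assert r.consequent <= vocab


def test_rule_validation():
    with pytest.raises(ValidationError):
        CandidateRule(frozenset(), frozenset({d("d1")}))
    with pytest.raises(ValidationError):
        CandidateRule(frozenset({d("d1")}), frozenset({d("d1")}))


def test_oracle_scope_guard():
    table = DescriptorTable()
    table.subject_ids = [f"s{i}" for i in range(21)]
    for sid in table.subject_ids:
        table.add(sid, "v", "x", ("x",))
    ctx = build_context(table)
    with pytest.raises(OracleScopeError):
        brute_force_rules(ctx)


def test_empty_table_is_context_error():
    with pytest.raises(ContextError):
        build_context(DescriptorTable())


def test_duplicate_entry_rejected():
    table = DescriptorTable()
    table.subject_ids = ["s1"]
    table.add("s1", "v", "x", ("x", "y"))
    table.entries.append(("s1", Descriptor("v", "x")))
    with pytest.raises(ValidationError):
        build_context(table)


def test_two_categories_of_one_variable_rejected():
    table = DescriptorTable()
    table.subject_ids = ["s1"]
    table.add("s1", "v", "x", ("x", "y"))
    table.entries.append(("s1", Descriptor("v", "y")))
    with pytest.raises(ValidationError):
        build_context(table)


def test_masked_cells_for_unmeasured_variable():
    table = DescriptorTable()
    table.subject_ids = ["s1", "s2"]
    table.add("s1", "v", "x", ("x", "y"))
    table.add("s1", "w", "x", ("x", "y"))
    table.add("s2", "w", "y", ("x", "y"))  # s2 unmeasured for v
    ctx = build_context(table)
    case = ctx.case_mask({"v"})
    assert ctx.subjects_from_mask(case) == {"s1"}
    assert ctx.subjects_from_mask(ctx.case_mask({"w"})) == {"s1", "s2"}


def _mined_with_metrics(ctx, min_support=1, max_size=2):
    from trialfca.rule_stats import score_rules

    concepts = enumerate_closed_itemsets(ctx, min_support=min_support)
    rules = generate_rules(
        concepts, ctx,
        MiningConstraints(max_antecedent_size=max_size, max_consequent_size=max_size),
    )
    return score_rules(rules, ctx)


def test_mined_metrics_match_oracle_on_random_contexts(rng):
    """Every mined rule's (support, confidence, lift, n) equals the oracle's."""
    for _ in range(40):
        ctx = random_context(rng, n_subjects=int(rng.integers(4, 13)),
                             n_descriptors=int(rng.integers(4, 11)))
        oracle = {
            (r.antecedent, r.consequent): m for r, m in brute_force_rules(ctx, 1, 2)
        }
        for sr in _mined_with_metrics(ctx):
            key = (sr.rule.antecedent, sr.rule.consequent)
            if key not in oracle:
                # oracle skipped it only if outside its size cap
                assert len(sr.rule.antecedent) > 2 or len(sr.rule.consequent) > 2
                continue
            support, conf, lift, n = oracle[key]
            m = sr.metrics
            assert m.support == support
            assert m.confidence == pytest.approx(conf, abs=1e-12)
            assert m.lift == pytest.approx(lift, abs=1e-12)
            assert m.n_effective == n
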