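"""Formal concept analysis: context construction, closure, concept and rule
enumeration.

A *formal context* is a binary subject × descriptor incidence matrix.  The
Galois maps — common objects of a descriptor set, common descriptors of an
object set — compose into a closure operator; its fixed points are the
*formal concepts* (extent, intent), i.e. maximal subject×descriptor
rectangles.  Concepts are enumerated with Close-by-One in lectic order,
pruned by minimum extent size, which yields every closed descriptor set
exactly once.

Candidate association rules X → Y are generated over closed sets only (the
non-redundant basis): for closed B ⊂ B′ the rule "B → B′∖B", with minimal
generators of B standing in for B when antecedent size is capped, plus the
exact (confidence-1) rules from a concept's generators to the rest of its
intent.  A brute-force enumerator over all small subset pairs serves as an
independent oracle in tests; it deliberately shares no code with the miner.

Missingness is first-class: a subject with an unmeasured source variable is
neither a positive nor a negative instance of that variable's categories, and
rule statistics later restrict to complete cases per rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import Descriptor, DescriptorTable
from .trial_data import OracleScopeError, TrialError, ValidationError


class ContextError(TrialError):
    """The descriptor table cannot form a valid context."""


@dataclass(frozen=True)
class FormalConcept:
    """A closed subject-set / descriptor-set pair (extent, intent)."""

    extent: frozenset[str]
    intent: frozenset[Descriptor]


@dataclass(frozen=True)
class CandidateRule:
    """An association rule X → Y over disjoint nonempty descriptor sets."""

    antecedent: frozenset[Descriptor]
    consequent: frozenset[Descriptor]

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValidationError("rule parts must be nonempty")
        if self.antecedent & self.consequent:
            raise ValidationError("antecedent and consequent must be disjoint")


class FormalContext:
    """Binary incidence matrix with per-variable missingness.

    Rows are subjects ordered by id; columns are descriptors ordered
    lexicographically by (name, category).  Extents are manipulated as
    integer bitmasks over subject indices for speed.
    """

    def __init__(
        self,
        subjects: Sequence[str],
        descriptors: Sequence[Descriptor],
        incidence: np.ndarray,
        measured: dict[str, frozenset[str]],
    ) -> None:
        self.subjects: tuple[str, ...] = tuple(subjects)
        self.descriptors: tuple[Descriptor, ...] = tuple(descriptors)
        self.incidence = np.asarray(incidence, dtype=bool)
        if self.incidence.shape != (len(self.subjects), len(self.descriptors)):
            raise ContextError("incidence shape does not match subjects × descriptors")
        self._sub_index = {s: i for i, s in enumerate(self.subjects)}
        self._desc_index = {d: j for j, d in enumerate(self.descriptors)}
        self.variable_of: tuple[str, ...] = tuple(d.name for d in self.descriptors)
        self.measured = measured
        self._col_masks: list[int] = []
        for j in range(len(self.descriptors)):
            mask = 0
            for i in np.flatnonzero(self.incidence[:, j]):
                mask |= 1 << int(i)
            self._col_masks.append(mask)
        self._case_masks: dict[str, int] = {}
        for var, sids in measured.items():
            mask = 0
            for s in sids:
                if s in self._sub_index:
                    mask |= 1 << self._sub_index[s]
            self._case_masks[var] = mask
        self._all_mask = (1 << len(self.subjects)) - 1

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptors)

    def descriptor_index(self, d: Descriptor) -> int:
        try:
            return self._desc_index[d]
        except KeyError:
            raise ContextError(f"unknown descriptor {d}") from None

    def column_mask(self, j: int) -> int:
        return self._col_masks[j]

    def all_subjects_mask(self) -> int:
        return self._all_mask

    def case_mask(self, variables: Iterable[str]) -> int:
        """Bitmask of subjects measured for *all* the given source variables."""
        mask = self._all_mask
        for var in set(variables):
            mask &= self._case_masks.get(var, self._all_mask)
        return mask

    def subjects_from_mask(self, mask: int) -> frozenset[str]:
        return frozenset(
            self.subjects[i] for i in range(len(self.subjects)) if mask >> i & 1
        )

    # -- Galois maps -------------------------------------------------------
    def extent_mask(self, descs: Iterable[Descriptor], within: int | None = None) -> int:
        mask = self._all_mask if within is None else within
        for d in descs:
            mask &= self._col_masks[self.descriptor_index(d)]
        return mask

    def intent_of_mask(self, extent: int) -> frozenset[Descriptor]:
        out = []
        for j, col in enumerate(self._col_masks):
            if extent & col == extent:
                out.append(self.descriptors[j])
        return frozenset(out)

    def closure(self, descs: Iterable[Descriptor]) -> frozenset[Descriptor]:
        """Galois closure: common descriptors of the common subjects."""
        return self.intent_of_mask(self.extent_mask(descs))

    def project(self, keep: Iterable[Descriptor]) -> "FormalContext":
        """Sub-context restricted to the given descriptor columns."""
        keep_set = set(keep)
        cols = [j for j, d in enumerate(self.descriptors) if d in keep_set]
        if not cols:
            raise ContextError("projection keeps no descriptors")
        variables = {self.descriptors[j].name for j in cols}
        return FormalContext(
            self.subjects,
            [self.descriptors[j] for j in cols],
            self.incidence[:, cols],
            {v: self.measured[v] for v in variables if v in self.measured},
        )


def build_context(table: DescriptorTable) -> FormalContext:
    """Materialize a descriptor table as a formal context.

    Columns are ordered lexicographically by (name, category) and rows by
    subject id; duplicate (subject, descriptor) entries are rejected.
    """
    if not table.entries:
        raise ContextError("descriptor table is empty")
    subjects = sorted(set(table.subject_ids) | {sid for sid, _ in table.entries})
    descriptors = sorted(
        {Descriptor(var, c) for var, cats in table.variables.items() for c in cats},
        key=lambda d: (d.name, d.category),
    )
    sub_index = {s: i for i, s in enumerate(subjects)}
    desc_index = {d: j for j, d in enumerate(descriptors)}
    incidence = np.zeros((len(subjects), len(descriptors)), dtype=bool)
    seen: set[tuple[str, Descriptor]] = set()
    per_var: dict[tuple[str, str], str] = {}
    for sid, d in table.entries:
        if (sid, d) in seen:
            raise ValidationError(f"duplicate descriptor entry ({sid}, {d})")
        seen.add((sid, d))
        key = (sid, d.name)
        if key in per_var and per_var[key] != d.category:
            raise ValidationError(
                f"subject {sid} carries two categories of variable {d.name}"
            )
        per_var[key] = d.category
        incidence[sub_index[sid], desc_index[d]] = True
    measured = {var: frozenset(sids) for var, sids in table.measured.items()}
    return FormalContext(subjects, descriptors, incidence, measured)


# ---------------------------------------------------------------------------
# Concept enumeration (Close-by-One)
# ---------------------------------------------------------------------------

def enumerate_closed_itemsets(
    context: FormalContext,
    min_support: int = 1,
    max_size: int | None = None,
) -> list[FormalConcept]:
    """All closed descriptor sets with extent ≥ min_support, in lectic order.

    Close-by-One: descend attribute indices in increasing order, closing each
    candidate and applying the canonicity test (the closure must not add an
    attribute below the current one).  ``max_size`` filters the *reported*
    intents by size; enumeration itself is pruned only by support, since a
    closure can always exceed a size cap transiently.
    """
    if min_support < 1:
        raise ValidationError("min_support must be ≥ 1")
    m = context.n_descriptors
    col = [context.column_mask(j) for j in range(m)]
    all_mask = context.all_subjects_mask()
    results: list[tuple[int, frozenset[Descriptor]]] = []

    def close(extent: int) -> tuple[int, ...]:
        return tuple(j for j in range(m) if extent & col[j] == extent)

    def record(extent: int, intent: tuple[int, ...]) -> None:
        if max_size is None or len(intent) <= max_size:
            results.append(
                (extent, frozenset(context.descriptors[j] for j in intent))
            )

    def cbo(extent: int, intent: tuple[int, ...], start: int) -> None:
        intent_set = set(intent)
        for j in range(start, m):
            if j in intent_set:
                continue
            new_extent = extent & col[j]
            if new_extent.bit_count() < min_support:
                continue
            new_intent = close(new_extent)
            if any(k < j and k not in intent_set for k in new_intent):
                continue  # canonicity: this closure is reached elsewhere
            record(new_extent, new_intent)
            cbo(new_extent, new_intent, j + 1)

    top_intent = close(all_mask)
    if all_mask.bit_count() >= min_support:
        record(all_mask, top_intent)
    cbo(all_mask, top_intent, 0)
    return [
        FormalConcept(context.subjects_from_mask(extent), intent)
        for extent, intent in results
    ]


def closure(descs: Iterable[Descriptor], context: FormalContext) -> frozenset[Descriptor]:
    """Module-level convenience wrapper for :meth:`FormalContext.closure`."""
    return context.closure(descs)


# ---------------------------------------------------------------------------
# Rule generation over the closed-set basis
# ---------------------------------------------------------------------------

@dataclass
class MiningConstraints:
    """Caps and vocabularies restricting candidate-rule generation."""

    max_antecedent_size: int | None = 3
    max_consequent_size: int | None = 2
    #: if set, every antecedent descriptor must belong to this set
    antecedent_vocab: frozenset[Descriptor] | None = None
    #: if set, every consequent descriptor must belong to this set
    consequent_vocab: frozenset[Descriptor] | None = None

    def antecedent_ok(self, descs: frozenset[Descriptor]) -> bool:
        if self.max_antecedent_size is not None and len(descs) > self.max_antecedent_size:
            return False
        return self.antecedent_vocab is None or descs <= self.antecedent_vocab

    def consequent_ok(self, descs: frozenset[Descriptor]) -> bool:
        if self.max_consequent_size is not None and len(descs) > self.max_consequent_size:
            return False
        return self.consequent_vocab is None or descs <= self.consequent_vocab


def minimal_generators(
    intent: frozenset[Descriptor],
    context: FormalContext,
    max_size: int | None = None,
) -> list[frozenset[Descriptor]]:
    """Minimal subsets of a closed intent with the same extent (generators)."""
    target = context.extent_mask(intent)
    ordered = sorted(intent, key=lambda d: (d.name, d.category))
    cap = len(ordered) if max_size is None else min(max_size, len(ordered))
    gens: list[frozenset[Descriptor]] = []
    for size in range(1, cap + 1):
        for combo in combinations(ordered, size):
            cand = frozenset(combo)
            if any(g <= cand for g in gens):
                continue
            if context.extent_mask(cand) == target:
                gens.append(cand)
    return gens


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


def _minimal_sub_masks(
    pool_bits: list[int],
    cap: int,
    accepts,
) -> list[int]:
    """Minimal subsets (as bitmasks) of ``pool_bits``, up to ``cap`` items,
    satisfying the monotone predicate ``accepts``."""
    found: list[int] = []
    for size in range(1, min(cap, len(pool_bits)) + 1):
        for combo in combinations(pool_bits, size):
            m = 0
            for b in combo:
                m |= 1 << b
            if any(f & m == f for f in found):
                continue
            if accepts(m):
                found.append(m)
    return found


def generate_rules(
    concepts: Sequence[FormalConcept],
    context: FormalContext,
    constraints: MiningConstraints | None = None,
) -> list[CandidateRule]:
    """Candidate rules over the closed-set basis, deterministically ordered.

    For every pair of closed intents B ⊂ B′ with strictly smaller extent,
    rules "generator(B) → Z" are emitted for each *minimal consequent
    generator* Z — a smallest subset of B′∖B whose addition to B pins down
    B′ — which keeps the basis complete under a consequent-size cap; the
    full difference B′∖B is also emitted when it fits the cap.  For every
    concept, exact (confidence-1) rules "generator → z" are emitted per
    remaining intent member.  Constraints filter on sizes and vocabularies;
    duplicates are collapsed.
    """
    cons = constraints or MiningConstraints()
    m = context.n_descriptors
    descs = context.descriptors
    col = [context.column_mask(j) for j in range(m)]
    full_vocab = (1 << m) - 1
    ant_vocab = full_vocab if cons.antecedent_vocab is None else sum(
        1 << j for j, d in enumerate(descs) if d in cons.antecedent_vocab
    )
    cons_vocab = full_vocab if cons.consequent_vocab is None else sum(
        1 << j for j, d in enumerate(descs) if d in cons.consequent_vocab
    )
    ant_cap = m if cons.max_antecedent_size is None else cons.max_antecedent_size
    cons_cap = m if cons.max_consequent_size is None else cons.max_consequent_size

    def extent_of(imask: int) -> int:
        e = context.all_subjects_mask()
        for b in _bits(imask):
            e &= col[b]
        return e

    intents: list[int] = []
    extents: list[int] = []
    for c in concepts:
        imask = 0
        for d in c.intent:
            imask |= 1 << context.descriptor_index(d)
        intents.append(imask)
        extents.append(extent_of(imask))

    gen_cache: dict[int, list[int]] = {}

    def gens_of(imask: int, target_extent: int) -> list[int]:
        """Minimal antecedent generators within the vocabulary and size cap."""
        if imask not in gen_cache:
            pool = [b for b in _bits(imask) if ant_vocab >> b & 1]
            gen_cache[imask] = _minimal_sub_masks(
                pool, ant_cap, lambda g: extent_of(g) == target_extent
            )
        return gen_cache[imask]

    out: set[tuple[int, int]] = set()

    # exact rules within each concept (singleton consequents suffice: any
    # larger subset of the intent has the same extent)
    for imask, emask in zip(intents, extents):
        if not imask:
            continue
        for g in gens_of(imask, emask):
            rest = imask & ~g
            if not rest:
                continue
            for b in _bits(rest & cons_vocab):
                out.add((g, 1 << b))
            if rest & cons_vocab == rest and rest.bit_count() <= cons_cap:
                out.add((g, rest))

    # between-concept rules along the subset order
    order = sorted(range(len(intents)), key=lambda i: intents[i].bit_count())
    for i in order:
        i1, e1 = intents[i], extents[i]
        if not i1:
            continue
        gens1 = gens_of(i1, e1)
        if not gens1:
            continue
        for j in order:
            i2, e2 = intents[j], extents[j]
            if i1 == i2 or i1 & i2 != i1 or e1 == e2:
                continue
            diff = i2 & ~i1
            diff_pool = _bits(diff & cons_vocab)
            for z in _minimal_sub_masks(
                diff_pool, cons_cap, lambda zm: extent_of(i1 | zm) == e2
            ):
                for g in gens1:
                    out.add((g, z))
            if diff & cons_vocab == diff and diff.bit_count() <= cons_cap:
                for g in gens1:
                    out.add((g, diff))

    def to_rule(pair: tuple[int, int]) -> CandidateRule:
        g, z = pair
        return CandidateRule(
            frozenset(descs[b] for b in _bits(g)),
            frozenset(descs[b] for b in _bits(z)),
        )

    def key(rule: CandidateRule) -> tuple:
        return (
            tuple(sorted((d.name, d.category) for d in rule.antecedent)),
            tuple(sorted((d.name, d.category) for d in rule.consequent)),
        )

    return sorted((to_rule(p) for p in out), key=key)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_rules(
    context: FormalContext,
    min_support: int = 1,
    max_size: int = 2,
) -> list[tuple[CandidateRule, tuple[int, float, float, int]]]:
    """Exhaustive (X, Y) enumeration with directly-counted metrics.

    Intended as a test oracle on tiny contexts only (≤ 20 subjects, ≤ 15
    descriptors).  Metrics are computed by plain row counting over the
    complete-case subjects of each rule, independent of the bitmask machinery:
    returns (support, confidence, lift, n_effective) per rule, skipping rules
    whose antecedent or consequent has empty extent.
    """
    if context.n_subjects > 20 or context.n_descriptors > 15:
        raise OracleScopeError("brute-force oracle limited to 20 subjects × 15 descriptors")
    descs = list(context.descriptors)
    rows: dict[str, set[Descriptor]] = {s: set() for s in context.subjects}
    for i, s in enumerate(context.subjects):
        for j, d in enumerate(descs):
            if context.incidence[i, j]:
                rows[s].add(d)
    measured = {var: set(sids) for var, sids in context.measured.items()}

    def cases(variables: set[str]) -> list[str]:
        return [
            s for s in context.subjects
            if all(s in measured.get(v, context.subjects) for v in variables)
        ]

    results = []
    subsets: list[tuple[Descriptor, ...]] = []
    for size in range(1, max_size + 1):
        subsets.extend(combinations(descs, size))
    for xs in subsets:
        x = frozenset(xs)
        for ys in subsets:
            y = frozenset(ys)
            if x & y:
                continue
            variables = {d.name for d in x | y}
            case_subjects = cases(variables)
            n = len(case_subjects)
            if n == 0:
                continue
            nx = sum(1 for s in case_subjects if x <= rows[s])
            ny = sum(1 for s in case_subjects if y <= rows[s])
            nxy = sum(1 for s in case_subjects if x <= rows[s] and y <= rows[s])
            if nx == 0 or ny == 0:
                continue
            if nxy < min_support:
                continue
            confidence = nxy / nx
            lift = (nxy * n) / (nx * ny)
            results.append((CandidateRule(x, y), (nxy, confidence, lift, n)))
    return results
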