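"""Formal concepts and association rules on a small hand-made context.

Eight subjects, three binary descriptors; the miner enumerates the closed
subject×descriptor rectangles and emits the non-redundant rule basis with
support / confidence / lift / exact p-values.
"""

from trialfca import (
    build_context,
    enumerate_closed_itemsets,
    generate_rules,
    score_rules,
)
from trialfca.preprocessing import DescriptorTable

rows = {
    "s1": ["doseC", "DR4", "improved"],
    "s2": ["doseC", "DR4", "improved"],
    "s3": ["doseC", "DR4", "improved"],
    "s4": ["doseC", "improved"],
    "s5": ["DR4"],
    "s6": ["DR4", "improved"],
    "s7": [],
    "s8": [],
}
table = DescriptorTable()
table.subject_ids = list(rows)
for sid, names in rows.items():
    for name in names:
        table.add(sid, name, "yes", ("yes",))
for name in ("doseC", "DR4", "improved"):
    table.measured[name] = set(rows)

context = build_context(table)
concepts = enumerate_closed_itemsets(context, min_support=1)
print(f"{len(concepts)} formal concepts (closed descriptor sets):")
for c in concepts:
    intent = ", ".join(sorted(d.name for d in c.intent)) or "∅"
    print(f"  {{{intent}}}  extent size {len(c.extent)}")

rules = generate_rules(concepts, context)
scored = score_rules(rules, context)
print(f"\n{len(scored)} scored rules (support / confidence / lift / Fisher p):")
for sr in sorted(scored, key=lambda s: -s.metrics.lift):
    ant = " & ".join(sorted(d.name for d in sr.rule.antecedent))
    con = " & ".join(sorted(d.name for d in sr.rule.consequent))
    m = sr.metrics
    print(f"  {ant} → {con}:  {m.support}  {m.confidence:.2f}  {m.lift:.2f}  {m.p_fisher:.3f}")
print(
    "\nLift > 1 means the antecedent enriches for the consequent relative to "
    "the whole cohort; lift = 1 is statistical independence."
)
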