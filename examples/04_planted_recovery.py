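"""Plant a {dose C ∧ DR4+} → improvement association and recover it with the
full pipeline (simulate → discretize → mine → score → filter → dose focus)."""

import tempfile

from trialfca import (
    Arm,
    PipelineConfig,
    PlantedRule,
    SimulationConfig,
    run_pipeline,
)

planted = PlantedRule(arm=Arm.doseC, hla_dr4=True, effect=0.0, penetrance=0.9)
# effect 0.0 halts the C-peptide decline for 90% of dose-C DR4+ subjects

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(
        out_dir=tmp,
        simulation=SimulationConfig(planted_rules=[planted], seed=3),
        seed=3,
        mode="dose-focus",
    )
    report = run_pipeline(config)

counts = report.provenance["counts"]
print(
    f"funnel: {counts['generated']} candidate rules → {counts['scored']} scored "
    f"→ {counts['selected']} selected (support ≥ 4, confidence ≥ 0.75, "
    "lift ≥ 1.25, p ≤ 0.05, dose necessary)"
)

print("\ntop selected rules by lift:")
top = sorted(report.rules, key=lambda sr: -sr.metrics.lift)[:5]
for sr in top:
    ant = " & ".join(sorted(str(d) for d in sr.rule.antecedent))
    con = " & ".join(sorted(str(d) for d in sr.rule.consequent))
    m = sr.metrics
    print(f"  {ant} → {con}")
    print(f"    support {m.support}, confidence {m.confidence:.2f}, lift {m.lift:.2f}, "
          f"Fisher p {m.p_fisher:.4f}")
print(
    "\nThe planted dose C ∧ DR4+ → better-than-expected-AUC association "
    "should appear with high confidence; dose-focus keeps only rules whose "
    "dose term is necessary (removing it breaks confidence or lift)."
)
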