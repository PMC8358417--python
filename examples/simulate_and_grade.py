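"""Generate a synthetic trial corpus and push it through the pipeline.

The generator emulates published summary rows: control medians per
setting, hazard ratios with CI widths driven by the event count, and
Bernoulli QoL/toxicity evidence.  Useful for stress-testing the rules
without any external data.
"""

from collections import Counter

from esmo_mcbs import SimulationConfig, generate_trials, grade_all

config = SimulationConfig(seed=42, n_trials=500)
records = generate_trials(config)
results = grade_all(records)

included = [r for r in results if r.final is not None]
print(f"{len(records)} synthetic trials; {len(included)} pass the significance gate")
print("final-grade distribution:", dict(sorted(Counter(r.final for r in included).items())))
print("forms used:", dict(Counter(r.form.value for r in included)))
print("The generator draws true hazard ratios uniformly down to 0.2, so strong "
      "effects — and hence grades 4-5 — are far more common here than in the "
      "published corpus, where only three treatments reach grade 4.")
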