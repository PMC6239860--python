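"""Simulate binding experiments and recover the configured propensities.

Generates HDL populations for each inhibitor condition, tabulates the
observed bound fractions (depressed by projection occlusion), applies the
visibility correction, and compares every condition against the control with
the chi-square test.
"""

from lipocount import (
    bound_fraction,
    compare_conditions,
    corrected_bound_fraction_records,
    default_config,
    generate_population,
    tabulate,
)

cfg = default_config(seed=42, n_particles=2000)
records = generate_population(cfg)
tables = tabulate(records)
mult = cfg.class_spec("HDL").multiplicity
control = tables[("HDL", "control")]

print("HDL binding by condition (truth = configured propensity):")
for cond in ("control", "Torcetrapib", "Dalcetrapib", "Anacetrapib"):
    t = tables[("HDL", cond)]
    sub = records[(records["class"] == "HDL") & (records["condition"] == cond)]
    corrected = corrected_bound_fraction_records(sub, cfg.rod_length, mult)
    truth = cfg.condition_spec(cond).propensity["HDL"]
    line = (f"  {cond:12s} observed {bound_fraction(t):6.1%}  "
            f"corrected {corrected:6.1%}  truth {truth:6.1%}")
    if cond != "control":
        r = compare_conditions(t, control)  # Yates-corrected by default
        line += f"  vs control: chi2={r.chi_square:7.1f}, p {r.p_display()}"
    print(line)
print("corrected estimates should bracket the truth; every inhibitor contrast"
      " is overwhelmingly significant")
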