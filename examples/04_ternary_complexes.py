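"""Quantify HDL-CETP-LDL bridges in a simulated two-lipoprotein mixture.

Each bridge contributes one ternary complex counted against both the HDL and
the LDL population totals.  The inhibitors suppress bridging (the configured
modulation), which the estimator recovers.
"""

from lipocount import (
    default_config,
    generate_ternary_population,
    tabulate,
    ternary_fractions,
)

cfg = default_config(seed=7, n_particles=3000)
records = generate_ternary_population(cfg)
tables = tabulate(records)

print("ternary-complex fractions (HDL side / LDL side, truth in parens):")
for cond in ("control", "Torcetrapib", "Dalcetrapib", "Anacetrapib"):
    f_hdl, f_ldl = ternary_fractions(tables[("HDL", cond)], tables[("LDL", cond)])
    truth_hdl = cfg.ternary.hdl_ternary_fraction(cond)
    truth_ldl = cfg.ternary.ldl_fraction[cond]
    print(f"  {cond:12s} HDL {f_hdl:6.1%} ({truth_hdl:.1%})   "
          f"LDL {f_ldl:6.1%} ({truth_ldl:.1%})")
print("inhibitors leave the LDL side nearly unchanged but cut HDL-side"
      " bridging by roughly a quarter to a half")
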