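"""Proportional-AC90 mixture design for the five household chemicals.

Each chemical enters the mixture at its AC90 (the concentration
retaining 90% cell viability) times a common scaling factor i, so the
components stay in fixed potency-proportional ratios while one knob
moves the whole mixture along the dose axis.
"""

from coexmix.data import household_ac90_table
from coexmix.mixture import mixture_series

table = household_ac90_table()
print("individual AC90 concentrations (µM):")
for entry in table.ordered():
    note = "  [1000 µM fallback: 90% viability never reached <= 2000 µM]" \
        if entry.status != "estimated" else ""
    print(f"  {entry.chemical:<24} {entry.ac90_um:>7.0f}{note}")

print("\nmixture series C_i = sum(AC90_c * i):")
for spec in mixture_series(table, [1.0, 0.5, 0.2]):
    parts = ", ".join(f"{c.split()[0]} {v:g}" for c, v in spec.components_um.items())
    print(f"  C_{spec.i:g}: total {spec.total_um:g} µM  ({parts})")

print("\nAt i = 0.2 every chemical sits at exactly one fifth of its AC90; "
      "this is the composition carried into expression testing.")
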