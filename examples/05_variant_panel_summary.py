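"""Summarize the bundled creatinase (afCR) variant panels.

Computes fold improvements and the design success rate for the 21 single
consensus mutants at 55 °C, the combinatorial series at 57 °C, and the
T50¹⁵/Tm gains of the best variants.
"""

from phyloconsensus import fold_improvement, summarize_variants
from phyloconsensus.datasets import (
    COMBINATORIAL_MUTANTS_57C,
    KINETIC_THERMODYNAMIC,
    SINGLE_MUTANTS_55C,
)

table, rate = summarize_variants(SINGLE_MUTANTS_55C, "M0")
improved = int((table["fold_improvement"] > 1).sum())
print(f"single mutants at 55 °C: {improved} of {len(table)} improved "
      f"→ design success rate {rate:.0f}%")
print(table.head(3).to_string(index=False))

combos = COMBINATORIAL_MUTANTS_57C.set_index("label")
ref = combos.loc["M0", "t_half"]
print("\ncombinatorial series at 57 °C (fold vs M0):")
for label in ("M1", "M2-4", "M3-4", "M4-2"):
    fold = fold_improvement(combos.loc[label, "t_half"], ref)
    print(f"  {label:>5} ({combos.loc[label, 'mutation']}): {fold}")

kt = KINETIC_THERMODYNAMIC.set_index("label")
print(f"\nM4-2 ΔT50¹⁵ vs M0: {kt.loc['M4-2', 't50_15'] - kt.loc['M0', 't50_15']:.1f} °C")
print(f"best ΔTm vs M0:    {(kt['tm'] - kt.loc['M0', 'tm']).max():.1f} °C")
# The quadruple mutant M4-2 gains ~1700-fold in half-life at 57 °C but only
# ~4 °C in T50¹⁵ — kinetic stability responds far more strongly to these
# mutations than the unfolding midpoint does.
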