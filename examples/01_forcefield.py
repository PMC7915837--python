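"""Force-field basics: the chi -> a_ij map and the interaction table.

Prints the repulsion amplitudes for athermal, theta and poor solvents,
a few entries of the calibrated table, and the charge equivalence
between one diblock polyelectrolyte chain and one porphyrin unit.
"""

from ipecsim import (
    charge_equivalence,
    chi_to_repulsion,
    default_interaction_table,
    make_diblock,
    make_porphyrin,
)

print("Flory chi -> DPD repulsion a_ij (reduced energy, rho = 3):")
for chi, label in [(0.0, "athermal solvent"), (0.5, "theta solvent"),
                   (4.5, "poor solvent")]:
    print(f"  chi = {chi:3.1f}  ->  a = {chi_to_repulsion(chi):5.1f}   ({label})")

table = default_interaction_table()
print("\nSelected interaction amplitudes of the calibrated model:")
for i, j, why in [
    ("P", "P", "porphyrin ring-ring: effective pi-pi attraction (a < 25)"),
    ("P", "S", "ring-solvent: strongly hydrophobic"),
    ("A+", "S", "polyelectrolyte backbone-solvent: moderately hydrophobic"),
    ("B", "S", "neutral block-solvent: marginally soluble"),
    ("A+", "CI-", "ion-backbone short-range attraction"),
]:
    print(f"  a({i:3s},{j:3s}) = {table.lookup(i, j):4.0f}   {why}")

chain = make_diblock(10, 25, +1)
porph = make_porphyrin()
eq = charge_equivalence(chain, porph)
print(f"\nChain net charge {chain.net_charge:+d} e, porphyrin {porph.net_charge:+d} e:")
print(f"  replacing one chain takes the equivalent of {eq} porphyrin units.")
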