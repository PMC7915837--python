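"""Porphyrin self-aggregation in a salt-free box.

Builds a small solution of tetra-cationic porphyrin units with their
counterions, runs DPD with smeared-charge electrostatics, and prints the
weight distribution F_w(AS) of aggregate sizes.  Takes about a minute.
"""

import ipecsim as ip

recipe = ip.ScenarioRecipe(n_porphyrin=8, L=7, seed=1)
print(f"{recipe.n_porphyrin} porphyrins in L = {recipe.L} box "
      f"(c = {recipe.porphyrin_volume_fraction:.1f} Vol%), "
      f"{recipe.n_total} beads total")

state = ip.build_initial_state(recipe)
engine = ip.Engine(state, ip.SimParams(seed=2),
                   charge_model=ip.ChargeModel())
snapshots = []
for _ in range(12):
    engine.run(250, thermo_stride=0, keep_frames=False)
    snapshots.append(state.copy())

dist = ip.porphyrin_aggregate_distribution(snapshots, discard_fraction=0.25)
print("\nF_w(AS) of porphyrin aggregates (frame-averaged):")
print("  AS   N_frac   F_w")
for s, nf, wf in zip(dist.support, dist.number_fraction,
                     dist.weight_fraction):
    print(f"  {s:2d}   {nf:6.3f}  {wf:6.3f}")
print(f"\nweight in dimers and larger: {dist.dimer_plus_weight:.3f}")
print("(at this concentration the rings stack readily; rerun with fewer "
      "porphyrins or a larger box to see monomers dominate, or add salt "
      "pairs to push aggregation further)")
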