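"""Competitive receptor occupancy and activation.

Builds a three-ligand synapse (dopamine, a partial agonist, a neutral
antagonist) and prints how occupancy and activation at the D2 receptor
change as the drug dose rises.  Occupancy follows C/Ki competition; the
activation is the efficacy-weighted occupancy, so the antagonist lowers
activation purely by displacing dopamine.
"""

from bgqsp import receptor_kinetics as rk

dopamine = rk.dopamine_ligand(30.0)        # ~healthy tonic free DA, nM
agonist = rk.Ligand("partial_agonist", {"D2": 5.0}, {"D2": 0.6}, 0.0)
antagonist = rk.Ligand("antagonist", {"D2": 2.0}, {}, 0.0)

print(f"{'drug conc (nM)':>15} {'occ DA':>8} {'occ drug':>9} {'activation':>11}")
for conc in [0.0, 1.0, 5.0, 20.0, 100.0]:
    ligs = [dopamine, agonist.with_concentration(conc)]
    occ = rk.competitive_occupancy(ligs, "D2")
    act = rk.receptor_activation(occ, ligs, "D2")
    print(f"{conc:15.1f} {occ['dopamine']:8.3f} "
          f"{occ['partial_agonist']:9.3f} {act:11.3f}")
print("-> the partial agonist adds its own (0.6-weighted) activation while"
      " displacing dopamine from the high-affinity pool")

print()
print(f"{'antag conc':>15} {'occ DA':>8} {'occ drug':>9} {'activation':>11}")
for conc in [0.0, 2.0, 10.0, 50.0]:
    ligs = [dopamine, antagonist.with_concentration(conc)]
    occ = rk.competitive_occupancy(ligs, "D2")
    act = rk.receptor_activation(occ, ligs, "D2")
    print(f"{conc:15.1f} {occ['dopamine']:8.3f} "
          f"{occ['antagonist']:9.3f} {act:11.3f}")
print("-> the neutral antagonist contributes no activation of its own;"
      " activation falls toward zero as it saturates the receptor")
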