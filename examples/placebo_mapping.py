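"""The placebo PET mapping: tracer displacement <-> dopamine release.

Anchors the displacement->release inversion (one-time procedure), then
inverts the two clinically observed placebo displacements: 23% displacement
of a D2-antagonist tracer (acute) and 11% of a DAT tracer (chronic).  The
inferred release increases are the quantities a virtual placebo arm applies
to the dopamine synapse.
"""

import numpy as np

from bgqsp import receptor_kinetics as rk

consts = rk.placebo_anchor_constants()
print("anchored imaging constants:",
      {k: round(v, 3) for k, v in consts.items()})

for label, disp, cls in [("acute (raclopride-class)", 23.0, rk.D2_TRACER),
                         ("chronic (DAT-tracer)", 11.0, rk.DAT_TRACER)]:
    fold = rk.release_change_from_displacement(disp, cls)
    print(f"{label}: {disp:.0f}% displacement -> "
          f"{100 * (fold - 1):+.1f}% dopamine release")

print("\nforward model (displacement vs release fold, D2-antagonist tracer):")
for fold in np.arange(1.0, 3.1, 0.4):
    d = rk.displacement_from_release(fold, rk.D2_TRACER)
    print(f"  release x{fold:.1f} -> {d:5.1f}% displacement")
print("-> autoreceptor feedback makes free dopamine, and therefore "
      "displacement, sub-linear in the release fold")
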