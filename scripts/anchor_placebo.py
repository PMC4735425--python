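"""One-time anchoring of the displacement -> release mapping.

Solves the two dimensionless constants of the PET imaging model (baseline
dopamine load relative to the D2-antagonist-tracer Ki, and relative to the
DAT-tracer sensitivity) so that the release-fold anchors reproduce the
observed displacements: +120% release -> 23% D2-tracer displacement and
+40% release -> 11% DAT-tracer displacement.  Prints the solved constants
and verifies the round trip.  The library performs the same solve lazily and
caches it; this script exists to make the procedure explicit and inspectable.
"""

from __future__ import annotations

import json

from bgqsp import receptor_kinetics as rk


def main() -> None:
    rk.placebo_anchor_constants.cache_clear()
    consts = rk.placebo_anchor_constants()
    report = {
        "anchors": {cls: {"displacement_pct": d, "release_fold": f}
                    for cls, (d, f) in rk.ANCHORS.items()},
        "solved_constants": consts,
        "roundtrip": {
            "D2 23% -> release fold":
                rk.release_change_from_displacement(23.0, rk.D2_TRACER),
            "DAT 11% -> release fold":
                rk.release_change_from_displacement(11.0, rk.DAT_TRACER),
        },
        "healthy_free_da_nM":
            rk.steady_state_free_da(rk.DopamineSynapseState()),
    }
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
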