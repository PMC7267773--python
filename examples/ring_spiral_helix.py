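"""Classify the three assembly outcomes of a two-interface oligomer.

The inter-axis angle alpha and offset h of the two dimerization two-folds
fix the composed generator (twist 2*alpha, rise 2*h).  Small changes in
the interface geometry switch the outcome between a closed ring (SAS6),
a near-planar spiral (ceSAS6) and an open helical filament (CCDC61).
"""

import protofil as pf
from protofil.synthetic import (
    CCDC61_LIKE,
    CESAS6_SPIRAL_LIKE,
    SAS6_RING_LIKE,
    interface_pair_axes,
)

presets = [
    ("SAS6-like ring   ", SAS6_RING_LIKE),
    ("ceSAS6-like spiral", CESAS6_SPIRAL_LIKE),
    ("CCDC61-like helix ", CCDC61_LIKE),
]

for name, geom in presets:
    head_c2, cc_c2 = interface_pair_axes(geom["alpha_deg"], geom["offset_h"])
    c = pf.classify_assembly(pf.compose(head_c2, cc_c2))
    order = f"N={c.ring_order}" if c.ring_order else f"{c.handedness}-handed"
    print(f"{name} alpha={geom['alpha_deg']:5.1f} h={geom['offset_h']:6.1f} -> "
          f"{c.kind:11s} twist {c.angle_deg:6.2f} deg, rise {c.rise_per_repeat:6.2f} A "
          f"({order}; closure residuals {c.closure_angle_residual:.2f} deg / "
          f"{c.closure_rise_residual:.2f} A)")
# A ring closes in both twist (N*twist = 360) and rise (N*rise = 0); the
# spiral's twist closes but its small residual rise prevents closure; the
# helix has a large per-repeat rise and never approaches closure.
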