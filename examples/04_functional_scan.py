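"""Interpolate the range-separation parameters from CAM-B3LYP to B3LYP.

CAM-B3LYP attenuates exchange as alpha + beta*erf(mu*r12); sliding
(alpha, beta) linearly to the B3LYP limit (0.20, 0) while holding
mu = 0.33 produces the five parameter sets of the functional scan, and
an override stanza per point for running the scan in a QC code.
"""

import ecdkit as ek
from ecdkit.rangesep import emit_overrides, path_to_frame

path = ek.parameter_path(ek.CAM_B3LYP, ek.B3LYP, n_points=5)
print(path_to_frame(path).to_string(index=False))
print()
print("HF-exchange weight at contact / at infinity for each point:")
for i, p in enumerate(path, start=1):
    print(f"  point {i}: {ek.hf_weight(0.0, p):.4f} -> {p.alpha + p.beta:.4f}")
print()
print("Override stanza for point 2 (alpha=0.1925, beta=0.3450):")
print(emit_overrides(path[1]))
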