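"""Synthesize a pristine Bragg peak and a Mod30 SOBP and extract their metrics.

Prints the distal D50, the 90-90 SOBP bounds, and the plateau flatness. D50
is the range metric a water tank measures; the 90-90 extent is the modulation
width delivered by the range-modulator wheel.
"""
import numpy as np

from protondosim import beam_preset, pristine_bragg, sobp_synthesize
from protondosim.metrics import d50_distal, sobp_bounds

z = np.arange(0.0, 130.0, 0.1)

pristine = pristine_bragg(beam_preset("127MeV-Mod0-20mm"), z)
print(f"127 MeV pristine: D50 = {d50_distal(pristine):.2f} mm WED")

weights, sobp = sobp_synthesize(beam_preset("127MeV-Mod30-20mm"), z_grid=z)
p90, d90 = sobp_bounds(sobp)
print(f"127 MeV Mod30:    D50 = {d50_distal(sobp):.2f} mm WED")
print(f"  90-90 plateau: {p90:.2f} -> {d90:.2f} mm  (extent {d90 - p90:.1f} mm)")
print(f"  plateau flatness: {sobp.meta['plateau_flatness'] * 100:.2f}%")
print(f"  {len(weights)} pristine components, weights sum {weights.sum():.3f}")
# The distal D50 tracks the pristine beam's range; the plateau extent tracks
# the nominal 30 mm modulation within the synthesis tolerance.
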