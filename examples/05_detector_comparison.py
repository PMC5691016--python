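"""Compare diode and chamber depth scans of one SOBP: ratio curve and the
distal-edge interpolated ratios.

With perfectly aligned detectors the diode/chamber ratio is 1 everywhere up
to the 25% distal clip. A 0.9 mm relative misalignment — the scale of the
D50 discrepancies seen between real detectors — produces the characteristic
sharp ratio rise beyond the distal edge of the SOBP.
"""
import numpy as np

from protondosim import Profile, beam_preset, detector_preset, ratio_curve
from protondosim.compare import shift_sensitivity
from protondosim.detectors import scan_profile
from protondosim.metrics import normalize

spec = beam_preset("127MeV-Mod30-20mm")
diode = detector_preset("PR60020")
markus = detector_preset("MarkusN23343")

kw = dict(axis="depth", start=30.0, stop=125.0, step=0.25)
dio = normalize(scan_profile(spec, diode, **kw), "max")
ref = normalize(scan_profile(spec, markus, **kw), "max")

aligned = ratio_curve(dio, ref)
print(f"aligned:    ratio@90% = {aligned.distal_ratio_90:.3f}, "
      f"ratio@95% = {aligned.distal_ratio_95:.3f}, clip {aligned.clip_depth:.1f} mm")

shifted = Profile(dio.positions + 0.9, dio.dose, axis="depth")
mis = ratio_curve(shifted, ref)
print(f"0.9 mm off: ratio@90% = {mis.distal_ratio_90:.3f}, "
      f"ratio@95% = {mis.distal_ratio_95:.3f}, D50 diff {mis.d50_difference:+.2f} mm")

for s in (0.4, 0.9):
    print(f"linear-falloff estimate for a {s} mm shift: "
          f"{shift_sensitivity(normalize(ref, 'max'), s):.0f}% ratio change")
# The distal ratios stay at 1.00 when aligned and rise by several percent at
# the 90% level under the misalignment. The linear-falloff estimates land
# around the 10-30% band quoted for mid-falloff shifts of this size (the
# SOBP's distal falloff is slightly softer than the pristine peak's, so the
# 0.4 mm figure sits just under 10%).
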