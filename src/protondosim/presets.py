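"""Study presets: the nine beam configurations and the two detector models.

Beam parameters reproduce the nominal radiosurgery beams of a single-stage
scattering system: 127 and 157 MeV (distal D50 near 100 and 153 mm WED),
modulations of 0/15/30/60 mm, and initial diameters of 8–20 mm. Distal 80–20
falloffs default to 4.0 mm (127 MeV) and 5.5 mm (157 MeV) — straggling of
roughly 1.2% of range plus source spectrum. Lateral penumbra defaults
(sigma0 = 0.7 mm, growth = 0.004 per mm) are calibrated so the 20 mm aperture
FW90M at 33 mm WED matches the simulated widths to within 0.5 mm.
"""
from __future__ import annotations

from .beam import BeamSpec
from .detectors import DetectorSpec, ReadoutModel

__all__ = ["BEAM_PRESETS", "DETECTOR_PRESETS", "READOUT_DEFAULT", "beam_preset", "detector_preset"]

_D50_127, _FALL_127 = 99.5, 4.0
_D50_157, _FALL_157 = 153.1, 5.5


def _beam(label, d50, fall, mod, diam):
    return BeamSpec(
        label=label, pristine_d50=d50, falloff_8020=fall,
        modulation=mod, aperture_diameter=diam,
    )


#: the nine energy/modulation/diameter combinations of the study
BEAM_PRESETS: dict[str, BeamSpec] = {
    "127MeV-Mod0-20mm": _beam("127MeV-Mod0-20mm", _D50_127, _FALL_127, 0.0, 20.0),
    "127MeV-Mod0-8mm": _beam("127MeV-Mod0-8mm", _D50_127, _FALL_127, 0.0, 8.0),
    "127MeV-Mod0-10mm": _beam("127MeV-Mod0-10mm", _D50_127, _FALL_127, 0.0, 10.0),
    "127MeV-Mod0-12mm": _beam("127MeV-Mod0-12mm", _D50_127, _FALL_127, 0.0, 12.0),
    "127MeV-Mod15-20mm": _beam("127MeV-Mod15-20mm", _D50_127, _FALL_127, 15.0, 20.0),
    "127MeV-Mod30-20mm": _beam("127MeV-Mod30-20mm", _D50_127, _FALL_127, 30.0, 20.0),
    "157MeV-Mod0-20mm": _beam("157MeV-Mod0-20mm", _D50_157, _FALL_157, 0.0, 20.0),
    "157MeV-Mod30-20mm": _beam("157MeV-Mod30-20mm", _D50_157, _FALL_157, 30.0, 20.0),
    "157MeV-Mod60-20mm": _beam("157MeV-Mod60-20mm", _D50_157, _FALL_157, 60.0, 20.0),
}

#: p-type proton diode (1 mm^2 x 20 um SV) and plane-parallel reference chamber
DETECTOR_PRESETS: dict[str, DetectorSpec] = {
    "PR60020": DetectorSpec(
        kind="diode", sv_thickness=0.020, window_wet=1.33,
        orientation="axial", name="PR60020",
    ),
    "PR60020-edge": DetectorSpec(
        kind="diode", sv_thickness=0.020, window_wet=1.33,
        orientation="edge_on", name="PR60020",
    ),
    "MarkusN23343": DetectorSpec(
        kind="plane_parallel_chamber", radius=2.65, sv_thickness=2.0,
        window_wet=1.06, orientation="axial", name="MarkusN23343",
    ),
}

READOUT_DEFAULT = ReadoutModel()


def beam_preset(name: str) -> BeamSpec:
    try:
        return BEAM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown beam preset {name!r}; available: {', '.join(BEAM_PRESETS)}"
        ) from None


def detector_preset(name: str) -> DetectorSpec:
    try:
        return DETECTOR_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown detector preset {name!r}; available: {', '.join(DETECTOR_PRESETS)}"
        ) from None
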