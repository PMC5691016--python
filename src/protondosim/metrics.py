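"""Quantitative descriptors of depth-dose and transverse profiles.

The extractors here mirror standard water-tank commissioning practice for
proton fields:

* ``d50_distal`` — water-equivalent depth, distal to the dose maximum, where
  the dose falls to 50% of maximum (the range metric commonly tabulated for
  Bragg and spread-out Bragg peaks).
* ``sobp_bounds`` — the proximal/distal 90% crossings bounding the SOBP
  plateau; their separation is the modulation width.
* ``full_width`` — FWHM / FW90M style full widths of lateral profiles.
* ``penumbra_width`` — 20–80% edge widths.
* ``interp_at_level`` — second-order (quadratic) interpolation of one curve at
  the depth where a reference curve crosses a stated distal level; used for
  distal-edge detector-ratio readouts.

Level crossings are located by linear interpolation between bracketing
samples; where noise produces multiple crossings, the outermost one is used.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ExtractionError, NormalizationError
from .profiles import Profile

__all__ = [
    "ProfileMetrics",
    "normalize",
    "com_depth",
    "d50_distal",
    "sobp_bounds",
    "full_width",
    "penumbra_width",
    "interp_at_level",
    "profile_metrics",
    "median_smooth",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileMetrics:
    """Flat record of the headline metrics of one profile (mm / percent)."""

    d50: float | None = None
    proximal90: float | None = None
    distal90: float | None = None
    fwhm: float | None = None
    fw90m: float | None = None
    penumbra_2080: float | None = None
    flatness_pct: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# crossing helpers
# ---------------------------------------------------------------------------

def _crossings(x: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """All positions where linearly interpolated ``y`` crosses ``level``."""
    d = y - level
    out = []
    exact = np.nonzero(d == 0)[0]
    for i in exact:
        out.append(x[i])
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    for i in sign_change:
        t = d[i] / (d[i] - d[i + 1])
        out.append(x[i] + t * (x[i + 1] - x[i]))
    return np.sort(np.asarray(out))


def _distal_crossing(profile: Profile, frac: float) -> float:
    """Deepest crossing of ``frac``·max distal to the global maximum."""
    y = profile.dose
    x = profile.positions
    imax = int(np.argmax(y))
    level = frac * y[imax]
    xs = _crossings(x[imax:], y[imax:], level)
    if xs.size == 0:
        raise ExtractionError(
            f"no distal crossing of {frac:.0%} of maximum (profile ends at "
            f"{x[-1]:.3g} mm with dose {y[-1] / y[imax]:.3g} of max)"
        )
    return float(xs[-1])


def _proximal_crossing(profile: Profile, frac: float) -> float:
    """Shallowest crossing of ``frac``·max proximal to (or at) the global maximum."""
    y = profile.dose
    x = profile.positions
    imax = int(np.argmax(y))
    level = frac * y[imax]
    xs = _crossings(x[: imax + 1], y[: imax + 1], level)
    if xs.size == 0:
        # dose never falls below the level proximally (e.g. entrance above 90%):
        # the bound is the first sample.
        return float(x[0])
    return float(xs[0])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(profile: Profile, mode: str = "max") -> Profile:
    """Rescale a profile so that the reference dose equals 1.

    ``max`` divides by the maximum dose (the rule for unmodulated depth-dose
    and all transverse profiles). ``com`` divides by the dose at the center of
    modulation — the midpoint of the proximal/distal 90% bounds — which is the
    rule for modulated depth-dose curves.
    """
    if mode not in ("max", "com"):
        raise NormalizationError(f"unknown normalization mode {mode!r}")
    peak = profile.max_dose
    if peak <= 0:
        raise NormalizationError("cannot normalize an all-zero profile")
    if mode == "max":
        ref = peak
    else:
        ref = float(profile(com_depth(profile)))
        if ref <= 0:
            raise NormalizationError("dose at the center of modulation is zero")
    return profile.with_dose(profile.dose / ref, normalization=mode)


def com_depth(profile: Profile) -> float:
    """Center of modulation: midpoint of the proximal and distal 90% bounds."""
    p90, d90 = sobp_bounds(profile)
    return 0.5 * (p90 + d90)


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------

def d50_distal(profile: Profile) -> float:
    """Depth of 50% of maximum dose, distal to the maximum (mm).

    Defined on the fraction of the (discrete) global maximum, so the result is
    invariant to the normalization mode of the input.
    """
    return _distal_crossing(profile, 0.5)


def sobp_bounds(profile: Profile) -> tuple[float, float]:
    """Outermost proximal and distal crossings of 90% of maximum (mm)."""
    d90 = _distal_crossing(profile, 0.9)
    p90 = _proximal_crossing(profile, 0.9)
    return p90, d90


def full_width(profile: Profile, level: float = 0.5) -> float:
    """Full width of the profile at ``level``·max (mm); outermost crossings."""
    if not 0.0 < level < 1.0:
        raise ExtractionError(f"level must be in (0,1), got {level}")
    y = profile.dose
    x = profile.positions
    xs = _crossings(x, y, level * y.max())
    imax = int(np.argmax(y))
    left = xs[xs <= x[imax]]
    right = xs[xs >= x[imax]]
    if left.size == 0 or right.size == 0:
        raise ExtractionError(
            f"profile does not cross {level:.0%} of maximum on both sides"
        )
    return float(right[-1] - left[0])


def penumbra_width(
    profile: Profile, lo: float = 0.2, hi: float = 0.8
) -> tuple[float, float, float]:
    """Edge widths between ``lo`` and ``hi`` fractions of maximum.

    Returns ``(left, right, mean)`` in mm; each side uses the outermost
    crossing of the lower level and the matching crossing of the upper level.
    """
    if not 0.0 < lo < hi < 1.0:
        raise ExtractionError("need 0 < lo < hi < 1")
    y = profile.dose
    x = profile.positions
    imax = int(np.argmax(y))
    widths = []
    for side in ("left", "right"):
        if side == "left":
            xs_lo = _crossings(x[: imax + 1], y[: imax + 1], lo * y[imax])
            xs_hi = _crossings(x[: imax + 1], y[: imax + 1], hi * y[imax])
            if xs_lo.size == 0 or xs_hi.size == 0:
                raise ExtractionError(f"missing {side} {lo:.0%}/{hi:.0%} crossing")
            widths.append(float(xs_hi[0] - xs_lo[0]))
        else:
            xs_lo = _crossings(x[imax:], y[imax:], lo * y[imax])
            xs_hi = _crossings(x[imax:], y[imax:], hi * y[imax])
            if xs_lo.size == 0 or xs_hi.size == 0:
                raise ExtractionError(f"missing {side} {lo:.0%}/{hi:.0%} crossing")
            widths.append(float(xs_lo[-1] - xs_hi[-1]))
    left, right = widths
    return left, right, 0.5 * (left + right)


def interp_at_level(
    curve: Profile,
    reference: Profile,
    level: float,
    *,
    edge: str = "distal",
) -> float:
    """Value of ``curve`` at the depth where ``reference`` crosses ``level``·max.

    The crossing depth on the reference is located by linear interpolation on
    its distal (or proximal) edge; ``curve`` is then evaluated there by
    quadratic interpolation through its three nearest samples. With fewer than
    three samples available the evaluation falls back to linear interpolation
    and logs a warning.
    """
    if edge == "distal":
        x0 = _distal_crossing(reference, level)
    elif edge == "proximal":
        x0 = _proximal_crossing(reference, level)
    else:
        raise ExtractionError(f"unknown edge {edge!r}")
    x, y = curve.positions, curve.dose
    if x.size < 3:
        warnings.warn(
            "fewer than 3 samples for quadratic interpolation; falling back to linear",
            stacklevel=2,
        )
        log.warning("interp_at_level: linear fallback (n=%d)", x.size)
        return float(np.interp(x0, x, y))
    i = int(np.clip(np.searchsorted(x, x0), 1, x.size - 2))
    # choose the 3 samples nearest x0
    if i >= 2 and abs(x[i - 2] - x0) < abs(x[i + 1] - x0):
        sel = slice(i - 2, i + 1)
    else:
        sel = slice(i - 1, i + 2)
    coeff = np.polyfit(x[sel] - x0, y[sel], 2)
    return float(coeff[-1])


def median_smooth(profile: Profile) -> Profile:
    """3-point median filter; applied only on explicit request, never silently."""
    y = profile.dose
    if y.size < 3:
        return profile
    sm = y.copy()
    sm[1:-1] = np.median(np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1)
    return profile.with_dose(sm)


def profile_metrics(profile: Profile) -> ProfileMetrics:
    """Best-effort extraction of all metrics applicable to the profile's axis."""
    out: dict = {}
    if profile.axis == "depth":
        try:
            out["d50"] = d50_distal(profile)
        except ExtractionError:
            pass
        try:
            p90, d90 = sobp_bounds(profile)
            out["proximal90"], out["distal90"] = p90, d90
            mask = (profile.positions >= p90) & (profile.positions <= d90)
            if mask.sum() >= 2:
                seg = profile.dose[mask]
                out["flatness_pct"] = float(
                    100.0 * np.max(np.abs(seg - seg.mean())) / seg.mean()
                )
        except ExtractionError:
            pass
    else:
        for key, level in (("fwhm", 0.5), ("fw90m", 0.9)):
            try:
                out[key] = full_width(profile, level)
            except ExtractionError:
                pass
        try:
            out["penumbra_2080"] = penumbra_width(profile)[2]
        except ExtractionError:
            pass
    return ProfileMetrics(**out)
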