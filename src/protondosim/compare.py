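"""Detector-comparison and calibration analyses.

This module reproduces, on synthetic data, the analyses used to qualify a
small-volume diode against a plane-parallel reference chamber:

* depth-wise diode/chamber dose-ratio curves, clipped at the 25% distal dose,
  with second-order interpolated ratios at the distal 90% and 95% levels;
* an analytic misalignment sensitivity for the distal falloff ("how much does
  a sub-millimetre shift move the ratio?");
* the four precursory calibration experiments — dose linearity, dose-rate
  uniformity, sensitivity decay with accumulated dose, and axial/edge-on
  orientation difference — as experiment simulators plus parameter-recovery
  fits; and
* Table-style agreement summaries of D50 and width differences across
  detectors/modalities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import interp1d

from .detectors import DetectorSpec, ReadoutModel, readout_charge
from .errors import ExtractionError, ProtonDosimError
from .metrics import (
    _distal_crossing,
    d50_distal,
    full_width,
    interp_at_level,
)
from .profiles import Profile

__all__ = [
    "ComparisonResult",
    "FitResult",
    "CalibrationResult",
    "ratio_curve",
    "shift_sensitivity",
    "linearity_fit",
    "decay_fit",
    "orientation_difference",
    "dose_rate_uniformity",
    "agreement_table",
    "simulate_linearity_experiment",
    "simulate_decay_experiment",
    "simulate_orientation_experiment",
    "simulate_dose_rate_experiment",
    "LINEARITY_DOSES_GY",
    "DOSE_RATES_CGY_S",
]

#: nine-dose linearity design, 0.6–23 Gy
LINEARITY_DOSES_GY = np.linspace(0.6, 23.0, 9)
#: fourteen dose rates spanning 0.7–2.3 cGy/s
DOSE_RATES_CGY_S = np.linspace(0.7, 2.3, 14)


# ---------------------------------------------------------------------------
# ratio curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """Diode/reference relative-dose ratio along depth.

    The ratio is defined only where the reference dose is at least 25% of its
    maximum and no deeper than the reference's distal 25% crossing.
    """

    depth: np.ndarray
    ratio: np.ndarray
    clip_depth: float
    distal_ratio_90: float
    distal_ratio_95: float
    d50_difference: float
    meta: dict = field(default_factory=dict)

    def as_profile(self) -> Profile:
        return Profile(self.depth, self.ratio, axis="depth", normalization="raw",
                       meta=dict(self.meta, quantity="dose ratio"))


def ratio_curve(diode: Profile, reference: Profile) -> ComparisonResult:
    """Pointwise diode/reference ratio on the reference grid.

    The diode curve is resampled onto the reference depths with quadratic
    interpolation; the ratio is clipped at the reference's distal 25% dose.
    Distal-edge ratios at the 90% and 95% reference levels use second-order
    interpolation of the ratio curve at the corresponding crossing depths.
    """
    lo = max(diode.positions[0], reference.positions[0])
    hi = min(diode.positions[-1], reference.positions[-1])
    if hi <= lo:
        raise ProtonDosimError("profiles have no overlapping depth support")
    clip = _distal_crossing(reference, 0.25)
    mask = (
        (reference.positions >= lo)
        & (reference.positions <= min(hi, clip))
        & (reference.dose >= 0.25 * reference.max_dose - 1e-12)
    )
    z = reference.positions[mask]
    if z.size < 3:
        raise ProtonDosimError("fewer than 3 usable depths above the 25% clip")
    kind = "quadratic" if diode.positions.size >= 3 else "linear"
    dio = interp1d(diode.positions, diode.dose, kind=kind, fill_value="extrapolate")(z)
    ratio = dio / reference.dose[mask]
    rprof = Profile(z, np.clip(ratio, 0.0, None), axis="depth")
    r90 = interp_at_level(rprof, reference, 0.90)
    r95 = interp_at_level(rprof, reference, 0.95)
    dd = d50_distal(diode) - d50_distal(reference)
    return ComparisonResult(
        depth=z, ratio=ratio, clip_depth=clip,
        distal_ratio_90=r90, distal_ratio_95=r95, d50_difference=dd,
        meta={"diode": diode.meta, "reference": reference.meta},
    )


def shift_sensitivity(profile: Profile, shift: float, *, eval_level: float = 0.6) -> float:
    """Percent ratio change at the distal falloff caused by a depth misalignment.

    Assumes the dose falls linearly between its distal 95% and 25% crossings.
    If one of two otherwise identical curves is shifted deeper by ``shift``
    mm, the ratio of the two at the depth of the ``eval_level`` (default:
    mid-falloff, 60%) changes by  g·s / (L − g·s)  with g the linear-falloff
    gradient and L the evaluation level.
    """
    if shift < 0:
        raise ProtonDosimError("shift must be nonnegative")
    if shift == 0:
        return 0.0
    z95 = _distal_crossing(profile, 0.95)
    z25 = _distal_crossing(profile, 0.25)
    width = z25 - z95
    if width <= 0:
        raise ExtractionError("degenerate distal falloff (95% and 25% coincide)")
    g = (0.95 - 0.25) / width  # fraction of max per mm
    denom = eval_level - g * shift
    if denom <= 0:
        raise ExtractionError(
            f"shift {shift} mm exceeds the linear-falloff regime at level {eval_level}"
        )
    return 100.0 * g * shift / denom


# ---------------------------------------------------------------------------
# calibration fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Least-squares line with 95% confidence interval on the slope."""

    slope: float
    intercept: float
    r_value: float
    slope_ci: tuple[float, float]
    intercept_stderr: float = float("nan")

    @property
    def slope_covers_zero(self) -> bool:
        return self.slope_ci[0] <= 0.0 <= self.slope_ci[1]


@dataclass(frozen=True)
class CalibrationResult:
    """Bundle of the four precursory-experiment analyses."""

    linearity: FitResult
    dose_rate: FitResult
    dose_rate_verdict: str
    decay_pct_per_100gy: float
    decay_ci: tuple[float, float]
    orientation_diff_pct: float
    orientation_ci: tuple[float, float]
    seed: int


def _slope_ci(x: np.ndarray, y: np.ndarray, *, seed: int | None = None) -> tuple[FitResult, None]:
    """OLS fit with a 95% CI: t-based for n ≤ 10, percentile bootstrap beyond.

    The bootstrap (1000 resamples) requires a seed for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    n = x.size
    if n <= 10:
        tq = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(1000, n))
        slopes = np.array([stats.linregress(x[i], y[i]).slope for i in idx])
        ci = (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5)))
    return (
        FitResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_value=float(res.rvalue),
            slope_ci=(float(ci[0]), float(ci[1])),
            intercept_stderr=float(res.intercept_stderr),
        ),
        None,
    )


def linearity_fit(doses_gy: np.ndarray, charges_pc: np.ndarray) -> FitResult:
    """Ordinary least squares of charge (pC) on dose (Gy).

    The intercept estimates the electrometer/readout offset; the correlation
    close to 1 together with a small intercept demonstrates dose linearity.
    """
    doses_gy = np.asarray(doses_gy, dtype=float)
    if doses_gy.size < 3:
        raise ProtonDosimError("need at least 3 dose points")
    if np.ptp(doses_gy) == 0:
        raise ProtonDosimError("doses are rank-deficient (all equal)")
    fit, _ = _slope_ci(doses_gy, np.asarray(charges_pc, dtype=float))
    return fit


def decay_fit(
    accumulated_gy: np.ndarray,
    responses: np.ndarray,
    *,
    baseline: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Sensitivity-decay rate in percent response loss per 100 Gy accumulated.

    ``responses`` are per-probe readings (charge per unit probe dose);
    they are normalized to ``baseline`` (default: the mean response of the
    probes at the lowest accumulation) and regressed on accumulated dose.
    Returns ``(rate, ci)`` where rate = −slope rescaled to % per 100 Gy.
    """
    acc = np.asarray(accumulated_gy, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if acc.size < 3:
        raise ProtonDosimError("need at least 3 accumulation points")
    if np.any(np.diff(acc) < 0):
        raise ProtonDosimError("accumulated dose must be nondecreasing")
    if baseline is None:
        baseline = float(resp[acc == acc.min()].mean())
    norm = resp / baseline
    fit, _ = _slope_ci(acc, norm)
    to_pct = -100.0 * 100.0  # fraction/Gy -> % per 100 Gy, loss positive
    rate = to_pct * fit.slope
    ci = tuple(sorted((to_pct * fit.slope_ci[0], to_pct * fit.slope_ci[1])))
    return rate, ci


def orientation_difference(
    axial: np.ndarray, edge_on: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Axial vs edge-on response difference in percent, with a 95% t-interval.

    Per-replicate charge/MU values from both orientations are normalized to
    the maximum of all points; the estimate is |mean(edge-on) − mean(axial)|
    ×100 on that normalized scale.
    """
    a = np.asarray(axial, dtype=float)
    e = np.asarray(edge_on, dtype=float)
    if a.size < 2 or e.size < 2:
        raise ProtonDosimError("need at least 2 replicates per orientation")
    norm = max(a.max(), e.max())
    if norm <= 0:
        raise ProtonDosimError("zero normalization denominator")
    an, en = a / norm, e / norm
    diff = en.mean() - an.mean()
    se = np.sqrt(an.var(ddof=1) / an.size + en.var(ddof=1) / en.size)
    dof = a.size + e.size - 2
    tq = stats.t.ppf(0.975, dof)
    est = abs(diff) * 100.0
    ci = (max(0.0, (abs(diff) - tq * se) * 100.0), (abs(diff) + tq * se) * 100.0)
    return est, ci


def dose_rate_uniformity(
    rates_cgy_s: np.ndarray, responses: np.ndarray, *, seed: int = 0
) -> tuple[FitResult, str]:
    """Trend of normalized dose-per-MU response against dose rate.

    Returns the fit and the verdict ``"uniform"`` when the 95% CI of the
    slope covers zero, else ``"trend"``.
    """
    rates = np.asarray(rates_cgy_s, dtype=float)
    if rates.size < 3:
        raise ProtonDosimError("need at least 3 dose rates")
    fit, _ = _slope_ci(rates, np.asarray(responses, dtype=float), seed=seed)
    return fit, ("uniform" if fit.slope_covers_zero else "trend")


# ---------------------------------------------------------------------------
# experiment simulators (the four precursory experiments)
# ---------------------------------------------------------------------------

def simulate_linearity_experiment(
    det: DetectorSpec,
    model: ReadoutModel,
    rng: np.random.Generator,
    doses_gy: np.ndarray = LINEARITY_DOSES_GY,
    dose_rate: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Deliver the nine-dose design and record charges. Returns (doses, pC)."""
    charges = np.array(
        [readout_charge(d, 0.0, dose_rate, det, model, rng) for d in doses_gy]
    )
    return np.asarray(doses_gy, dtype=float), charges


def simulate_decay_experiment(
    det: DetectorSpec,
    model: ReadoutModel,
    rng: np.random.Generator,
    *,
    probe_dose: float = 2.0,
    probes_per_set: int = 3,
    accumulation_step: float = 56.0,
    n_accumulations: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline probe triplet, then probe triplets after repeated accumulations.

    Mirrors the radiation-damage protocol: average response from three 2 Gy
    probes, repeated after each 56 Gy accumulation. Probe doses themselves
    accrue to the accumulated total. Returns per-probe
    ``(accumulated_gy, response)`` with response = (charge − offset)/dose.
    """
    acc = 0.0
    xs, ys = [], []
    for k in range(n_accumulations + 1):
        if k > 0:
            acc += accumulation_step
        for _ in range(probes_per_set):
            q = readout_charge(probe_dose, acc, 1.5, det, model, rng)
            xs.append(acc)
            ys.append((q - model.offset) / probe_dose)
            acc += probe_dose
    return np.asarray(xs), np.asarray(ys)


def simulate_orientation_experiment(
    det_axial: DetectorSpec,
    det_edge: DetectorSpec,
    model: ReadoutModel,
    rng: np.random.Generator,
    *,
    dose_cgy: float = 170.0,
    replicates: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Four replicates of 170 cGy in each orientation; returns charge/MU pairs.

    Delivery is one MU per cGy here, so charge/MU is charge/dose.
    """
    dose_gy = dose_cgy / 100.0
    ax = np.array(
        [readout_charge(dose_gy, 0.0, 1.5, det_axial, model, rng) / dose_cgy
         for _ in range(replicates)]
    )
    eo = np.array(
        [readout_charge(dose_gy, 0.0, 1.5, det_edge, model, rng) / dose_cgy
         for _ in range(replicates)]
    )
    return ax, eo


def simulate_dose_rate_experiment(
    det: DetectorSpec,
    model: ReadoutModel,
    rng: np.random.Generator,
    rates_cgy_s: np.ndarray = DOSE_RATES_CGY_S,
    dose_gy: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed dose at each of the dose rates; returns (rates, normalized response)."""
    resp = np.array(
        [
            (readout_charge(dose_gy, 0.0, r, det, model, rng) - model.offset) / dose_gy
            for r in rates_cgy_s
        ]
    )
    return np.asarray(rates_cgy_s, dtype=float), resp / resp.mean()


# ---------------------------------------------------------------------------
# agreement tables
# ---------------------------------------------------------------------------

def agreement_table(
    profile_sets: dict[str, dict[str, Profile]],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-beam D50 (depth) or FWHM/FW90M (lateral) differences across modalities.

    ``profile_sets`` maps beam label -> {modality -> Profile}; every beam must
    carry the same modalities, otherwise an error lists the orphans. For each
    ``(a, b)`` pair the signed difference a − b is reported in mm.
    """
    if not profile_sets:
        raise ProtonDosimError("empty profile set")
    modalities = None
    orphans = []
    for label, prof_map in profile_sets.items():
        keys = set(prof_map)
        if modalities is None:
            modalities = keys
        elif keys != modalities:
            orphans.append(f"{label}: has {sorted(keys)}, expected {sorted(modalities)}")
    if orphans:
        raise ProtonDosimError("unmatched beams:\n" + "\n".join(orphans))
    mods = sorted(modalities)
    if pairs is None:
        ref = mods[0]
        pairs = [(m, ref) for m in mods if m != ref]
    rows = []
    for label, prof_map in profile_sets.items():
        axis = next(iter(prof_map.values())).axis
        quantities = ["d50"] if axis == "depth" else ["fwhm", "fw90m"]
        for qty in quantities:
            vals = {}
            for m in mods:
                p = prof_map[m]
                if qty == "d50":
                    vals[m] = d50_distal(p)
                else:
                    vals[m] = full_width(p, 0.5 if qty == "fwhm" else 0.9)
            row = {"beam": label, "quantity": qty}
            row.update({f"{m}_mm": vals[m] for m in mods})
            for a, b in pairs:
                row[f"{a}-{b}_mm"] = vals[a] - vals[b]
            rows.append(row)
    return pd.DataFrame(rows)
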