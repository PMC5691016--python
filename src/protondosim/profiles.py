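"""1-D dose profiles (depth-dose and transverse) and their container type."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ProtonDosimError

__all__ = ["Profile"]


@dataclass(frozen=True)
class Profile:
    """A 1-D relative-dose profile sampled on a strictly increasing position axis.

    Parameters
    ----------
    positions
        Sample positions in mm. Depth profiles use water-equivalent depth (WED)
        measured from the phantom surface along the beam; lateral profiles use
        off-axis distance.
    dose
        Nonnegative relative dose at each position.
    axis
        ``"depth"`` or ``"lateral"``.
    normalization
        ``"max"`` (max dose = 1), ``"com"`` (dose at the center of modulation = 1)
        or ``"raw"`` (unnormalized).
    meta
        Free-form provenance (beam label, detector, normalization details).
    """

    positions: np.ndarray
    dose: np.ndarray
    axis: str = "depth"
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        if pos.ndim != 1 or dose.ndim != 1 or pos.size != dose.size:
            raise ProtonDosimError("positions and dose must be 1-D arrays of equal length")
        if pos.size == 0:
            raise ProtonDosimError("profile must be nonempty")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ProtonDosimError("positions must be strictly increasing")
        if np.any(dose < 0):
            raise ProtonDosimError("relative dose must be nonnegative")
        if self.axis not in ("depth", "lateral"):
            raise ProtonDosimError(f"unknown profile axis {self.axis!r}")
        if self.normalization not in ("max", "com", "raw"):
            raise ProtonDosimError(f"unknown normalization mode {self.normalization!r}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dose", dose)

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return self.positions.size

    def __call__(self, x) -> np.ndarray:
        """Linear interpolation of dose at position(s) ``x`` (clamped at the ends)."""
        return np.interp(x, self.positions, self.dose)

    @property
    def max_dose(self) -> float:
        return float(self.dose.max())

    def with_dose(self, dose, *, normalization: str | None = None) -> "Profile":
        return replace(
            self,
            dose=np.asarray(dose, dtype=float),
            normalization=normalization or self.normalization,
        )

    def as_callable(self) -> Callable[[np.ndarray], np.ndarray]:
        return self.__call__
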