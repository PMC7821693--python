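"""CD thermal-melt analysis: MRE conversion and Tm extraction.

The melting temperature is located at the extremum of the first derivative of
the melting profile (signal versus temperature), refined by parabolic
interpolation through the extremum and its two neighbours.  Optional
Savitzky–Golay smoothing is available for noisy curves but is off by default:
at the usual 2 °C sampling the raw centered-difference derivative is already
well conditioned and smoothing should be an explicit analysis choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic_bundles import MeltCurve

__all__ = [
    "MeltResult",
    "NoTransitionError",
    "molar_residue_ellipticity",
    "melting_temperature",
]


class NoTransitionError(ValueError):
    """Raised when a melting profile shows no resolvable transition."""


@dataclass
class MeltResult:
    """Extracted melting temperature and bookkeeping."""

    tm: float
    derivative_extremum_value: float
    method: str = "first_derivative"
    smoothing_window: int | None = None


def molar_residue_ellipticity(
    theta_mdeg: float | np.ndarray,
    concentration: float,
    n_residues: int,
    pathlength: float,
) -> float | np.ndarray:
    """Convert observed ellipticity (mdeg) to mean residue ellipticity.

    MRE = θ_mdeg / (10 · n_residues · c · l) in deg·cm²·dmol⁻¹, with the
    molar concentration ``c`` in mol/L and the cuvette ``pathlength`` in cm.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    out = np.asarray(theta_mdeg, dtype=float) / (
        10.0 * n_residues * concentration * pathlength
    )
    return float(out) if out.ndim == 0 else out


def melting_temperature(
    curve: MeltCurve, smoothing_window: int | None = None
) -> MeltResult:
    """Tm from the extremum of the first derivative of the melting profile.

    The derivative is a centered finite difference on the (optionally
    Savitzky–Golay smoothed, polynomial order 2) signal; the extremum
    temperature is refined by fitting a parabola through the extremum and its
    neighbours.  Raises :class:`NoTransitionError` for flat or purely linear
    profiles, where the derivative has no extremum above the numerical noise
    floor.
    """
    t = curve.temperatures
    y = curve.signal.astype(float)
    if smoothing_window is not None:
        if smoothing_window < 3 or smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be an odd integer >= 3")
        y = savgol_filter(y, smoothing_window, polyorder=2)

    amplitude = float(np.ptp(y))
    if amplitude <= 1e-12:
        raise NoTransitionError("flat melting profile: no transition")
    deriv = np.gradient(y, t)
    # a linear drift has (numerically) constant derivative: no transition
    if float(np.ptp(np.abs(deriv))) <= 1e-9 * np.max(np.abs(deriv)):
        raise NoTransitionError("monotone-linear profile: no transition")

    k = int(np.argmax(np.abs(deriv)))
    if k == 0 or k == len(t) - 1:
        # extremum at the grid edge: the transition midpoint is outside
        # (or at the border of) the scanned range
        raise NoTransitionError("derivative extremum at grid edge")
    # parabolic refinement through (k-1, k, k+1) on |derivative|
    y0, y1, y2 = np.abs(deriv[k - 1 : k + 2])
    denom = y0 - 2.0 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
    offset = float(np.clip(offset, -1.0, 1.0))
    # local grid spacing (grids may be non-uniform)
    h = 0.5 * (t[k + 1] - t[k - 1])
    tm = float(t[k] + offset * h)
    return MeltResult(
        tm=tm,
        derivative_extremum_value=float(deriv[k]),
        method="first_derivative",
        smoothing_window=smoothing_window,
    )
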