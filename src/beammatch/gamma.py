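"""1-D and 2-D gamma-index engine.

The gamma index combines a dose-difference criterion (percent of the global
normalisation dose, taken as the reference maximum) with a
distance-to-agreement (DTA) criterion:

    gamma(r) = min over r' of sqrt( |r - r'|^2 / dta^2  +  (D_e(r') - D_r(r))^2 / dd^2 )

A reference point passes when gamma <= 1 (boundary inclusive).  The evaluated
distribution is linearly interpolated at search positions spaced dta/10, and
the search is restricted to |r' - r| <= 3*dta; a point whose true optimum lies
outside that window therefore reports the windowed minimum (>= 3), which is
always a clear failure.  Reference points below the low-dose threshold are
excluded from the summary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "DosePlane",
    "gamma_1d",
    "gamma_2d",
    "summarize",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: DTA (mm), dose difference (% of global max), threshold (%)."""

    dta_mm: float
    dose_diff_pct: float
    low_dose_threshold_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.dta_mm <= 0 or self.dose_diff_pct <= 0:
            raise ValueError("dta and dose_diff must be positive")
        if not 0.0 <= self.low_dose_threshold_pct < 100.0:
            raise ValueError("low-dose threshold must be in [0, 100)")


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values for the evaluated reference points."""

    gamma_values: np.ndarray
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_values, dtype=float)
        if g.ndim != 1 or np.any(g < 0):
            raise ValueError("gamma values must be a 1-D non-negative array")
        object.__setattr__(self, "gamma_values", g)

    @property
    def n_evaluated(self) -> int:
        return int(self.gamma_values.size)

    @property
    def passing_rate(self) -> float:
        """Percent of evaluated points with gamma <= 1.

        The boundary is inclusive; a 1e-9 tolerance keeps points sitting
        exactly on the criterion from flipping on floating-point roundoff.
        """
        if self.n_evaluated == 0:
            raise ValueError("no evaluated points")
        return float(100.0 * np.mean(self.gamma_values <= 1.0 + 1e-9))

    @property
    def mean_gamma(self) -> float:
        if self.n_evaluated == 0:
            raise ValueError("no evaluated points")
        return float(np.mean(self.gamma_values))


@dataclass(frozen=True)
class DosePlane:
    """A 2-D planar dose image on a square-pitch grid.

    ``dose[iy, ix]`` maps to beam coordinates
    ``x = origin[0] + ix*pitch``, ``y = origin[1] + iy*pitch``.
    """

    dose: np.ndarray
    pitch_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.ndim != 2:
            raise ValueError("dose must be a 2-D array")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "origin_mm", (float(self.origin_mm[0]), float(self.origin_mm[1])))

    @property
    def x_mm(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.dose.shape[1]) * self.pitch_mm

    @property
    def y_mm(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.dose.shape[0]) * self.pitch_mm


_WINDOW_DTAS = 3.0   # search window half-width in units of dta
_FINE_DIVISOR = 10   # search step = dta / _FINE_DIVISOR


def gamma_1d(reference, evaluated, criteria: GammaCriteria) -> GammaResult:
    """Gamma analysis of two 1-D depth-dose curves.

    Parameters
    ----------
    reference, evaluated
        Objects with ``depth_mm`` and ``dose`` arrays on uniform grids
        (e.g. :class:`beammatch.idd.IDDCurve`), both normalised consistently;
        dose differences are taken in percent of the reference maximum.
    """
    z_ref = np.asarray(reference.depth_mm, dtype=float)
    d_ref = np.asarray(reference.dose, dtype=float)
    z_ev = np.asarray(evaluated.depth_mm, dtype=float)
    d_ev = np.asarray(evaluated.dose, dtype=float)
    if z_ev[0] > z_ref[-1] or z_ev[-1] < z_ref[0]:
        raise ValueError("reference and evaluated curves do not overlap")

    norm = d_ref.max()
    if norm <= 0:
        raise ValueError("reference curve has no positive dose")
    keep = d_ref >= criteria.low_dose_threshold_pct / 100.0 * norm
    if not np.any(keep):
        raise ValueError("low-dose threshold excludes every reference point")
    z_r, d_r = z_ref[keep], d_ref[keep]

    n_off = _WINDOW_DTAS * _FINE_DIVISOR
    deltas = np.arange(-n_off, n_off + 1) * (criteria.dta_mm / _FINE_DIVISOR)
    pos = z_r[:, None] + deltas[None, :]                      # (n_ref, n_off)
    d_e = np.interp(pos, z_ev, d_ev)
    dist2 = (deltas / criteria.dta_mm) ** 2
    dd = criteria.dose_diff_pct / 100.0 * norm
    gam2 = dist2[None, :] + ((d_e - d_r[:, None]) / dd) ** 2
    gam2[(pos < z_ev[0]) | (pos > z_ev[-1])] = np.inf        # no extrapolation
    gamma = np.sqrt(gam2.min(axis=1))
    if not np.all(np.isfinite(gamma)):
        raise ValueError("some reference points have no evaluated point in range")
    return GammaResult(gamma, criteria)


def gamma_2d(reference: DosePlane, evaluated: DosePlane, criteria: GammaCriteria) -> GammaResult:
    """Gamma analysis of two planar dose distributions.

    The reference is typically the measured (coarse) grid and the evaluated
    the computed (fine) grid; the evaluated plane is bilinearly interpolated
    at search positions on a dta/10 polar-disc grid of radius 3*dta.
    """
    if (
        reference.x_mm[0] > evaluated.x_mm[-1]
        or reference.x_mm[-1] < evaluated.x_mm[0]
        or reference.y_mm[0] > evaluated.y_mm[-1]
        or reference.y_mm[-1] < evaluated.y_mm[0]
    ):
        raise ValueError("reference and evaluated planes do not overlap")

    norm = reference.dose.max()
    if norm <= 0:
        raise ValueError("reference plane has no positive dose")
    yy, xx = np.meshgrid(reference.y_mm, reference.x_mm, indexing="ij")
    keep = reference.dose >= criteria.low_dose_threshold_pct / 100.0 * norm
    if not np.any(keep):
        raise ValueError("low-dose threshold excludes every reference point")
    rx, ry = xx[keep], yy[keep]
    d_r = reference.dose[keep]

    step = criteria.dta_mm / _FINE_DIVISOR
    n_off = _WINDOW_DTAS * _FINE_DIVISOR
    off = np.arange(-n_off, n_off + 1) * step
    ox, oy = np.meshgrid(off, off)
    in_disc = ox**2 + oy**2 <= (_WINDOW_DTAS * criteria.dta_mm) ** 2 + 1e-12
    ox, oy = ox[in_disc], oy[in_disc]                         # (n_off,)
    dist2 = (ox**2 + oy**2) / criteria.dta_mm**2

    px = rx[:, None] + ox[None, :]                            # (n_ref, n_off)
    py = ry[:, None] + oy[None, :]
    # fractional pixel indices into the evaluated grid
    ix = (px - evaluated.origin_mm[0]) / evaluated.pitch_mm
    iy = (py - evaluated.origin_mm[1]) / evaluated.pitch_mm
    inside = (
        (ix >= 0) & (ix <= evaluated.dose.shape[1] - 1)
        & (iy >= 0) & (iy <= evaluated.dose.shape[0] - 1)
    )
    d_e = map_coordinates(
        evaluated.dose, [iy.ravel(), ix.ravel()], order=1, mode="nearest"
    ).reshape(ix.shape)
    dd = criteria.dose_diff_pct / 100.0 * norm
    gam2 = dist2[None, :] + ((d_e - d_r[:, None]) / dd) ** 2
    gam2[~inside] = np.inf
    gamma = np.sqrt(gam2.min(axis=1))
    if not np.all(np.isfinite(gamma)):
        raise ValueError("some reference points have no evaluated point in range")
    return GammaResult(gamma, criteria)


def summarize(result: GammaResult) -> tuple[float, float]:
    """(passing rate in %, mean gamma) over the evaluated points."""
    if result.n_evaluated == 0:
        raise ValueError("empty evaluation set")
    return result.passing_rate, result.mean_gamma
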