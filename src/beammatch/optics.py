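"""Spot-profile extraction, Gaussian sigma fitting and Fermi-Eyges optics.

The scanned-beam spot at a plane z is treated as a single 2-D cylindrical
Gaussian.  From a planar image of the 5-spot test pattern, the five spots are
extracted, recentred and averaged into an *equivalent spot*; its X and Y cross
sections are fitted with a 1-D Gaussian to obtain sigma per axis.

Under free drift the transverse second moments of the phase space propagate
so that the beam width is a quadratic in z:

    sigma^2(z) = A + 2*B*z + C*z^2

with A the spatial variance (mm^2), B the spatial-angular covariance
(mm*mrad) and C the angular variance (mrad^2) at the reference plane, when z
is expressed in metres (1 mrad * 1 m = 1 mm).  Fitting this quadratic to the
sigmas measured at five planes yields the beam-optics moments at the
isocenter; :class:`FermiEygesModel` / :class:`FermiEygesResults` implement the
fit in Model/Results style.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .gamma import DosePlane

__all__ = [
    "SpotPlane",
    "SpotPattern",
    "five_spot_pattern",
    "EquivalentSpot",
    "GaussianFit",
    "OpticsMoments",
    "FermiEygesModel",
    "FermiEygesResults",
    "extract_spots",
    "average_spot",
    "cross_sections",
    "fit_gaussian",
    "fit_fe_moments",
    "sigma_at",
    "relative_difference",
]

PLANE_POSITIONS_MM = (-300.0, -150.0, 0.0, 150.0, 300.0)


@dataclass(frozen=True)
class SpotPlane(DosePlane):
    """A planar spot image at distance ``z_mm`` from the isocenter.

    z is positive downstream (beam direction).
    """

    z_mm: float = 0.0
    energy: float | None = None


@dataclass(frozen=True)
class SpotPattern:
    """Nominal spot positions (mm) of a test pattern and their nominal sigma."""

    positions_mm: tuple[tuple[float, float], ...]
    nominal_sigma_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.nominal_sigma_mm <= 0:
            raise ValueError("nominal sigma must be positive")


def five_spot_pattern(spacing_mm: float = 80.0, nominal_sigma_mm: float = 4.0) -> SpotPattern:
    """Centre spot plus four corner spots at (+/-spacing, +/-spacing)."""
    s = spacing_mm
    return SpotPattern(
        positions_mm=((0.0, 0.0), (s, s), (s, -s), (-s, s), (-s, -s)),
        nominal_sigma_mm=nominal_sigma_mm,
    )


@dataclass(frozen=True)
class EquivalentSpot:
    """The pixelwise average of the five recentred spot sub-images."""

    dose: np.ndarray
    pitch_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("equivalent spot must be a square 2-D image")
        object.__setattr__(self, "dose", d)

    @property
    def center_index(self) -> int:
        return self.dose.shape[0] // 2

    @property
    def axis_mm(self) -> np.ndarray:
        n = self.dose.shape[0]
        return (np.arange(n) - self.center_index) * self.pitch_mm


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of a 1-D Gaussian-plus-baseline least-squares fit."""

    mu_mm: float
    sigma_mm: float
    amplitude: float
    baseline: float
    rms_residual: float


@dataclass(frozen=True)
class OpticsMoments:
    """Fermi-Eyges second moments at the reference plane (z_ref, one axis).

    A: spatial variance <x^2> (mm^2); B: spatial-angular covariance <x theta>
    (mm*mrad); C: angular variance <theta^2> (mrad^2).  B < 0 denotes a beam
    converging towards a downstream waist.

    Physically C is a variance and therefore non-negative, but an
    unconstrained quadratic fit to noisy sigmas may return a slightly
    negative C; the binding requirement is that sigma^2(z) stays positive
    over the measurement span, which the fit enforces.
    """

    A: float
    B: float
    C: float
    z_ref_mm: float = 0.0
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("spatial variance A must be positive")


def sigma_at(moments: OpticsMoments, z_mm: float | np.ndarray) -> float | np.ndarray:
    """Beam sigma (mm) at distance z (mm) from the reference plane."""
    z_m = (np.asarray(z_mm, dtype=float) - moments.z_ref_mm) / 1000.0
    var = moments.A + 2.0 * moments.B * z_m + moments.C * z_m**2
    if np.any(var <= 0):
        raise ValueError("moments give non-positive variance at the requested z")
    s = np.sqrt(var)
    return float(s) if np.isscalar(z_mm) else s


def extract_spots(
    plane: SpotPlane | DosePlane,
    pattern: SpotPattern,
    max_centroid_shift_mm: float = 5.0,
) -> list[np.ndarray]:
    """Cut and recentre one square sub-image per pattern spot.

    The background (median of the outer 5 % border frame) is subtracted and
    negative pixels clipped; a square ROI of half-width 8 nominal sigmas is
    cut around each nominal position and recentred on the nearest pixel to its
    intensity centroid.
    """
    img = plane.dose
    ny, nx = img.shape
    border = max(1, int(round(0.05 * min(ny, nx))))
    mask = np.zeros_like(img, dtype=bool)
    mask[:border, :] = mask[-border:, :] = True
    mask[:, :border] = mask[:, -border:] = True
    bg = float(np.median(img[mask]))
    clean = np.clip(img - bg, 0.0, None)
    if clean.max() <= 0:
        raise ValueError("image contains no signal above background")

    pitch = plane.pitch_mm
    half_px = int(round(8.0 * pattern.nominal_sigma_mm / pitch))
    x0, y0 = plane.origin_mm
    centers_px: list[tuple[int, int]] = []
    rois: list[np.ndarray] = []
    for (sx, sy) in pattern.positions_mm:
        jx = int(round((sx - x0) / pitch))
        jy = int(round((sy - y0) / pitch))
        if (
            jx - half_px < 0 or jx + half_px >= nx
            or jy - half_px < 0 or jy + half_px >= ny
        ):
            raise ValueError("pattern spot ROI extends outside the image")
        roi = clean[jy - half_px : jy + half_px + 1, jx - half_px : jx + half_px + 1]
        tot = roi.sum()
        if tot <= 0:
            raise ValueError("no signal in spot ROI")
        iy, ix = np.indices(roi.shape)
        cy = float((iy * roi).sum() / tot) - half_px
        cx = float((ix * roi).sum() / tot) - half_px
        if np.hypot(cx * pitch, cy * pitch) > max_centroid_shift_mm:
            raise ValueError(
                f"spot centroid displaced {np.hypot(cx * pitch, cy * pitch):.1f} mm "
                f"from nominal position ({sx}, {sy})"
            )
        ky, kx = jy + int(round(cy)), jx + int(round(cx))
        if (
            kx - half_px < 0 or kx + half_px >= nx
            or ky - half_px < 0 or ky + half_px >= ny
        ):
            raise ValueError("recentred ROI extends outside the image")
        centers_px.append((ky, kx))
        rois.append(clean[ky - half_px : ky + half_px + 1, kx - half_px : kx + half_px + 1])

    for i in range(len(centers_px)):
        for j in range(i + 1, len(centers_px)):
            dy = abs(centers_px[i][0] - centers_px[j][0])
            dx = abs(centers_px[i][1] - centers_px[j][1])
            if dy <= 2 * half_px and dx <= 2 * half_px:
                raise ValueError("spot ROIs overlap; pattern too tight for 8-sigma ROIs")
    return rois


def average_spot(sub_images: list[np.ndarray], pitch_mm: float) -> EquivalentSpot:
    """Pixelwise arithmetic mean of the recentred spot sub-images."""
    shapes = {s.shape for s in sub_images}
    if len(shapes) != 1:
        raise ValueError("sub-images must share a common shape")
    return EquivalentSpot(np.mean(np.stack(sub_images), axis=0), pitch_mm)


def cross_sections(spot: EquivalentSpot) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """X and Y profiles through the spot centroid (nearest grid line).

    Returns ``((x_mm, values_x), (y_mm, values_y))``.
    """
    img = spot.dose
    tot = img.sum()
    if tot <= 0:
        raise ValueError("empty spot image")
    iy, ix = np.indices(img.shape)
    cy = int(round(float((iy * img).sum() / tot)))
    cx = int(round(float((ix * img).sum() / tot)))
    ax = spot.axis_mm
    return (ax, img[cy, :].copy()), (ax, img[:, cx].copy())


def _gauss(x, amp, mu, sigma, base):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + base


def fit_gaussian(x_mm: np.ndarray, values: np.ndarray, max_iter: int = 200) -> GaussianFit:
    """Nonlinear least-squares fit of a single Gaussian plus flat baseline.

    Initialised from the profile moments (centroid, RMS width, minimum).
    """
    x = np.asarray(x_mm, dtype=float)
    v = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 profile points")
    base0 = float(v.min())
    w = np.clip(v - base0, 0.0, None)
    if w.max() <= 0:
        raise ValueError("profile has no positive peak")
    mu0 = float((x * w).sum() / w.sum())
    sig0 = float(np.sqrt((w * (x - mu0) ** 2).sum() / w.sum()))
    sig0 = max(sig0, (x[1] - x[0]) / 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss,
                x,
                v,
                p0=[float(w.max()), mu0, sig0, base0],
                maxfev=max_iter * 5,
            )
    except RuntimeError as err:
        raise RuntimeError("Gaussian fit did not converge") from err
    amp, mu, sigma, base = popt
    sigma = abs(float(sigma))
    if sigma <= 0 or amp <= 0:
        raise RuntimeError("Gaussian fit collapsed to a degenerate solution")
    resid = v - _gauss(x, *popt)
    rms = float(np.sqrt(np.mean(resid**2)) / max(abs(amp), 1e-300))
    return GaussianFit(float(mu), sigma, float(amp), float(base), rms)


class FermiEygesModel:
    """Quadratic free-drift fit of measured sigmas over planes.

    Parameters
    ----------
    z_mm : array-like
        Plane positions relative to the isocenter (mm, >= 3 distinct values).
    sigma_mm : array-like
        Fitted single-Gaussian spot sigmas at those planes (mm, > 0).
    axis : str
        Scanning axis label ('x' or 'y').
    """

    def __init__(self, z_mm, sigma_mm, axis: str = "x"):
        z = np.asarray(z_mm, dtype=float)
        s = np.asarray(sigma_mm, dtype=float)
        if z.shape != s.shape or z.ndim != 1:
            raise ValueError("z and sigma must be 1-D arrays of equal length")
        if np.unique(z).size < 3:
            raise ValueError("need at least 3 distinct planes")
        if np.any(s <= 0):
            raise ValueError("all sigmas must be positive")
        self.z_mm = z
        self.sigma_mm = s
        self.axis = axis

    def fit(self) -> "FermiEygesResults":
        z_m = self.z_mm / 1000.0
        X = np.column_stack([np.ones_like(z_m), 2.0 * z_m, z_m**2])
        y = self.sigma_mm**2
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise ValueError("rank-deficient design: planes do not constrain a quadratic")
        A, B, C = (float(c) for c in coef)
        if C < 0 and C > -1e-9 * max(A, 1.0):
            C = 0.0  # exact-arithmetic noise on noiseless data
        # positivity of sigma^2 over the measurement span [-300, 300] mm
        zz = np.linspace(-0.3, 0.3, 601)
        if np.any(A + 2 * B * zz + C * zz**2 <= 0):
            raise ValueError("fitted variance non-positive within the plane span")
        moments = OpticsMoments(A=A, B=B, C=C, z_ref_mm=0.0, axis=self.axis)
        resid = y - X @ coef
        return FermiEygesResults(self, moments, float(np.sqrt(np.mean(resid**2))))


@dataclass(frozen=True)
class FermiEygesResults:
    """Fitted beam-optics moments with residual diagnostics."""

    model: FermiEygesModel
    moments: OpticsMoments
    rms_residual_mm2: float

    def sigma_at(self, z_mm):
        """Model sigma (mm) at any z (mm)."""
        return sigma_at(self.moments, z_mm)

    def summary(self) -> pd.DataFrame:
        m = self.moments
        return pd.DataFrame(
            {
                "axis": [m.axis],
                "spatial_variance_mm2": [m.A],
                "covariance_mm_mrad": [m.B],
                "angular_variance_mrad2": [m.C],
                "sigma_iso_mm": [float(np.sqrt(m.A))],
                "rms_residual_mm2": [self.rms_residual_mm2],
                "n_planes": [self.model.z_mm.size],
            }
        )


def fit_fe_moments(sigmas: list[tuple[float, float]], axis: str = "x") -> OpticsMoments:
    """Fit free-drift moments from ``[(z_mm, sigma_mm), ...]`` pairs."""
    z, s = zip(*sigmas)
    return FermiEygesModel(np.asarray(z), np.asarray(s), axis).fit().moments


def relative_difference(a: float, b: float) -> float:
    """100 * (a - b) / b; b is the comparison baseline."""
    if b == 0:
        raise ZeroDivisionError("relative difference baseline is zero")
    return 100.0 * (a - b) / b
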