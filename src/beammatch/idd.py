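"""Integrated depth-dose (IDD) curves and effective energy-spectrum fitting.

A measured IDD curve for a nominal beam energy is modelled as a non-negative
linear combination of pre-calculated mono-energetic pristine Bragg peaks; the
superposition weights form the beam's *effective energy spectrum*.  The fit is
a plain non-negative least-squares (NNLS) problem

    min_w || d - B w ||_2   s.t.  w >= 0

where the columns of B are unit-maximum pristine peaks on the measurement
depth grid.  The fitted spectrum is renormalised to unit sum with the overall
amplitude kept as a separate scale factor, so spectra are comparable across
nominal energies after all curves are normalised to unity.

The modelling interface follows the Model/Results convention:
``EffectiveSpectrumModel(measured, basis).fit()`` returns a
:class:`SpectrumFitResults` carrying the spectrum, the reconstructed
("computed") curve, the residual, R80 and the R80 Energy.  Functional wrappers
(:func:`fit_spectrum`, :func:`reconstruct_idd`, :func:`r80`,
:func:`r80_energy`) expose the same operations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls

from .config import BeamLineConfig
from .physics import energy_from_range, mono_bragg, range_from_energy

__all__ = [
    "IDDCurve",
    "PristineBasis",
    "EnergySpectrum",
    "EffectiveSpectrumModel",
    "SpectrumFitResults",
    "resample_curve",
    "normalize_unity",
    "build_basis",
    "fit_spectrum",
    "reconstruct_idd",
    "r80",
    "r80_energy",
]


@dataclass(frozen=True)
class IDDCurve:
    """A 1-D depth-dose curve on a uniform depth grid.

    Attributes
    ----------
    depth_mm : numpy.ndarray
        Strictly increasing uniform depth grid (mm).
    dose : numpy.ndarray
        Non-negative dose values (normalised or arbitrary units).
    nominal_energy : float or None
        Nominal beam energy (MeV) the curve belongs to, if any.
    """

    depth_mm: np.ndarray
    dose: np.ndarray
    nominal_energy: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, dtype=float)
        v = np.asarray(self.dose, dtype=float)
        if d.ndim != 1 or d.shape != v.shape:
            raise ValueError("depth and dose must be 1-D arrays of equal length")
        steps = np.diff(d)
        if d.size < 2 or np.any(steps <= 0) or not np.allclose(
            steps, steps[0], rtol=1e-6, atol=1e-9
        ):
            raise ValueError("depth grid must be uniform and strictly increasing")
        if np.any(v < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "depth_mm", d)
        object.__setattr__(self, "dose", v)

    @property
    def grid_step(self) -> float:
        return float(self.depth_mm[1] - self.depth_mm[0])


@dataclass(frozen=True)
class PristineBasis:
    """Mono-energetic pristine Bragg peaks on a shared depth grid.

    ``member_curves`` has one row per member energy; each row is normalised to
    unit maximum.
    """

    member_energies: np.ndarray
    member_curves: np.ndarray
    depth_mm: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.member_energies, dtype=float)
        c = np.asarray(self.member_curves, dtype=float)
        d = np.asarray(self.depth_mm, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("member energies must be strictly increasing")
        if c.shape != (e.size, d.size):
            raise ValueError("member_curves must be (n_members, n_depths)")
        object.__setattr__(self, "member_energies", e)
        object.__setattr__(self, "member_curves", c)
        object.__setattr__(self, "depth_mm", d)

    def __len__(self) -> int:
        return int(self.member_energies.size)


@dataclass(frozen=True)
class EnergySpectrum:
    """Non-negative superposition weights over mono-energetic peaks.

    Weights are normalised to unit sum; the overall curve amplitude is kept
    separately (see :class:`SpectrumFitResults.scale`).
    """

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1:
            raise ValueError("energies and weights must be 1-D arrays of equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise ValueError("spectrum must have positive total weight")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / s)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    @property
    def sigma_energy(self) -> float:
        mu = self.mean_energy
        return float(np.sqrt(np.sum(self.weights * (self.energies - mu) ** 2)))


def resample_curve(curve: IDDCurve, step_mm: float) -> IDDCurve:
    """Cubic-spline resample onto a uniform grid with the given step.

    The new grid spans the same depth range (first point preserved exactly;
    extrapolation is never performed).
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    if curve.depth_mm.size < 4:
        raise ValueError("need at least 4 points for spline resampling")
    start, stop = curve.depth_mm[0], curve.depth_mm[-1]
    n = int(np.floor((stop - start) / step_mm + 1e-9))
    new_depth = start + np.arange(n + 1) * step_mm
    spline = CubicSpline(curve.depth_mm, curve.dose)
    new_dose = spline(new_depth)
    new_dose[new_dose < 0] = 0.0
    return IDDCurve(new_depth, new_dose, curve.nominal_energy)


def normalize_unity(curve: IDDCurve) -> IDDCurve:
    """Renormalise so the curve maximum is exactly 1."""
    peak = curve.dose.max()
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero curve")
    return replace(curve, dose=curve.dose / peak)


def build_basis(
    nominal_energy: float,
    depth_grid_mm: np.ndarray,
    config: BeamLineConfig = BeamLineConfig(),
    half_width_mev: float = 10.0,
    step_mev: float = 0.5,
) -> PristineBasis:
    """Pristine-peak basis at ``nominal_energy +/- half_width`` (unit maxima).

    Defaults give 41 members at 0.5 MeV spacing, a span wide enough to resolve
    sub-MeV effective spectra while keeping the NNLS system well conditioned.
    """
    if half_width_mev <= 0 or step_mev <= 0:
        raise ValueError("half_width and step must be positive")
    n = int(round(half_width_mev / step_mev))
    energies = nominal_energy + (np.arange(2 * n + 1) - n) * step_mev
    grid = np.asarray(depth_grid_mm, dtype=float)
    curves = np.empty((energies.size, grid.size))
    for i, e in enumerate(energies):
        c = mono_bragg(range_from_energy(e, config), grid, config)
        curves[i] = c / c.max()
    return PristineBasis(energies, curves, grid)


class EffectiveSpectrumModel:
    """NNLS deconvolution of a measured IDD into an effective energy spectrum.

    Parameters
    ----------
    measured : IDDCurve
        The measured curve; must share the basis depth grid (resample first).
    basis : PristineBasis
        Pre-calculated mono-energetic pristine peaks.
    """

    def __init__(self, measured: IDDCurve, basis: PristineBasis):
        if len(basis) == 0:
            raise ValueError("basis is empty")
        if measured.depth_mm.shape != basis.depth_mm.shape or not np.allclose(
            measured.depth_mm, basis.depth_mm, atol=1e-9
        ):
            raise ValueError("measured curve and basis must share the depth grid")
        self.measured = measured
        self.basis = basis

    def fit(self) -> "SpectrumFitResults":
        A = self.basis.member_curves.T
        w, rnorm = nnls(A, self.measured.dose, maxiter=50 * A.shape[1])
        total = w.sum()
        if total <= 0:
            raise RuntimeError("NNLS returned an all-zero spectrum")
        spectrum = EnergySpectrum(self.basis.member_energies, w / total)
        return SpectrumFitResults(
            model=self, spectrum=spectrum, scale=float(total), residual_norm=float(rnorm)
        )


@dataclass(frozen=True)
class SpectrumFitResults:
    """Results of an effective energy-spectrum fit.

    Attributes
    ----------
    spectrum : EnergySpectrum
        Unit-sum non-negative weights over the basis energies.
    scale : float
        Overall amplitude absorbed out of the weights.
    residual_norm : float
        Euclidean norm of the NNLS residual.
    """

    model: EffectiveSpectrumModel
    spectrum: EnergySpectrum
    scale: float
    residual_norm: float

    def reconstruction(self) -> IDDCurve:
        """The model-reconstructed ("computed") IDD, normalised to unity."""
        return reconstruct_idd(self.spectrum, self.model.basis)

    def r80(self) -> float:
        """Distal 80 % depth (mm) of the reconstructed curve."""
        return r80(self.reconstruction())

    def r80_energy(self, config: BeamLineConfig = BeamLineConfig()) -> float:
        """Single equivalent energy (MeV) with the same R80 as the spectrum."""
        return energy_from_range(self.r80() / 10.0, config)

    def summary(self) -> pd.DataFrame:
        """One-row summary table of the fit."""
        meas = normalize_unity(self.model.measured)
        rms = float(
            np.sqrt(np.mean((meas.dose - self.reconstruction().dose) ** 2))
        )
        return pd.DataFrame(
            {
                "nominal_energy_MeV": [self.model.measured.nominal_energy],
                "mean_energy_MeV": [self.spectrum.mean_energy],
                "sigma_energy_MeV": [self.spectrum.sigma_energy],
                "r80_mm": [self.r80()],
                "r80_energy_MeV": [self.r80_energy()],
                "n_active_weights": [int(np.sum(self.spectrum.weights > 1e-6))],
                "rms_residual_unity": [rms],
            }
        )


def fit_spectrum(measured: IDDCurve, basis: PristineBasis) -> EnergySpectrum:
    """Fit the effective energy spectrum of a measured IDD (NNLS weights)."""
    return EffectiveSpectrumModel(measured, basis).fit().spectrum


def reconstruct_idd(spectrum: EnergySpectrum, basis: PristineBasis) -> IDDCurve:
    """Weighted superposition of basis peaks, renormalised to unity."""
    idx = np.searchsorted(basis.member_energies, spectrum.energies)
    if np.any(idx >= len(basis)) or not np.allclose(
        basis.member_energies[np.clip(idx, 0, len(basis) - 1)], spectrum.energies
    ):
        raise ValueError("spectrum energies must be a subset of basis energies")
    dose = spectrum.weights @ basis.member_curves[idx]
    return normalize_unity(
        IDDCurve(basis.depth_mm, dose, float(spectrum.mean_energy))
    )


def r80(curve: IDDCurve) -> float:
    """Distal depth (mm) where dose first falls through 80 % of the maximum.

    Located by linear interpolation between the bracketing grid points distal
    to the global maximum.
    """
    dose = curve.dose
    i_peak = int(np.argmax(dose))
    level = 0.8 * dose[i_peak]
    distal = dose[i_peak:]
    below = np.nonzero(distal <= level)[0]
    if below.size == 0:
        raise ValueError("curve is truncated before the distal 80% falloff")
    j = i_peak + int(below[0])
    if j == i_peak:
        return float(curve.depth_mm[j])
    z0, z1 = curve.depth_mm[j - 1], curve.depth_mm[j]
    d0, d1 = dose[j - 1], dose[j]
    return float(z0 + (d0 - level) / (d0 - d1) * (z1 - z0))


def r80_energy(
    spectrum: EnergySpectrum,
    basis: PristineBasis,
    config: BeamLineConfig = BeamLineConfig(),
) -> float:
    """Energy (MeV) of the mono-energetic beam sharing the spectrum's R80."""
    return energy_from_range(r80(reconstruct_idd(spectrum, basis)) / 10.0, config)
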