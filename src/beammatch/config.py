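"""Configuration objects for the beam line, gantry perturbations and detectors.

All dataclasses here are frozen value objects that can round-trip through a
YAML config file (see :func:`load_config` / :func:`save_config`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "BeamLineConfig",
    "GantryPerturbation",
    "DetectorSpec",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class BeamLineConfig:
    """Constants describing one beam line.

    The range-energy relation is a power law ``R = alpha * E**p`` (R in cm of
    water, E in MeV) and range straggling grows with range as
    ``sigma = straggling_k * R**straggling_m`` (cm).  The virtual source-axis
    distances are stored as metadata only; no computation uses them.

    Parameters
    ----------
    alpha, p
        Range-energy power-law coefficient (cm * MeV**-p) and exponent.
    straggling_k, straggling_m
        Straggling power-law coefficient (cm**(1-m)) and exponent.
    depth_max_mm, depth_step_mm
        Default water depth grid: ``[0, depth_max_mm]`` at ``depth_step_mm``.
    sad_x_cm, sad_y_cm
        Virtual SADs per scanning axis (metadata).
    """

    alpha: float = 0.0022
    p: float = 1.77
    straggling_k: float = 0.012
    straggling_m: float = 0.935
    depth_max_mm: float = 350.0
    depth_step_mm: float = 0.1
    sad_x_cm: float = 221.5
    sad_y_cm: float = 184.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 1.0 < self.p < 2.0:
            raise ValueError("range-energy exponent p must lie in (1, 2)")
        if not (self.straggling_k > 0 and self.straggling_m > 0):
            raise ValueError("straggling coefficients must be positive")
        if not (self.depth_max_mm > 0 and self.depth_step_mm > 0):
            raise ValueError("depth grid parameters must be positive")


@dataclass(frozen=True)
class GantryPerturbation:
    """Small systematic + stochastic deviations applied to one gantry.

    The identity perturbation (all defaults) leaves the nominal beam model
    untouched and noise-free.

    Parameters
    ----------
    range_offset_mm
        Rigid shift applied to every Bragg peak's range.
    spectrum_sigma_scale
        Multiplier on the energy-spread sigma_E.
    sigma_scale
        Multiplier on the spot sigma per axis.
    spot_jitter_mm
        Standard deviation of random per-spot position offsets.
    dose_noise
        Relative s.d. of multiplicative (lognormal) dose noise.
    seed
        Extra seed component mixed into the gantry's random stream.
    """

    range_offset_mm: float = 0.0
    spectrum_sigma_scale: float = 1.0
    sigma_scale: float = 1.0
    spot_jitter_mm: float = 0.0
    dose_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.spectrum_sigma_scale > 0 and self.sigma_scale > 0):
            raise ValueError("scale factors must be positive")
        if self.dose_noise < 0 or self.spot_jitter_mm < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def matched_default(cls, seed: int = 0) -> "GantryPerturbation":
        """Perturbation of a second, beam-matched gantry relative to the first.

        Magnitudes follow typical matched-gantry tolerances: range agreement
        around 0.3 mm, spot sigmas within a few percent, sub-percent dose
        noise.
        """
        return cls(
            range_offset_mm=0.3,
            spectrum_sigma_scale=1.05,
            sigma_scale=1.02,
            spot_jitter_mm=0.1,
            dose_noise=0.002,
            seed=seed,
        )

    @classmethod
    def qa_default(cls, seed: int = 0) -> "GantryPerturbation":
        """Default delivery/model mismatch for patient-specific QA simulation.

        Spot sigmas off by at most 2.3 %, spot positions jittered with 0.3 mm
        s.d., a 0.3 mm range offset driving a small amplitude change, and
        0.5 % detector noise.
        """
        return cls(
            range_offset_mm=0.3,
            spectrum_sigma_scale=1.0,
            sigma_scale=1.023,
            spot_jitter_mm=0.3,
            dose_noise=0.005,
            seed=seed,
        )


@dataclass(frozen=True)
class DetectorSpec:
    """Square planar detector: active side length and pixel pitch, in mm."""

    size_mm: float = 300.0
    pitch_mm: float = 0.5

    def __post_init__(self) -> None:
        if not (self.size_mm > 0 and self.pitch_mm > 0):
            raise ValueError("detector dimensions must be positive")

    @classmethod
    def lynx(cls) -> "DetectorSpec":
        """Scintillation spot camera: 300 mm x 300 mm at 0.5 mm resolution."""
        return cls(size_mm=300.0, pitch_mm=0.5)

    @classmethod
    def matrixx(cls) -> "DetectorSpec":
        """Ion-chamber QA array: 24.4 cm x 24.4 cm at 7.6 mm pitch."""
        return cls(size_mm=244.0, pitch_mm=7.6)

    @property
    def n_pixels(self) -> int:
        return int(round(self.size_mm / self.pitch_mm)) + 1

    def axis_mm(self):
        """Pixel-centre coordinates, symmetric about the detector centre."""
        import numpy as np

        n = self.n_pixels
        half = (n - 1) / 2.0 * self.pitch_mm
        return np.linspace(-half, half, n)


_SECTIONS = {
    "beamline": BeamLineConfig,
    "perturbation": GantryPerturbation,
    "detector": DetectorSpec,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config with optional beamline/perturbation/detector sections.

    Missing sections fall back to the dataclass defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, cls in _SECTIONS.items():
        out[name] = cls(**(raw.get(name) or {}))
    return out


def save_config(cfg: dict, path: str | Path) -> None:
    """Write the sections produced by :func:`load_config` back to YAML."""
    raw = {name: asdict(obj) for name, obj in cfg.items() if obj is not None}
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
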