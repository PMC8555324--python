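"""Synthetic two-gantry beam-data generator.

Emulates the measurement campaign the analysis pipeline expects: per-energy
integrated depth-dose curves on a 0.1 mm grid, planar 5-spot images at five
planes around the isocenter, and paired computed/measured QA planes — for two
"gantries" differing by a small configurable perturbation (range offset,
energy-spread scale, spot-sigma scale, position jitter, dose noise).

Per-energy beam parameters the real machines do not publish are stand-ins
chosen at plausible magnitudes and kept fixed:

* energy spread ``sigma_E(E) = 0.7 % of E``;
* isocenter spot sigma log-linear in E from 6 mm at 70 MeV down to 3 mm at
  226.09 MeV, identical in X and Y (cylindrical spots);
* angular divergence scaled to the spot size (``sqrt(C) = 0.35*sigma_iso``
  mrad) with a mild convergence towards a downstream waist
  (``B = -0.1*sqrt(A*C)``).

All randomness flows through a ``numpy`` Generator seeded from the caller, so
identical seeds reproduce datasets bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BeamLineConfig, DetectorSpec, GantryPerturbation
from .gamma import DosePlane
from .idd import IDDCurve, normalize_unity
from .optics import (
    PLANE_POSITIONS_MM,
    OpticsMoments,
    SpotPattern,
    SpotPlane,
    five_spot_pattern,
    sigma_at,
)
from .physics import mono_bragg, range_from_energy

__all__ = [
    "NominalEnergyGrid",
    "GantryDataset",
    "QAFieldSpec",
    "standard_energy_grid",
    "default_sigma_e",
    "default_isocenter_sigma",
    "default_moments",
    "simulate_idd",
    "simulate_spot_planes",
    "simulate_gantry",
    "simulate_qa_pair",
    "qa_field_template",
    "QA_COHORTS",
]

BACKGROUND_NOISE_FRACTION = 1e-3  # additive detector floor, fraction of image max


@dataclass(frozen=True)
class NominalEnergyGrid:
    """Ordered list of nominal beam energies (MeV)."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)

    def __len__(self) -> int:
        return int(self.energies.size)

    def __iter__(self):
        return iter(self.energies)


def standard_energy_grid() -> NominalEnergyGrid:
    """The 33 nominal energies: 70.0 to 225.0 MeV step 5, plus 226.09 MeV."""
    return NominalEnergyGrid(np.append(np.arange(70.0, 225.0 + 2.5, 5.0), 226.09))


def default_sigma_e(energy_mev: float) -> float:
    """Synthetic energy-spread sigma_E (MeV): 0.7 % of the nominal energy."""
    return 0.007 * energy_mev


def default_isocenter_sigma(energy_mev: float) -> float:
    """Synthetic isocenter spot sigma (mm), log-linear from 6 mm to 3 mm."""
    e_lo, e_hi, s_lo, s_hi = 70.0, 226.09, 6.0, 3.0
    b = np.log(s_hi / s_lo) / np.log(e_hi / e_lo)
    return float(s_lo * (energy_mev / e_lo) ** b)


def default_moments(energy_mev: float, axis: str = "x") -> OpticsMoments:
    """Synthetic free-drift moments consistent with the default spot sigma."""
    sigma = default_isocenter_sigma(energy_mev)
    A = sigma**2
    C = (0.35 * sigma) ** 2
    B = -0.1 * np.sqrt(A * C)
    return OpticsMoments(A=A, B=B, C=C, z_ref_mm=0.0, axis=axis)


def simulate_idd(
    energy_mev: float,
    sigma_e_mev: float,
    perturbation: GantryPerturbation = GantryPerturbation(),
    config: BeamLineConfig = BeamLineConfig(),
    rng: np.random.Generator | int | None = None,
) -> IDDCurve:
    """One synthetic measured IDD curve, normalised to unit maximum.

    A Gaussian effective spectrum of width ``sigma_e * spectrum_sigma_scale``
    (truncated at +/- 4 sigma, sampled at 0.5 MeV — the same granularity the
    deconvolution basis uses) weights pristine peaks whose ranges are rigidly
    shifted by ``range_offset_mm``; multiplicative lognormal noise of
    relative s.d. ``dose_noise`` is applied pointwise.
    """
    if sigma_e_mev < 0:
        raise ValueError("sigma_E must be non-negative")
    rng = np.random.default_rng(rng)
    n_step = int(round(config.depth_max_mm / config.depth_step_mm))
    grid = np.arange(n_step + 1) * config.depth_step_mm
    sig = sigma_e_mev * perturbation.spectrum_sigma_scale
    if sig == 0:
        energies = np.array([energy_mev])
        weights = np.array([1.0])
    else:
        step = 0.5
        k = max(1, int(np.ceil(4.0 * sig / step)))
        energies = energy_mev + (np.arange(2 * k + 1) - k) * step
        weights = np.exp(-0.5 * ((energies - energy_mev) / sig) ** 2)
        weights /= weights.sum()
    dose = np.zeros_like(grid)
    for e, w in zip(energies, weights):
        r = range_from_energy(e, config) + perturbation.range_offset_mm / 10.0
        dose += w * mono_bragg(r, grid, config)
    if perturbation.dose_noise > 0:
        s = perturbation.dose_noise
        dose = dose * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=dose.shape)
    return normalize_unity(IDDCurve(grid, dose, float(energy_mev)))


def simulate_spot_planes(
    energy_mev: float,
    moments: dict[str, OpticsMoments] | OpticsMoments,
    pattern: SpotPattern | None = None,
    detector: DetectorSpec | None = None,
    perturbation: GantryPerturbation = GantryPerturbation(),
    rng: np.random.Generator | int | None = None,
    plane_positions_mm: tuple[float, ...] = PLANE_POSITIONS_MM,
) -> list[SpotPlane]:
    """Planar 5-spot images at the measurement planes for one energy.

    The per-axis sigma at plane z follows the free-drift quadratic of the
    given moments, scaled by ``perturbation.sigma_scale``; spots are rendered
    as equal-amplitude Gaussians at the pattern positions plus jitter, with
    multiplicative lognormal noise and an additive background floor.
    """
    rng = np.random.default_rng(rng)
    pattern = pattern or five_spot_pattern()
    detector = detector or DetectorSpec.lynx()
    if isinstance(moments, OpticsMoments):
        moments = {"x": moments, "y": moments}
    ax = detector.axis_mm()
    planes: list[SpotPlane] = []
    for z in plane_positions_mm:
        sx = sigma_at(moments["x"], z) * perturbation.sigma_scale
        sy = sigma_at(moments["y"], z) * perturbation.sigma_scale
        img = np.zeros((ax.size, ax.size))
        for (px, py) in pattern.positions_mm:
            jx, jy = rng.normal(0.0, perturbation.spot_jitter_mm, size=2) if perturbation.spot_jitter_mm > 0 else (0.0, 0.0)
            gx = np.exp(-0.5 * ((ax - (px + jx)) / sx) ** 2)
            gy = np.exp(-0.5 * ((ax - (py + jy)) / sy) ** 2)
            img += np.outer(gy, gx)
        if perturbation.dose_noise > 0:
            s = perturbation.dose_noise
            img *= rng.lognormal(mean=-0.5 * s * s, sigma=s, size=img.shape)
            img += rng.normal(0.0, BACKGROUND_NOISE_FRACTION * img.max(), size=img.shape)
            img = np.clip(img, 0.0, None)
        planes.append(
            SpotPlane(
                dose=img,
                pitch_mm=detector.pitch_mm,
                origin_mm=(float(ax[0]), float(ax[0])),
                z_mm=float(z),
                energy=float(energy_mev),
            )
        )
    return planes


@dataclass(frozen=True)
class GantryDataset:
    """Complete synthetic dataset for one gantry.

    ``idd_curves`` maps nominal energy -> IDDCurve; ``spot_planes`` maps
    nominal energy -> list of five SpotPlanes (may be empty if spot images
    were not generated).
    """

    gantry_id: str
    idd_curves: dict[float, IDDCurve]
    spot_planes: dict[float, list[SpotPlane]]
    config: BeamLineConfig
    perturbation: GantryPerturbation

    @property
    def energies(self) -> np.ndarray:
        return np.array(sorted(self.idd_curves))


def simulate_gantry(
    gantry_id: str,
    perturbation: GantryPerturbation = GantryPerturbation(),
    config: BeamLineConfig = BeamLineConfig(),
    seed: int = 0,
    energies: NominalEnergyGrid | None = None,
    include_spot_planes: bool = True,
    pattern: SpotPattern | None = None,
    detector: DetectorSpec | None = None,
) -> GantryDataset:
    """Full synthetic dataset for one gantry over the nominal energy grid."""
    grid = energies or standard_energy_grid()
    root = np.random.SeedSequence([int(seed), int(perturbation.seed) & 0x7FFFFFFF])
    seqs = root.spawn(2 * len(grid))
    idd: dict[float, IDDCurve] = {}
    spots: dict[float, list[SpotPlane]] = {}
    for i, e in enumerate(grid):
        e = float(e)
        idd[e] = simulate_idd(
            e, default_sigma_e(e), perturbation, config, np.random.default_rng(seqs[2 * i])
        )
        if include_spot_planes:
            mom = {"x": default_moments(e, "x"), "y": default_moments(e, "y")}
            spots[e] = simulate_spot_planes(
                e, mom, pattern, detector, perturbation, np.random.default_rng(seqs[2 * i + 1])
            )
        else:
            spots[e] = []
    return GantryDataset(gantry_id, idd, spots, config, perturbation)


@dataclass(frozen=True)
class QAFieldSpec:
    """A planar QA field: scanned spot positions (mm), weights and sigma (mm)."""

    positions_mm: np.ndarray
    weights: np.ndarray
    sigma_mm: float
    name: str = "field"

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_mm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or w.shape != (p.shape[0],):
            raise ValueError("positions must be (n, 2) with matching weights")
        if self.sigma_mm <= 0 or np.any(w < 0):
            raise ValueError("sigma must be positive and weights non-negative")
        object.__setattr__(self, "positions_mm", p)
        object.__setattr__(self, "weights", w)


# Per-cohort field templates (target half-size mm, spot sigma mm); synthetic
# stand-ins for the unpublished clinical plans.
QA_COHORTS: dict[str, dict[str, float]] = {
    "prostate": {"half_size_mm": 40.0, "sigma_mm": 5.0, "spacing_mm": 8.0},
    "lung": {"half_size_mm": 35.0, "sigma_mm": 5.5, "spacing_mm": 8.0},
    "NPC": {"half_size_mm": 55.0, "sigma_mm": 6.0, "spacing_mm": 9.0},
}


def qa_field_template(
    cohort: str, rng: np.random.Generator | int | None = None
) -> QAFieldSpec:
    """Synthetic per-plan QA field for a cohort, with mild weight modulation."""
    if cohort not in QA_COHORTS:
        raise KeyError(f"unknown cohort {cohort!r}; options: {sorted(QA_COHORTS)}")
    rng = np.random.default_rng(rng)
    t = QA_COHORTS[cohort]
    half = t["half_size_mm"] * rng.uniform(0.85, 1.15)
    spacing = t["spacing_mm"]
    n = int(np.floor(half / spacing))
    coords = (np.arange(2 * n + 1) - n) * spacing
    gx, gy = np.meshgrid(coords, coords)
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    w = rng.uniform(0.7, 1.3, size=pos.shape[0])
    return QAFieldSpec(pos, w, t["sigma_mm"], name=cohort)


def _render_field(field: QAFieldSpec, x_mm, y_mm, sigma_scale=1.0, jitter=None):
    # each spot deposits a fixed meterset, so its 2-D Gaussian is
    # area-normalised: widening sigma softens the penumbra but conserves dose
    # in the flat region
    sx = field.sigma_mm * sigma_scale
    out = np.zeros((len(y_mm), len(x_mm)))
    offsets = jitter if jitter is not None else np.zeros_like(field.positions_mm)
    for (px, py), w, (jx, jy) in zip(field.positions_mm, field.weights, offsets):
        gx = np.exp(-0.5 * ((np.asarray(x_mm) - (px + jx)) / sx) ** 2)
        gy = np.exp(-0.5 * ((np.asarray(y_mm) - (py + jy)) / sx) ** 2)
        out += w / (2.0 * np.pi * sx * sx) * np.outer(gy, gx)
    return out


def simulate_qa_pair(
    field: QAFieldSpec,
    perturbation: GantryPerturbation = GantryPerturbation(),
    detector: DetectorSpec | None = None,
    rng: np.random.Generator | int | None = None,
    computed_pitch_mm: float = 1.0,
) -> tuple[DosePlane, DosePlane]:
    """A (computed, measured) QA plane pair for one field.

    The computed plane renders the nominal field on a fine grid (1 mm, the
    planning-dose resolution); the measured plane renders the perturbed field
    (sigma scaled, per-spot position jitter, range-driven amplitude factor of
    2 %/mm of range offset) sampled at the QA detector pitch with
    multiplicative noise.
    """
    rng = np.random.default_rng(rng)
    detector = detector or DetectorSpec.matrixx()
    half = detector.size_mm / 2.0
    n_fine = int(round(detector.size_mm / computed_pitch_mm))
    fine = -half + np.arange(n_fine + 1) * computed_pitch_mm
    computed = DosePlane(
        _render_field(field, fine, fine),
        pitch_mm=computed_pitch_mm,
        origin_mm=(float(fine[0]), float(fine[0])),
    )
    coarse = detector.axis_mm()
    jitter = (
        rng.normal(0.0, perturbation.spot_jitter_mm, size=field.positions_mm.shape)
        if perturbation.spot_jitter_mm > 0
        else None
    )
    amp = 1.0 + 0.02 * perturbation.range_offset_mm
    meas = amp * _render_field(
        field, coarse, coarse, sigma_scale=perturbation.sigma_scale, jitter=jitter
    )
    if perturbation.dose_noise > 0:
        s = perturbation.dose_noise
        meas *= rng.lognormal(mean=-0.5 * s * s, sigma=s, size=meas.shape)
    measured = DosePlane(
        meas, pitch_mm=detector.pitch_mm, origin_mm=(float(coarse[0]), float(coarse[0]))
    )
    return computed, measured
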