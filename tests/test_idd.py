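"""IDD resampling, normalisation and effective energy-spectrum fitting."""
import numpy as np
import pytest

from beammatch.config import GantryPerturbation
from beammatch.gamma import GammaCriteria, gamma_1d
from beammatch.idd import (
    EffectiveSpectrumModel,
    EnergySpectrum,
    IDDCurve,
    build_basis,
    fit_spectrum,
    normalize_unity,
    r80,
    r80_energy,
    reconstruct_idd,
    resample_curve,
)
from beammatch.physics import mono_bragg, range_from_energy
from beammatch.synthetic import simulate_idd

from oracles import grid_search_two_weights


# --- resampling and normalisation -------------------------------------------

def test_resample_preserves_knots_and_linearity():
    z = np.arange(0.0, 10.1, 1.0)
    ramp = IDDCurve(z, 0.1 * z)
    same = resample_curve(ramp, 1.0)
    np.testing.assert_allclose(same.dose, ramp.dose, atol=1e-12)
    fine = resample_curve(ramp, 0.25)
    np.testing.assert_allclose(fine.dose, 0.1 * fine.depth_mm, atol=1e-12)
    with pytest.raises(ValueError):
        resample_curve(ramp, -1.0)


def test_resample_1mm_to_0p1mm_keeps_r80(config):
    """Spline refinement of a coarse peak moves R80 by less than 0.05 mm.

    Oracle: the same analytic peak evaluated directly on the 0.1 mm grid.
    """
    coarse_grid = np.arange(0.0, 350.0 + 0.5, 1.0)
    fine_grid = np.arange(0.0, 350.0 + 0.05, 0.1)
    coarse = IDDCurve(coarse_grid, mono_bragg(20.0, coarse_grid, config))
    direct = IDDCurve(fine_grid, mono_bragg(20.0, fine_grid, config))
    resampled = resample_curve(coarse, 0.1)
    assert r80(resampled) == pytest.approx(r80(direct), abs=0.05)


def test_normalize_unity_examples():
    c = IDDCurve(np.arange(3.0), np.array([2.0, 4.0, 8.0]))
    n = normalize_unity(c)
    np.testing.assert_allclose(n.dose, [0.25, 0.5, 1.0])
    np.testing.assert_allclose(normalize_unity(n).dose, n.dose)  # idempotent
    # shape preserving
    np.testing.assert_allclose(n.dose / n.dose[0], c.dose / c.dose[0])
    with pytest.raises(ValueError):
        normalize_unity(IDDCurve(np.arange(3.0), np.zeros(3)))


# --- basis -------------------------------------------------------------------

def test_basis_defaults(config, depth_grid, basis_150):
    assert len(basis_150) == 41
    assert basis_150.member_energies[0] == pytest.approx(140.0)
    assert basis_150.member_energies[-1] == pytest.approx(160.0)
    r80s = [r80(IDDCurve(depth_grid, c)) for c in basis_150.member_curves]
    assert np.all(np.diff(r80s) > 0)
    # member at the nominal energy is the unit-maximum pristine peak
    direct = mono_bragg(range_from_energy(150.0, config), depth_grid, config)
    np.testing.assert_allclose(
        basis_150.member_curves[20], direct / direct.max(), atol=1e-12
    )


# --- spectrum fitting --------------------------------------------------------

def test_fit_recovers_single_member(basis_150, depth_grid):
    measured = IDDCurve(depth_grid, basis_150.member_curves[17], 148.5)
    spec = fit_spectrum(measured, basis_150)
    assert spec.weights[17] > 0.99
    assert np.all(np.delete(spec.weights, 17) < 0.01)


def test_fit_recovers_two_member_mixture(basis_150, depth_grid):
    """Noiseless 50/50 mixture of two members, versus an exhaustive grid search."""
    i, j = 15, 25
    mix = 0.5 * basis_150.member_curves[i] + 0.5 * basis_150.member_curves[j]
    spec = fit_spectrum(IDDCurve(depth_grid, mix), basis_150)
    wi_o, wj_o = grid_search_two_weights(
        mix, basis_150.member_curves[i], basis_150.member_curves[j]
    )
    assert spec.weights[i] == pytest.approx(wi_o / (wi_o + wj_o), abs=0.02)
    assert spec.weights[j] == pytest.approx(wj_o / (wi_o + wj_o), abs=0.02)
    assert spec.weights[i] == pytest.approx(0.5, abs=0.02)
    assert spec.weights[j] == pytest.approx(0.5, abs=0.02)
    assert np.delete(spec.weights, [i, j]).sum() < 0.02


def test_fit_recovers_gaussian_spectrum_mean(config, basis_150):
    """A sigma_E = 1.5 MeV Gaussian spectrum is recovered to 0.5 MeV in the mean."""
    curve = simulate_idd(
        150.0, 1.5, GantryPerturbation(dose_noise=0.002), config, rng=7
    )
    res = EffectiveSpectrumModel(curve, basis_150).fit()
    assert res.spectrum.mean_energy == pytest.approx(150.0, abs=0.5)
    assert res.spectrum.sigma_energy == pytest.approx(1.5, abs=0.5)


def test_fit_residual_properties(noisy_idd_150, basis_150, config, depth_grid):
    res = EffectiveSpectrumModel(noisy_idd_150, basis_150).fit()
    # weights sum to one
    assert res.spectrum.weights.sum() == pytest.approx(1.0, abs=1e-9)
    # residual no worse than the best single member at its optimal scale
    best_single = min(
        np.linalg.norm(
            noisy_idd_150.dose
            - (noisy_idd_150.dose @ b / (b @ b)) * b
        )
        for b in basis_150.member_curves
    )
    assert res.residual_norm <= best_single + 1e-12
    # finer basis never fits worse (same span)
    coarse = build_basis(150.0, depth_grid, config, step_mev=1.0)
    res_coarse = EffectiveSpectrumModel(noisy_idd_150, coarse).fit()
    assert res.residual_norm <= res_coarse.residual_norm + 1e-9


def test_fit_rejects_grid_mismatch(basis_150):
    other = IDDCurve(np.arange(0.0, 10.1, 1.0), np.ones(11))
    with pytest.raises(ValueError):
        EffectiveSpectrumModel(other, basis_150)


# --- reconstruction and R80 --------------------------------------------------

def test_reconstruct_delta_and_roundtrip(config, basis_150, depth_grid):
    delta = EnergySpectrum(np.array([150.0]), np.array([1.0]))
    rec = reconstruct_idd(delta, basis_150)
    np.testing.assert_allclose(rec.dose, basis_150.member_curves[20], atol=1e-12)
    assert rec.dose.max() == pytest.approx(1.0)

    # noiseless curve built from the basis family: fit -> reconstruct is exact
    # under 1 mm/1% gamma
    truth = simulate_idd(150.0, 1.0, GantryPerturbation(), config, rng=0)
    res = EffectiveSpectrumModel(truth, basis_150).fit()
    g = gamma_1d(truth, res.reconstruction(), GammaCriteria(1.0, 1.0))
    assert g.passing_rate == 100.0
    assert g.mean_gamma < 0.1

    with pytest.raises(ValueError):
        reconstruct_idd(EnergySpectrum(np.array([150.25]), np.array([1.0])), basis_150)


def test_r80_translation_and_scale_properties(config, depth_grid):
    dose = mono_bragg(20.0, depth_grid, config)
    curve = IDDCurve(depth_grid, dose)
    base = r80(curve)
    assert base == pytest.approx(200.0, abs=0.5)
    # translation equivariance: shift the grid by +1.0 mm
    shifted = IDDCurve(depth_grid + 1.0, dose)
    assert r80(shifted) == pytest.approx(base + 1.0, abs=1e-9)
    # amplitude invariance
    assert r80(IDDCurve(depth_grid, 5.0 * dose)) == pytest.approx(base, abs=1e-12)
    # truncated curve has no distal crossing
    cut = int(np.searchsorted(depth_grid, 199.0))
    with pytest.raises(ValueError):
        r80(IDDCurve(depth_grid[:cut], dose[:cut]))


def test_r80_increases_with_energy(config, depth_grid):
    energies = [70.0, 100.0, 150.0, 200.0, 226.09]
    vals = [
        r80(IDDCurve(depth_grid, mono_bragg(range_from_energy(e, config), depth_grid, config)))
        for e in energies
    ]
    assert np.all(np.diff(vals) > 0)


def test_r80_energy_self_consistency(config, basis_150):
    delta = EnergySpectrum(np.array([150.0]), np.array([1.0]))
    assert r80_energy(delta, basis_150, config) == pytest.approx(150.0, abs=0.3)
    # symmetric Gaussian spectrum centred at 150 stays within 1 MeV
    e = basis_150.member_energies
    w = np.exp(-0.5 * ((e - 150.0) / 1.5) ** 2)
    sym = EnergySpectrum(e, w / w.sum())
    assert r80_energy(sym, basis_150, config) == pytest.approx(150.0, abs=1.0)
    # widening the spectrum moves the equivalent energy by less than the widening
    w2 = np.exp(-0.5 * ((e - 150.0) / 3.0) ** 2)
    wide = EnergySpectrum(e, w2 / w2.sum())
    shift = abs(
        r80_energy(wide, basis_150, config) - r80_energy(sym, basis_150, config)
    )
    assert shift < 1.5  # much smaller than the 1.5 MeV widening
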