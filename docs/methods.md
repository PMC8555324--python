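# Methods

This note documents the models behind `beammatch`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Pristine Bragg-peak model and range–energy relation

All depth-dose machinery rests on a two-parameter power law between beam
energy E (MeV) and water-equivalent range R (cm),

    R = α·E^p,        α = 0.0022 cm·MeV⁻ᵖ,  p = 1.77,

whose constants reproduce the machine's printed limits (69.8 MeV ↔
4.0 g/cm², 226.09 MeV ↔ 32.0 g/cm², both within 1 %). The pristine
mono-energetic peak is the ideal stopping profile implied by the same power
law, D̂(z) ∝ (R−z)^(1/p−1) for z < R, convolved with a Gaussian range-straggling
kernel of width σ_s(R) = k·R^m (k = 0.012 cm^(1−m), m = 0.935). The
singular-but-integrable profile is cell-averaged analytically on a 0.01 mm
internal grid before convolution, which keeps the distal 80 % depth (R80) of
the result within a few hundredths of a millimetre of R (verified against
direct adaptive quadrature of the convolution integral). Two properties of
this family matter downstream, and only these: the distal edge tracks R
sharply, and neighbouring-energy peaks overlap smoothly so non-negative
mixtures can represent broadened measured curves. Nuclear build-up and the
low-dose halo are deliberately absent; peak-to-entrance ratios are therefore
higher than measured proton IDDs. The tail decays to <0.5 % of the peak by
R + 3σ_s and <0.1 % by R + 4σ_s.

## Effective energy-spectrum fitting

A measured IDD on the 0.1 mm grid is fitted as a non-negative linear
combination of unit-maximum pristine peaks placed at the nominal energy
±10 MeV in 0.5 MeV steps (41 members). Plain NNLS is used, with no
regularisation: the problem is small (≈3500 × 41), the non-negativity
constraint itself provides strong implicit regularisation, and any smoothing
penalty would need a tuning parameter the analysis cannot justify. The
fitted weights are renormalised to unit sum — the *effective energy
spectrum* — with the overall amplitude kept as a separate scale so spectra
are comparable across energies once curves are normalised to unit maximum.
NNLS solutions are sparse, so a Gaussian truth of width σ_E comes back as a
handful of spikes with the correct mean and width rather than a smooth
curve; the reconstruction (and hence R80, R80 Energy and γ agreement) is
insensitive to this. The basis span/step trade-off: a wider span adds
ill-conditioned near-collinear columns; a finer step improves reconstruction
fidelity when the true spectrum lies off the grid but slows the fit. Both
are configurable; 0.5 MeV matches the generator's spectrum sampling, which
is the situation a planning system fitting against its own pristine-peak
library is in.

R80 is taken on the distal falloff (the standard proton range surrogate):
the first crossing of 80 % of the global maximum distal to the peak, located
by linear interpolation between grid points (sub-grid bias < 0.05 mm on the
0.1 mm grid). R80 Energy inverts the range–energy law at the reconstructed
curve's R80.

## Gamma index

γ(r) for reference point r is the minimum over evaluated positions r′ of
√(|r−r′|²/dta² + ΔD²/dd²), with the dose difference taken in percent of the
*global* reference maximum (the convention that matches reported 100 % rates
on near-identical curves; local normalisation would be far stricter in
high-gradient regions). A point passes when γ ≤ 1, boundary inclusive with a
1e−9 tolerance so points sitting exactly on the criterion do not flip on
floating-point roundoff. The search evaluates the (linearly/bilinearly
interpolated) evaluated distribution at positions spaced dta/10 within a
window of radius 3·dta; a point whose true optimum lies outside the window
reports the windowed minimum (≥ 3), an unambiguous failure, so the window
cannot change a pass/fail decision. The engine is validated against an
exhaustive full-grid brute-force search in the test suite. Reference roles:
the measured distribution is the reference (intra-gantry and QA); in
cross-gantry comparisons the first/lower-numbered gantry is the reference
and the denominator of relative differences.

## Spot optics

Spot images are background-subtracted (median of the outer 5 % border),
clipped at zero, and a square ROI of half-width 8 nominal σ is cut around
each pattern position and recentred on the nearest pixel to its intensity
centroid (errors on centroids >5 mm off-nominal or overlapping ROIs). The
five ROIs are averaged pixelwise into the equivalent spot; σ per axis comes
from a Gaussian-plus-baseline least-squares fit to the cross-section through
the centroid, initialised from profile moments. The baseline term absorbs
any residual detector floor. Cross-section fits (rather than full 2-D fits)
match the per-axis treatment and the cylindrical single-Gaussian assumption.

The free-drift Fermi–Eyges fit regresses σ²(z) on [1, 2z, z²] with z in
metres, so A is in mm², B in mm·mrad and C in mrad² (1 mrad over 1 m is
1 mm). B < 0 denotes a beam converging to a downstream waist. The fit
rejects rank-deficient designs and any solution with σ²(z) ≤ 0 on
[−300, +300] mm. C is physically a variance, but the unconstrained
least-squares estimate can come out slightly negative when the quadratic
term is weakly constrained by noisy data (its z² lever arm over ±0.3 m is
small compared with A); the estimate is left unconstrained because
truncating at zero would bias ensemble averages, and the positivity of
σ²(z) over the span is the requirement that actually matters. Exact
arithmetic noise (|C| < 1e−9·A on noiseless data) is clamped to zero.

## Synthetic two-gantry generator

The generator produces the measurement campaign the pipeline expects, for
two gantries differing by a `GantryPerturbation`. Machine tables that real
vendors do not publish are synthetic stand-ins, chosen once at plausible
magnitudes:

| quantity | default | rationale |
|---|---|---|
| energy spread σ_E(E) | 0.7 % of E | sub-MeV at low E, ≈1.6 MeV at 226 MeV, typical of cyclotron + ESS beams |
| isocenter spot σ(E) | 6 mm (70 MeV) → 3 mm (226.09 MeV), log-linear | the familiar monotone shrink of PBS spots with energy |
| angular variance | √C = 0.35·σ_iso mrad | divergence scales with spot size; σ changes only a few % over ±30 cm |
| covariance | B = −0.1·√(A·C) | mild convergence to a waist ≈30 cm downstream; guarantees σ² > 0 everywhere |
| matched-gantry offset | 0.3 mm range, ×1.05 σ_E, ×1.02 spot σ, 0.1 mm jitter, 0.2 % noise | the tolerance envelope of a matched pair: R80 within ±0.3 mm, isocenter σ within ±10 % |
| QA mismatch | ×1.023 spot σ, 0.3 mm jitter, 0.3 mm range (→ 0.6 % amplitude), 0.5 % noise | the largest intra-gantry σ deviation observed in matched systems, plus detector-level noise |

IDD curves are Gaussian-weighted superpositions of pristine peaks sampled at
0.5 MeV (±4σ_E), the same granularity as the deconvolution basis — the
situation of a planning system that fits measurements against its own
pristine library. Dose noise is multiplicative lognormal (doses stay
positive); images additionally get an additive Gaussian floor at 0.1 % of
the maximum. QA fields are grids of area-normalised Gaussians (a spot
delivers a fixed meterset, so widening σ softens the penumbra but conserves
flat-region dose — the reason modest σ mismatches still pass 3 mm/3 %);
cohort templates (prostate/lung/NPC) differ in target size and spot σ and
get per-plan size and weight modulation. In the QA study the four arms share
each plan's field, and the two arms delivered on the same gantry share the
delivery's random draw, which is what makes model-paired passing rates
correlate across plans as they do in real model-sharing QA.

What the generator does **not** emulate: nuclear halos and large-angle
scatter tails, detector-specific response (CCD glare, ion-recombination),
setup/positioning errors beyond per-spot jitter, range shifters and oblique
incidence, and any CT-based heterogeneity. Tests passing on this generator
therefore demonstrate the correctness and sensitivity of the *analysis* —
deconvolution, γ scoring, optics fitting, statistics — not the clinical
performance of any real machine.

## Problem sizes and determinism

Default runs use the full 33-energy grid for IDD work; spot-plane and
CLI-driven end-to-end examples use reduced energy subsets where five planes
of 601×601 px images per energy would otherwise dominate runtime without
adding information. The QA study uses 12 plans per cohort (three cohorts,
four arms, both criteria). All randomness flows through
`numpy.random.Generator` objects spawned from a single `SeedSequence`, so
every pipeline stage is bit-reproducible under a fixed seed.

## Known limitations

* The absolute scale of spectra, spot amplitudes and QA doses is arbitrary;
  no meterset/absolute-dose calibration is modelled (matched rooms calibrate
  these to 0.00 % by construction).
* Virtual source–axis distances are carried as metadata only; no divergence
  correction is applied to planar images.
* The paired t/r statistics of a real model-sharing study depend on the
  actual measurement noise structure; here they are validated for their
  statistical behaviour (textbook-formula agreement, null calibration,
  correlation under shared delivery draws), not for specific values.
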