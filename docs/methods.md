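# Methods

`ppgmc` models reflection-mode photoplethysmography (PPG): the change in
diffuse reflectance at the skin surface between the systolic and diastolic
phases of the cardiac cycle, and why that change is larger for green light
than for near-infrared (NIR) light despite NIR's longer optical paths.
This note records the models, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## The physical model

**Skin geometry.** A voxelized block (default 2 × 4.7 × 1.1 mm³, X–Y–Z)
holds an epidermis slab of thickness *D* ∈ {50, 100, 150} µm over a dermis
containing parallel cylindrical blood vessels running along Y. The
cross-sectional vessel density is 33.75 vessels/mm² over the X–Z plane
(74 cylinders in the default block). The cardiac cycle is represented by
two vessel diameters at fixed centers: 75 µm (systole) and 117 µm
(diastole); dilating at fixed centers guarantees that the two phases differ
only in blood volume. Vessel centers are placed by seeded rejection
sampling (non-overlapping circles, uniform over a configurable depth band
defaulting to [*D* + 50 µm, bottom − one diameter]); because the default
diastolic packing fraction sits near the sequential-adsorption jamming
limit, a deterministic pairwise-repulsion relaxation finishes the packing
when rejection stalls. A regular-grid option exists for fully
deterministic tests. Voxel membership is decided by voxel
*center*, with voxel *k* spanning [*kh*, (*k*+1)*h*) mm; the z = 0 face is
the air–tissue interface.

**Phantom geometry.** Two-layer gel phantoms: a melanin-like ink + lipid
top layer of thickness *D* ∈ {0, 0.20} mm over a deep hemoglobin + lipid
layer. A seven-phantom series whose bottom-layer Hb concentration traces
the arc 2.0 → 3.1 → 2.0 mg/mL stands in for one cardiac pulse, each phantom
being one phase point.

**Optical properties.** Media carry (μa, μs, g, n); μa and μs may be
spectra. The shipped defaults are parameterized, literature-shaped curves,
*not* measured ground truth: an oxyhemoglobin-shaped μa table (per mg/mL,
with the 540/577 nm double peak and the deep red–NIR window, interpolated
monotonically in log space), a melanin-like power law (∝ λ⁻³) shared by
India-ink and epidermal melanin (epidermis uses the standard melanosome law
6.6·10¹⁰ λ⁻³·³³ mm⁻¹ times a 0.30 melanin fraction, a heavily pigmented
skin), a power-law Intralipid μs′ (1.7 (500/λ)²·⁴ mm⁻¹ per 1% w/v), tissue
μs′ = 4.6 (500/λ)¹·⁴² mm⁻¹, and a weak dermis baseline + water term.
Anisotropy and refractive index are not spectral: g = 0.9, n = 1.40 for
skin layers and blood; g = 0.75, n = 1.33 for gel phantoms; ambient n = 1.
Every value is overridable, and tabulated user spectra can be read from
two-column text files. The package's conclusions are *orderings* driven by
the spectral shapes (blood absorbs ~20× more at 523 than at 945 nm), which
are robust to the exact amplitudes.

## The Monte Carlo engine

Weighted photon packets are traced through the voxel grid:

* **Launch.** Gaussian lateral profile with beam diameter 0.4 mm under the
  2σ convention (σ = 0.2 mm), normal incidence by default; the specular
  Fresnel fraction is split off deterministically at entry.
* **Propagation.** A dimensionless scattering depth *s* ~ Exp(1) is
  consumed against the per-voxel μs by DDA stepping across voxel
  boundaries. Absorption never terminates or randomizes a path: the weight
  is attenuated continuously as exp(−μa·dl) along every segment
  (microscopic Beer–Lambert / survival weighting). A detected packet's
  weight is therefore exactly exp(−Σᵢ μa,ᵢ lᵢ) given its geometric path.
  This is the main variance-reduction choice: the systole/diastole
  reflectance difference is a small difference of large numbers, and
  removing absorption-event noise (together with coupled launch streams,
  below) is what makes it resolvable at ~10⁶-photon budgets.
* **Scattering.** Henyey–Greenstein deflection by the standard inverse
  CDF; azimuth uniform.
* **Boundaries.** Unpolarized Fresnel reflection/refraction at z = 0 only
  (internal boundaries are index-matched); lateral and bottom faces
  terminate packets as recorded escapes, matching a finite simulated block.
* **Detection.** Detector discs (default radius 0.3 mm, three azimuthal
  copies pooled per SDD available; the desk-scale studies use one enlarged
  0.5 mm disc) on the surface; a transmitted packet crossing a disc within
  the acceptance cone is recorded with its exit weight and its per-medium
  partial pathlengths lᵢ.
* **Termination.** Russian roulette below weight 10⁻⁴ with survival 0.1
  (configurable), bookkept as a net ledger entry (killed weight minus
  survivor boosts) so the weight ledger closes exactly.
* **Accounting.** Every run closes detected + absorbed + escaped(top) +
  escaped(sides/bottom) + specular + roulette_net = launched to better than
  10⁻⁹ relative (per-photon telescoping makes it ~10⁻¹⁴ in practice).
  Identical (seed, config) gives bitwise-identical results; batches use
  independent `SeedSequence` streams.

**Coupled seeds.** A systole/diastole pair shares its launch streams
(identical `RngPolicy`), so paths are identical until a packet first meets
a voxel whose label differs between the phases. The residual correlation
substantially cancels launch noise in the AC/DC difference.

## The PPG analysis layer

DRS (simulated) is the detected weight fraction at a detector; measured
DRS is sample/reference counts × the reference reflectance factor (0.99
Spectralon-like standard). The PPG waveform is −log DRS over the phase
points (natural log; the base cancels in the ratio). The quality metric is
AC/DC = 100% × (max − min)/min of −log DRS over the two cardiac phases,
implemented symmetric in its arguments — phase *labels* are metadata,
since the sign convention differs between common statements of the
formula. Note AC/DC is deliberately *not* invariant to a common
multiplicative reference error; a sensitivity test documents this.

MOP = Σᵢⱼ lᵢⱼ wⱼ / Σⱼ wⱼ, the detected-weight-averaged pathlength, over all
media by default or over a subset (e.g. blood-only partial pathlength).
MOP is reported for the diastolic run by default (configurable to systole
or pooled). AC/DC uncertainty is a seeded nonparametric bootstrap (200
resamples) over the detection records of both phases.

## Diffusion closed form

The dipole (extrapolated-boundary) solution provides the independent
analytic cross-check for the engine and the fast phantom forward model.
It uses the absorption-independent diffusion coefficient formulation:
z₀ = 1/μs′, Dc = 1/(3μs′), μeff = √(3 μa μs′), zb = 2A·Dc with Groenhuis'
A(n_rel). With absorption entering only through μeff, R(ρ) is strictly
decreasing in μa at every ρ — the Beer–Lambert limit the forward model
must honor — whereas the classical μt′-based source depth violates it
weakly where ρ ≲ z₀ (the deep-NIR phantom corner). For the two-layer
phantom the thin top absorber adds 2·DPF·μa,top·D to −log DRS (modified
Beer–Lambert, default DPF = 2 for the doubly traversed layer); this is an
approximation, flagged in the result provenance, adequate for the
orderings studied. Synthetic DRS is defined as R(SDD)·(detector area), so
its absolute scale (~10⁻²) is a geometry convention, not an instrument
calibration — AC/DC *magnitudes* from the synthetic phantom set are not
comparable to any particular spectrometer, only their orderings are
meaningful.

## Synthetic measurement sets

`emulate_measurement_set` writes spectrometer-like files: counts =
DRS/0.99 × a smooth lamp-response curve, one file per phantom per
replicate plus the reference, with a JSON manifest. Noise is
multiplicative log-normal, mean-preserving, with a Gaussian correlation
kernel along wavelength (defaults: 1% relative SD, 20 nm correlation
length — plausible spectrometer behavior; no noise law is prescribed by
the physical experiment, so both are configurable). What the generator
does *not* emulate: stray light, wavelength-dependent dark noise, probe
pressure and contact variation, phantom aging, or inter-phantom
fabrication error; passing tests therefore demonstrate the correctness of
the analysis chain and the physics orderings, not instrument-grade
calibration on real data.

## Problem sizes of the shipped studies

Chosen once as the package's desk-scale defaults (single CPU, minutes):

* **Oracle suite** — closed-form checks; 10⁴–10⁶ samples; exact where the
  estimator is deterministic (ballistic transmission, Fresnel, ledger).
* **Diffusion-limit check** — μa = 0.01, μs′ = 1.0 mm⁻¹, index-matched
  16 × 16 × 10 mm block at 0.1 mm voxels, 10⁷ photons; agreement within
  10% at ρ = 2–4 mm (measured worst deviation ≈ 7%, a combination of
  diffusion-theory error, voxelization and residual finite-volume
  truncation).
* **Skin trend study** — SDD 1 and 2 mm, 0.5 mm detector discs, 10 µm
  voxels (the fine 2 µm voxel remains available for convergence checks);
  per-phase budgets 4·10⁶ (523 nm), 1.2·10⁶ (945 nm), 1.5·10⁶
  (150 µm-epidermis cell). These give ≳10⁵ detected photons at SDD 1 mm
  and ~10³ at the heavily attenuated green SDD 2 mm cell; all reported
  orderings hold with ≥7 bootstrap-SE separation.
* **Phantom study** — diffusion engine over the 450–900 nm grid at 2 nm;
  noiseless for the ordering summary (at 900 nm the true AC/DC of the
  series, ~0.05%, sits below the noise floor of a 3-replicate 1%-noise
  set, so noisy orderings there would probe the noise model, not the
  physics); noise propagation is tested separately.

## Known limitations

* Straight parallel cylinders only: no branching, capillary loops,
  multi-layer dermis or subcutis; vessels at 33.75/mm² with the 117 µm
  diastolic diameter occupy ~36% of the dermis cross-section, which makes
  green transport beyond SDD ≈ 2 mm extremely attenuated in this model.
* Steady-state only; no time-of-flight, polarization or fluorescence.
* Internal index mismatches are ignored (Fresnel at the surface only).
* The diffusion two-layer form is first-order in top-layer absorption.
* CPU execution only; throughput ~10⁵ photons/s in skin at 10 µm voxels.
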