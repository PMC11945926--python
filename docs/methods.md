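# Methods

This note records the models, numerical choices and limitations behind
`y90dose`, in the order the pipeline runs them.

## Beta spectrum

The ⁹⁰Y emission spectrum is the allowed-transition Fermi shape
`p·W·(W₀−W)²·F(Z,W)` for the single ground-state branch (endpoint
2.2801 MeV, daughter Z = 40), with the non-relativistic Fermi function
`F = 2πη/(1−e^{−2πη})`, η = αZW/p.  It is tabulated at 400 energies and
sampled by inverse-CDF interpolation; the quadrature mean is ≈0.948 MeV,
within ~1.5% of evaluated-nuclear-data means for ⁹⁰Y.  The spectrum is an
ordinary `BetaSpectrum` value, so a published tabulation can be dropped in
without touching the transport code.

## Kernel Monte Carlo

* **Geometry.** Decays start uniformly inside the central voxel of an
  odd-shaped grid; the default replication grid is 53×53×53 voxels of
  0.8×0.8×0.78 mm³ in unit-density water-equivalent tissue.  Convolution
  requires the kernel and activity grids to match exactly; a mismatched
  kernel is refused rather than resampled, and the intended workflow is to
  generate the kernel directly on the activity map's grid.
* **Electron transport.** Straightened condensed-history tracks: each
  history deposits its collision energy along a straight line of length
  equal to its range, split into 48 segments whose energy losses come from
  the Katz–Penfold range–energy fit `R = 0.412·E^(1.265−0.0954 lnE)`
  (g/cm², E in MeV) and its numerical inverse.  Multiple-scattering
  deflection and energy-loss straggling are not modelled; straight tracks
  slightly stretch the depth profile relative to a condensed-history code
  with angular scattering, which is conservative for range-type claims
  (the simulated 99.9%-energy radius, ~0.98 cm, still sits below the 1.2 cm
  practical penetration of the endpoint electrons).
* **Photon component.** Bremsstrahlung is modelled as a fixed radiative
  yield (default 0.007 of the emitted beta energy, the soft-tissue scale
  for this spectrum) emitted from the source voxel and deposited through an
  isotropic exponentially attenuated point kernel `µ e^{−µr}/(4πr²)` with a
  single effective coefficient µ = 0.011 mm⁻¹ (an energy-absorption scale
  for the few-hundred-keV bremsstrahlung continuum).  Using one µ for both
  attenuation and deposition conserves energy globally; the central voxel
  gets the analytic integral over a volume-equivalent sphere, and energy
  escaping the grid is tallied in `escaped_photon_mev_per_decay`, never
  redistributed.  Internal pair production and characteristic X-rays are
  ignored.  This reproduces the qualitative beta/photon crossover (the
  beta component dominates out to ~1.1 cm) without photon transport.
* **Uncertainty.** Histories run in ≥2 equal batches with streams spawned
  from one master seed (`numpy` SeedSequence), so results are bitwise
  reproducible.  The per-voxel relative uncertainty is the standard error
  of the batch means; it scales as 1/√N, which is also how a reduced run is
  extrapolated to production statistics.
* **Units.** Energy per decay per voxel converts to dose per unit cumulated
  activity as `E·(1.602×10⁻¹³ J/MeV)/(voxel mass)`, expressed in
  mGy·MBq⁻¹·s⁻¹ (1 MBq·s = 10⁶ decays).

## Activity surrogate and cumulated activity

Voxel activity is the administered activity allocated proportionally to
raw image intensity *within the VOI only*; outside the VOI it is exactly
zero.  No background subtraction or windowing is applied by default (both
exist as options); whether normalisation should instead span the whole
brain is an open modelling question, and the VOI-only choice is the
documented default.  Negative intensities are clipped to zero and logged.
The carrier is treated as a permanent implant: cumulated activity is `a/λ`
with λ = ln2/64 h, with no biological clearance term.

## Dose engine

Zero-padded FFT convolution (scipy `fftconvolve`, float64 accumulation)
with the mGy→Gy conversion folded in; negative round-off is clipped.  Dose
carried beyond the image volume is physical, so it is tallied
(`escaped_dose_gy_cm3`) rather than silently lost.  A triple-loop direct
sum of the convolution ships in the package as the independent oracle; the
two agree to better than 1e-10 relative.  Exported volumes are float32
NIfTI with a JSON sidecar; in-memory arrays stay float64.

## Radiobiology

Linear-quadratic BED with the defaults: tumor α/β = 10 Gy, T½,rep = 1.5 h;
normal tissue α/β = 2.5 Gy, T½,rep = 2.5 h; T½,phys = 64 h.  The
permanent-implant dose-rate factor λ/(λ+µ) is 3/131 ≈ 0.0229 for tumor
parameters.  Voxelwise external-beam BED uses d = D_voxel/N with N fixed at
30 fractions — the standard voxelwise LQ convention when the fraction count,
not the fraction size, is what the plan fixes.  No repopulation, EQD2
conversion or cell-survival modelling.

## External-beam comparator

The comparator emulates only what the plan comparison consumes: the
prescription (60 Gy mean PTV dose, renormalised exactly), a Gaussian
penumbra (σ = 6 mm) from blurring the PTV indicator, a ±2% in-target
homogeneity band, and a uniform out-of-field floor of 0.08 × prescription.
The floor plus penumbra put the surrogate's normal-brain mean dose in the
several-Gy regime characteristic of arc therapy of large recurrences, an
order of magnitude above the microbubble plans — the comparison the
pipeline is designed to quantify.  No OAR-sparing optimisation, arc
geometry or deliverability modelling.

## DVH and prescription

`D_p` ("dose received by at least fraction p of the volume") has two
deliberate implementations: the exact order statistic on voxel doses
(k-th largest, k = ⌈pn⌉), used by all solvers because it is exactly
scale-equivariant — so re-deriving D95 at the solved A95 closes the loop to
float precision — and a binned cumulative curve (0.1 Gy bins, linear
interpolation between edges) for export and plotting.  A95/A99 follow from
the linearity of physical dose in activity; the BED-matched activity
bisects/Brent-solves the strictly increasing scale equation to 1e-6
relative (the uniform-dose case is checked against the closed-form
quadratic inversion).  Plan contrasts use a two-sided paired t-test at the
0.05 level; zero-variance difference vectors are reported as degenerate
rather than as NaN statistics.

## Synthetic phantoms

Phantoms stand in for the undeposited patient cohort and emulate the
statistical structure the analysis assumes, not MR physics:

* ellipsoidal brain (default semi-axes 62×78×55 mm, ≈1.1 L) on a 0.8 mm
  grid (coarser grids are first-class for desk-scale studies);
* tumor as a union of overlapping random spheres (largest connected
  component), thresholded on a distance field so the requested volume is
  met to within one voxel and the mask stays strictly inside the brain;
  a pure sphere is available for analytic tests;
* within-VOI enhancement log-normal with σ_log = 0.5 (median contrast
  5× background) — several-fold intensity variation across a recurrence,
  chosen once as a realistic heterogeneity scale since no within-VOI
  intensity statistics are published for this setting; background brain is
  clipped Gaussian noise around a constant level;
* cohorts log-space the PTV/normal-brain volume ratio (default 0.005–0.15,
  nine phantoms) with child seeds spawned from one master seed.

Not modelled: bias fields, registration error, vessel/bone structure, DCE
kinetics.  Passing tests on these phantoms validate the pipeline's
mechanics and direction-of-effect behaviour, not patient-level dose
accuracy.

## Problem sizes

The bundled test suite runs the kernel at 4×10⁵ histories on the 53³
replication grid and 1.5×10⁵ histories on the cohort grid, and the cohort
at 1.6 mm voxels (90×108×80) — sizes chosen so the whole suite completes in
well under a minute of compute while leaving every statistical assertion
with comfortable margin.  `scripts/acceptance.py` uses 10⁶ histories in 20
batches; its uncertainty figure is extrapolated by 1/√N to 5×10⁸ histories.

## Known limitations

* No multiple scattering or secondary-electron transport; kernel accuracy
  is at the "kernel-scale dosimetry" level, not DOSXYZnrc replication.
* Homogeneous unit-density medium; no bone/air heterogeneity corrections.
* The photon model is a one-parameter point kernel; its tail shape beyond
  a few centimetres is qualitative.
* The intensity→activity surrogate is taken as given; perfusion and
  catheter-territory flow are out of scope.
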