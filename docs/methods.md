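# Methods

## Physical model

**Activity quantification.** A PET scanner imaging ⁹⁰Y detects only the
internal pair-production branch (~32 per million decays), so quantification
rests on a single scalar sensitivity S (cps/MBq) measured with a sphere
phantom. The conversion per voxel is

    c [Bq/ml] = cps / (S · 10⁻⁶ · v_ml)

and is strictly linear. S is pooled over phantom inserts as a
volume-weighted mean; because partial-volume losses make small spheres read
low, the per-insert estimates, the unweighted mean and the largest-insert
(plateau) value are all reported, and a volume threshold can exclude
inserts below a chosen size. The shipped default for S is 0.32 cps/MBq;
any quantitative use should substitute a locally measured value. Phantom
decay during a ~30 min acquisition is neglected (⁹⁰Y T½ = 2.67 d; effect
< 1%).

**Dose-rate field.** For a homogeneous unit-density medium the
instantaneous dose rate is the 3D discrete convolution of per-voxel
activity (Bq = concentration × voxel ml) with a voxel S-value kernel
(Gy per Bq·s). The convolution is evaluated as a frequency-domain product
(zero-padded boundary: tissue outside the field of view carries no
activity), and is cross-checked in the test suite against a brute-force
direct summation to 10⁻¹⁰ relative on small grids. Tiny negative
excursions from FFT round-off are clipped to zero. Tissue heterogeneity,
density scaling and partial-volume recovery are out of scope.

**Kernels.** Kernels are centre-aligned with odd dimensions per axis.
Published Monte Carlo S-value tables are user-supplied inputs (sparse
`i j k S` TSV; octant tables are expanded by symmetry, asymmetric tables
are symmetrized by mirror averaging with a warning above 1%). The bundled
generator instead synthesizes an analytic kernel from an isotropic
exponential point-dose profile (energy deposited at radius r with density
μe^(−μr); default μ = 0.3 mm⁻¹, mean range 3.3 mm, comparable to the ⁹⁰Y
beta mean path). The voxel-pair integral reduces to a separable triangular
overlap weight integrated in spherical coordinates, which removes the 1/r²
singularity; the result is rescaled so Σ S·mass equals the mean emitted
energy per decay (0.9337 MeV) exactly at the generated extent. The
generator is deterministic; the test suite validates its self-dose value
against an independent Monte Carlo point-sampling oracle.

**Kernel resampling.** Changing voxel pitch by plain value interpolation
does not conserve energy across anisotropic pitch changes, so resampling
interpolates the dose-deposition density (tricubic), clips negatives, and
renormalizes so Σ S·mass is preserved exactly; the output covers the same
physical radius as the input. The resampled-kernel invariants (centre
maximum, reflection symmetry, energy closure) are re-validated in tests
for isotropic and anisotropic targets, including the 5.47 × 5.47 × 3.27 mm
PET pitch used in the default example configuration.

**Time integration.** Microspheres are a permanent implant with no
biological clearance: R(t) = R₀e^(−λt) with λ = ln2/T½ (0.2596 d⁻¹ for
⁹⁰Y), giving total dose D = R₀/λ analytically. By default the imaged dose
rate is decay-corrected back to administration time
(R₀ = R(t_ref)·e^(+λΔt)), so D is the dose delivered from administration
onward; switched off, D = R(t_ref)/λ is the dose from imaging time onward.
At a 5 h imaging delay the two differ by ≈5.6%; because the imaging offset
is rarely recorded in the image headers, it is an explicit input. Whether
resampling onto a finer CT grid happens before or after integration is
immaterial (both maps are linear; asserted in tests); the pipeline
resamples the dose-rate field linearly, with an exact box-overlap
(volume-preserving) mode also available when an extensive redistribution
of energy is wanted instead.

## Radiobiology

**BED for a permanent implant.** For mono-exponentially decaying dose rate
the LQ biologically effective dose is

    BED = D · (1 + R₀ / ((μ + λ)(α/β))),   R₀ = D·λ,

with μ = ln2/T_repair. (The equivalent form BED = D·(1 + G·D/(α/β)) with
the Lea–Catcheside protraction factor G = λ/(μ+λ) is used as a numerical
oracle in the tests.) Note R₀ = D·λ — dose rate is dose *times* the decay
constant — and the protraction denominator contains the *ratio* α/β; these
are the only dimensionally consistent readings of the standard formula.
Defaults: α/β = 10 Gy and T_repair = 1 h for tumour, α/β = 2.5 Gy and
T_repair = 1.5 h for normal liver (late-reacting tissue), shipped as
presets `tumor` and `liver`.

**EQ2.** BED converts to the iso-effective total dose at d = 2 Gy/fraction
as EQ2 = BED/(1 + d/(α/β)). For the default tissues the divisors are 1.2
(tumour) and 1.8 (liver).

**Why per-bin, not per-mean.** BED is strictly convex in D, so applying it
to a structure's mean dose underestimates: the conversions are applied to
each differential-DVH bin (within which dose and dose rate are effectively
constant), volumes ride along unchanged, and the transformed histogram is
re-binned on a uniform axis with total volume conserved exactly. The mean
BED therefore exceeds bed(mean dose) for any inhomogeneous structure
(Jensen's inequality; asserted as a test).

**TCP.** Poisson model per bin: TCP = Π exp(−ρVᵢe^(−αDᵢ)), defaults
α = 0.33 Gy⁻¹ and clonogen density ρ = 10⁷ cm⁻³ (ρ is read as *per cm³*,
the only interpretation making ρV dimensionless). Accumulation is in the
log domain with an underflow floor at e^(−745), so a cold bin returns
exactly 0.0 rather than NaN — any ≥1 cm³ volume at 0 Gy contributes a
factor exp(−10⁷). By default Dᵢ is the curve's own dose axis (physical
unless a BED/EQ2 curve is supplied). Normal-tissue complication modelling
(LKB/NTCP, liver-disease risk) is deliberately not computed.

**Partition model.** Dt = 49.8·(A/M)·r/(1+(Mt/M)(r−1)),
Dl = Dt/r, with the conventional 49.8 Gy·kg/GBq constant taken as printed
in the standard formula rather than recomputed from nuclear data (≈49.7).
The model closes energy exactly: Mt·Dt + (M−Mt)·Dl = 49.8·A_effective,
where an optional lung-shunt fraction pre-scales A. The uptake ratio r is
a scalar input; planar-image ROI counting is out of scope.

## Synthetic data

The phantom generator rasterizes the four-sphere set (0.22, 2, 16,
65.45 cm³ at 2.996 MBq/ml; cold 8.26 L background) on a 2 mm grid — fine
enough that the smallest sphere spans ≥27 voxels — and simulates counts as
S × per-voxel activity, optionally blurred with an isotropic Gaussian PSF
surrogate (FWHM configurable; the scanner PSF is not otherwise modelled)
and degraded with Poisson noise over a 30 min acquisition. Insert masks
are the true geometric spheres, not threshold contours, so calibration
recovery is exactly invertible in the noise-free case.

The virtual patient is an ellipsoidal liver (default 1500 cm³, axes
1 : 0.8 : 0.65) with spherical tumours placed by a seeded RNG (defaults:
one 100 cm³ tumour, uptake ratio 4, 1.1–1.2 GBq administered, imaged at
5 h — desk-scale values within the range such treatments span). Activity
bookkeeping is exact: total imaged activity equals
A_admin·e^(−λ·t_image)·(1 − extrahepatic fraction). Optional cold
sub-spheres inside tumours reproduce the geographic-miss/TCP≈0
configuration. Ground-truth dose is forward-computed with the same kernel
machinery the pipeline uses, so pipeline-recovery tests isolate the stage
under test; they consequently do *not* validate reconstruction physics
(sinogram noise, scatter, randoms), motion, or microsphere clustering —
passing tests demonstrate internal consistency and correct mathematics,
not scanner-level accuracy on real data.

Default fixture sizes (128³ at 3 mm for the patient, ~100³ at 2 mm for the
phantom) generate in seconds on one core; the shared test fixture uses
72³ at 4 mm.

## Numerical choices

* Grid convention: index (i,j,k) ↦ origin + index·spacing, axis order
  (x,y,z) everywhere in memory regardless of on-disk layout — one
  convention, no kernel flips.
* RT Dose export: DoseGridScaling = max/(2¹⁶−1) (32-bit optional), so the
  stored maximum uses the full integer range and read-back error is below
  one scaling quantum; GridFrameOffsetVector carries relative offsets,
  DoseSummationType PLAN, DoseType PHYSICAL.
* Out-of-extent fill on resampling is 0 (air/absent tissue).
* Mask resampling is nearest-neighbour only, keeping masks binary; masks
  are all-in/all-out (no fractional voxel occupancy).
* DVH bins: uniform, default 0.5 Gy (≤1% mean-dose discretization error at
  typical dose scales), half-open [lo, hi) with the top bin closed. The
  "±" spread reported is the volume-weighted population SD, labelled as
  such.
* Kernel validation tolerances: reflection symmetry to 1e−9 relative;
  energy closure within a configurable truncation tolerance (default 5%,
  accommodating finite table extents).
* Degenerate inputs fail loudly: empty masks, negative doses/activities,
  inconsistent DICOM slice spacing, kernels missing the self-dose entry,
  non-overlapping geometries.

## Known limitations

Homogeneous unit-density dosimetry only; no attenuation/scatter or
reconstruction modelling; no DICOM RT Structure Set parsing or image
registration (masks must arrive co-registered); no recovery-coefficient
correction of patient images; TCP/BED parameters are population defaults
with substantial uncertainty and the TCP model ignores interpatient
radiosensitivity variation.
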