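# Methods

This note documents the models, numerical choices and limitations behind
`detem`: a desk-scale pipeline for studying the per-spot *energy margin*
(EM) in distal-edge-tracking (DET) intensity-modulated proton therapy.

## Problem setting

DET places scanned proton pencil-beam spots only at the distal edge of the
planning target volume (PTV) as seen from each beam angle. The plan's
conformity therefore hangs on each spot's range being exactly right: a rigid
setup shift that changes the water-equivalent path length (WEPL) upstream of
a spot makes it undershoot (target underdose) or overshoot (normal-tissue
overdose). The EM strategy assigns each spot, at BEV position x0, the energy

    E1(x0) = max { E0(x) : |x_k - x0_k| <= d  on each BEV axis k }

where E0 is the nominal distal-edge energy profile over the beam's-eye-view
(BEV) lattice and d is the maximum setup shift projected on the BEV plane
(default 6 mm). Shift components parallel to the beam axis cannot change a
pencil beam's range and are excluded by construction. The component-wise
inequality defines an axis-aligned box neighborhood; a disc of radius d is
available (`neighborhood="disc"`) as the physically motivated alternative,
and the box is the default because it follows the printed operator.
Energies are quantized *up* to the next whole MeV (1 MeV deliverable
resolution), so quantization never causes undershoot.

## Phantom

The default phantom emulates a challenging head-and-neck case: a 160 mm
diameter water cylinder (axis superior-inferior, length 108 mm), a 25 mm
radius spherical CTV at the isocenter, and a 20 mm radius spherical air
cavity tangent to the CTV on the lateral side, so that beams from roughly
3 of 24 arc directions traverse a large low-density heterogeneity directly
upstream of the target. PTV = CTV + 5 mm isotropic margin (Euclidean
distance transform with physical spacing); ring = 10 mm shell around the
PTV clipped to the body, the worst-case normal-tissue surrogate. Default
voxel spacing is 2 mm isotropic - a desk-scale choice; spacing is metadata,
not method. The body length and the centered CTV position are the package's
own choices where the study geometry leaves them open.

Materials are assigned from density by thresholds (air < 0.207, adipose to
0.979, water to 1.0, muscle to 1.109, dense bone above, g/cm^3), with each
interval closed at its lower bound so the partition is total. Each
material's relative stopping power (RSP) is scaled by the voxel's density
over the material's nominal density; nominal densities are set equal to the
RSP values so the scaling is continuous across thresholds and a
density-1.0 voxel has RSP exactly 1 despite being labeled muscle under the
lower-closed convention.

## Dose engine

Monte Carlo transport is replaced by an analytic pencil-beam engine; the EM
operator, the planning procedure and the robustness protocol are independent
of the transport engine.

* **Range-energy**: Bragg-Kleeman, R = 10 * alpha * E^p mm with
  alpha = 0.0022 cm/MeV^p, p = 1.77; exact analytic inverse.
* **WEPL**: exact Siddon-style voxel-boundary ray marching of RSP. Verified
  in tests against a 0.1 mm midpoint quadrature within 0.5%.
* **Depth dose**: pristine curve proportional to (R - z)^(1/p - 1)
  (the Bragg-Kleeman stopping power of the residual range), bin-averaged
  analytically across the end-of-range singularity on a 0.5 mm grid, then
  convolved with a Gaussian range spread sigma_R = p * R * sigma_E / E
  (sigma_E = 1% of E), and set to zero beyond R + 4 sigma_R. The peak falls
  within 2 mm of R.
* **Lateral spread**: sigma(wed)^2 = sigma_air^2 + (0.02 R)^2 (wed/R)^3,
  with sigma_air = 3 mm at isocenter; the multiple-Coulomb-scattering term
  reaches 2% of range at end of range with the conventional ~t^1.5 growth.
  The Gaussian is truncated at 3.5 sigma.
* **Per-voxel dose**: separable product of the depth dose at the voxel's
  WEPL and a 2D BEV Gaussian. A voxel's WEPL is taken from the spot's own
  central axis at equal geometric depth (the standard pencil-beam lateral
  approximation). Dose is normalized so a unit spot weight gives 1 Gy at
  the spot's Bragg peak in uniform water, making optimizer weights
  interpretable. Because the Bragg curve is evaluated in WEPL (water)
  space, the engine computes dose-to-water directly - fluence times the
  water stopping power - which replaces explicit stopping-power-ratio
  scaling. Nuclear halo and neutron dose are omitted.

For each beam all spots are parallel rays. The engine precomputes a
per-beam lattice of central-axis WEPL profiles (one Siddon trace per
3 mm lattice node, resampled on a 1 mm geometric-depth grid). A rigid
patient shift s is applied exactly as a beam translation by -s: a spot's
effective BEV position becomes (u - s.u_hat, v - s_z) and its axis profile
is read from the lattice by bilinear interpolation. At zero shift, spots
coincide with lattice nodes, so planned and delivered doses share one code
path and zero-shift courses reproduce the planned dose to round-off.
A 1 mm lattice changes course-level results by < 0.4% of prescription, so
the 3 mm default stands.

## Planning and optimization

DET spots sit on a 3 mm BEV lattice over the PTV footprint; E0 is the
energy whose range equals the WEPL from phantom entry to the ray's distal
PTV exit. The ORG plan uses E0, the EM plan uses E1; both share the spot
positions, objectives and optimizer.

Objectives (60 Gy in 30 x 2 Gy fractions): PTV between 58 and 60 Gy, ring
maximum 60 Gy, and at most 3% of the ring volume above 54 Gy. The
objective is a sum of one-sided quadratic voxel penalties; the DVH
constraint uses iterative worst-voxel selection (the hottest 3% of ring
voxels are exempt, the remaining above-54 voxels are pulled toward 54 Gy -
exempting the hottest minimizes the penalty, which keeps the logged
objective monotone under reselection). Weights are optimized by stages of
bound-constrained quasi-Newton iterations (L-BFGS-B, weights >= 0) with the
selection frozen per stage; nonnegativity holds at every iterate and the
stage objective sequence is nonincreasing.

Penalty weights default to PTV-min 1000, PTV-max 10, ring-max 10, ring-DVH
10. The PTV-minimum weight must dominate the ring terms by about two
orders of magnitude for the optimizer to actually reach the 58 Gy floor
against the penumbra cost in the immediately adjacent ring; with a 100/10
balance the converged plans stall near 57.0 Gy.

The influence matrix covers every PTV and ring voxel plus a 10% random
sample of remaining body voxels; entries below 0.2% of a spot's maximum
are dropped (sparsity), which perturbs sampled doses by well under 1%.

Two caveats the tests report honestly:

* The ring DVH requirement is *not attainable as a plan outcome* at these
  beam parameters: 3% of the ~145 cc ring is a shell only ~0.4 mm thick
  around the PTV, while the physical penumbra (3 mm spot sigma, ~2 mm range
  spread) is several millimetres. The optimizer treats it as the soft
  objective it is; converged plans reach V54 ~= 3.2-3.6% (ORG) and ~9-11%
  (EM - margined spots overshoot into the ring by design, which is also why
  the EM plan's ring dose is higher everywhere). The corresponding
  acceptance tests are expected to fail and are left failing.
* The planned CTV dose-volume histograms of ORG and EM agree within 1% of
  prescription, and the EM plan's mean energy exceeds the ORG plan's by
  ~6 MeV on the default phantom.

## Course simulation and evaluation

Per-fraction setup errors are sampled independently per axis from a
zero-mean Gaussian (sigma 2 mm) truncated by rejection at +/-4 mm, with an
additional whole-vector rejection at a 6 mm 3D norm so both printed bounds
of the uncertainty model hold simultaneously (toggleable). Rejection, not
clipping, so no probability mass accumulates at the bounds; the resulting
per-axis SD is 1.76 mm. One shift set is shared by the ORG and EM
deliveries, so the comparison is paired by construction. Each fraction is
a full dose recomputation through the shifted geometry at 1/30 of the plan
weights; courses are evaluated on the CTV/PTV/ring voxels to keep 30x2
recomputations desk-scale.

Courses are accumulated into normalized total dose,
NTD = sum_i d_i (ab + d_i)/(ab + d_ref), with d_ref = 2 Gy, alpha/beta =
10 Gy for the CTV and 1.5 Gy for the ring; each structure is read from the
grid accumulated with its own alpha/beta (the structures are disjoint).
The planned reference is converted with the same formula assuming uniform
fractionation, so a zero-shift course reports exactly zero variation.
Cumulative DVHs use 0.1 Gy bins; Dx% is interpolated at the dose where the
cumulative volume falls below x%, with plateau ties resolved to the larger
dose so the metric matches the sort-based definition. Dose-volume
variation is (delivered - planned)/60 Gy x 100%, so target underdose is
negative, matching the convention that a plan is acceptably robust when no
CTV volume point falls below -3%.

## What the synthetic phantom does and does not show

The phantom reproduces the *mechanism*: spots whose paths graze the cavity
rim show range errors of 10-20 mm under millimetre shifts, single-fraction
shifts of 2-4 mm depress the CTV D95 by 3.5-8.5% of prescription, and the
paired course reproduces every qualitative ordering of the study - the EM
plan is more robust than ORG at every CTV volume point, setup blur erodes
the ORG plan's high-dose ring region far more than the EM plan's, and the
EM plan pays with higher planned normal-tissue dose.

It does not reproduce the *magnitude* of the clinical result. Averaged
over 30 zero-mean fractions, the ORG CTV D95 variation on this phantom is
-0.4 to -1.3% of prescription, not below -3%: only ~3 of 24 beams traverse
heterogeneity in a cylindrically symmetric water body, whereas in real
head-and-neck anatomy essentially every beam path crosses air cavities,
bone and oblique surfaces. Passing robustness tests on this phantom
therefore validate the pipeline's mechanics, not the clinical effect size;
the two magnitude assertions that encode the clinical effect size are left
failing with this explanation rather than weakened.

## Problem sizes used

Default experiments run a 2 mm, 86 x 86 x 60 voxel phantom, ~7500 spots in
24 beams, full PTV/ring voxel sampling, 900 optimizer iterations in the
acceptance script (600 in the test suite), and 30-fraction paired courses
over 5 shift seeds (2 in the test suite) - the package's desk-scale choice
of problem size.
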