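# Methods

This note records the models implemented by `qatract`, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and the
numerical decisions a maintainer should know about. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Orientation tessellation

SDFs and ODFs are sampled on a subdivided icosahedron projected to the unit
sphere: `10·4^k + 2` vertices at subdivision level `k`, built by midpoint
(Loop-style) subdivision. Level 3 gives the standard 642-direction set with
a mean adjacent-vertex arc of 8.64°; level and statistic (mean or max edge
arc) are both exposed because "angular resolution" is reported either way in
the literature — we report the mean. The construction is antipodally
symmetric; all antipodal bookkeeping (pair index, hemisphere
representatives) is exact by construction rather than by nearest-neighbor
matching at tolerance. Diffusion is symmetric, so SDFs are evaluated only on
the 321 hemisphere representatives.

## Reconstruction

**Diffusion tensor / FA.** Log-linear fit seeded by ordinary least squares
and refined by one weighted pass (weights = squared predicted signal), the
standard WLS scheme. Negative eigenvalues are clipped to zero before
`FA = sqrt(3/2 · Σ(λᵢ−λ̄)² / Σλᵢ²)`, keeping FA in [0, 1] in noisy voxels.
Voxels with non-positive b0 signal are left NaN and never tracked into.
Multiple b0 volumes are averaged.

**GQI spin distribution functions.** For hemisphere direction û,

```
ψ(û) = Σᵢ Sᵢ · sinc( σ · sqrt(6·D·bᵢ) · ⟨ĝᵢ, û⟩ ),    sinc(x) = sin(x)/x
```

with σ the diffusion sampling length ratio (default 1.25, the value
recommended for this reconstruction) and D a fixed free-water diffusivity,
2.5×10⁻³ mm²/s at body temperature. The absolute choice of D shifts the
kernel width but is largely absorbed by the Z₀ normalization; it is
configurable. ψ is linear in the signal and therefore scales with spin
density — the property QA depends on. Small negative ringing is clipped at
zero. `iso(ψ)` is the exact per-voxel minimum sample (no smoothed floor):
deterministic, and exact for the flat baseline it is meant to capture.

A caveat the tests make explicit: with a *finite* gradient set, a perfectly
direction-independent signal does not produce a perfectly constant ψ — the
residual non-uniformity is the discrete direction sum's, about 5 % peak-to-
trough for 160 directions at b = 4000, and shrinks as the set grows. Claims
about "constant" SDFs are therefore tested at that discretization level.

**q-ball ODFs / GFA.** Analytic q-ball: even real spherical-harmonic fit of
the single-shell signal (order 8) under Laplace–Beltrami regularization
(λ = 0.006), then the Funk–Radon transform (degree-l coefficients scaled by
2π·P_l(0)). These are the standard, deterministic choices for a desk-scale
implementation. Grid (multi-b) data fall back to the outermost shell with a
warning record. `GFA = sqrt(n·Σ(ψᵢ−ψ̄)² / ((n−1)·Σψᵢ²))` over hemisphere
samples; constant or all-zero ODFs give 0 by convention.

## Peaks and QA

A fiber orientation is a vertex whose ψ strictly exceeds ψ at every 1-ring
neighbor (hemisphere-symmetrized adjacency). Strictness means plateaus and
exact ties yield no peak — deterministic and conservative. At most
`max_peaks` (default 3, the deepest crossing commonly resolved, e.g. the
three-way centrum semiovale crossing) are kept, sorted by descending QA.

**Z₀** scales free-water diffusion to 1: the reciprocal of the mean maximum
ψ over a free-water region. Phantoms pass their known water region. The
`auto` rule (voxels in the top 0.1 % of iso) is a documented stand-in for in
vivo use; it rests on the assumption that free water (CSF) carries the
largest isotropic SDF baseline, which holds in vivo because CSF's spin
density and long T2 make it several times brighter than white matter on
long-TE b0 images, but does *not* hold for an equal-spin-density phantom.
The test suite models the CSF case explicitly.

**Index swapping.** FA/GFA/anatomy maps attach to the peak map so the
tracker can threshold on any of them. The asymmetry is the point: those are
voxel-level, all-or-nothing filters; QA filtering is per orientation and can
drop one noisy fiber while keeping its crossing partner.

## Tracking

Euler integration with step Δs (default half the smallest voxel dimension;
2.5 mm voxels → 1.25 mm). At position r the up-to-8 lattice voxels of the
containing trilinear cell are polled; voxel R contributes its selected fiber
v̂(R) with weight `f(Δr) = (1−|Δr_x|)(1−|Δr_y|)(1−|Δr_z|)`. Selection keeps
fibers with index > θ_q and |⟨û, â⟩| > cos θ_a and returns δ(û,â)·â for the
smallest turning angle; angle ties break toward larger QA (deterministic,
favors salient fibers). Propagation stops when the summed weight drops below
0.5 (configurable), the position leaves the grid, or a 300 mm length guard
trips (the guard has no physical meaning; it prevents endless circulation in
loop-shaped fields, and is the one length parameter with no protocol
counterpart). Tracking is bidirectional; the two half-tracks share the seed
once.

Coordinates are continuous voxel indices with integers at voxel centers
(so the cell of r = (32.3, 12.4, 16.9) is {32,33}×{12,13}×{16,17});
streamlines are stored in mm. Direction vectors live in the image frame and
the affine is treated as scale + translation; oblique affines are out of
scope.

With `interpolation="nearest"` and a small step the tracker is FACT; the
suite checks this against an independent FACT implementation (follow the
nearest voxel's fiber to the voxel face, re-select, repeat) within 1-voxel
Hausdorff distance.

**Seeding.** A seeded PCG64 generator draws a voxel uniformly from the seed
region and a uniform sub-voxel offset — "deterministically random", so a run
is bitwise reproducible from its manifest. The initial direction is the seed
voxel's qualifying peak with the highest index value (option: random
qualifying peak); the protocol the defaults mirror used whole-brain seeding
until 2000 accepted tracks, a 60° angular threshold, and a 40 mm minimum
length. A seed budget (default 200× the target count) bounds generation when
filters are strict; exhausting it yields a partial tractogram plus a warning
record rather than an error.

One property worth stating precisely: raising θ_q shrinks (never grows) the
set of voxels reachable by tracks from a fixed seed list. With
nearest-neighbor weighting this is guaranteed (a raised threshold can only
truncate the identical voxel sequence); with trilinear weighting the path
itself can shift, so the suite verifies the containment empirically on a
fixed field and seed sequence.

## Phantoms

Fiber compartments are axially symmetric Gaussian tensors (λ∥ = 1.7×10⁻³,
λ⊥ = 0.2×10⁻³ mm²/s — typical packed-axon values), free water is isotropic
at 2.5×10⁻³ mm²/s (matching the GQI kernel constant), and non-diffusive
material contributes zero signal. Rician noise is the magnitude of a
complex Gaussian perturbation with σ = S0/SNR, SNR defined on b0. The
Gaussian mixture is the standard desk-scale surrogate for physical capillary
or wound-fiber phantoms, whose restricted-diffusion signal has no closed
form.

**Crossing phantom** (default 20×20×3 voxels of 2.5 mm; 160 directions at
b = 4000 s/mm² + 1 b0, SNR 30): two 4-voxel-wide bundles crossing at 90° in
a water bath with solid corner inserts. Bundle voxels are 0.5 fiber + 0.5
non-diffusive (capillary walls); crossing voxels 0.5 + 0.5 two fibers;
bundle ends facing the bath 0.5 fiber + 0.5 free water. This composition —
read off the physical phantom's stacked-placeholder construction — is what
makes the per-bundle anisotropic spin mass identical across the three
partial-volume conditions, so noiseless per-peak QA is equal in all three
while FA falls in the water and crossing conditions and rises beside solid
material.

**Spindle phantom** (default 44×44×5 voxels of 2.5 mm; 180 directions at
b = 1000 s/mm² + 20 b0, SNR 20 — a typical single-shot EPI figure): six
concentric ring strands of tangentially oriented fiber, volume fractions
0.9 → 0.15 emulating the decreasing groove sizes of the physical resolution
spindle, separated by ≥ 1 voxel, wound on a non-diffusive plastic body and
surrounded by gel. The plastic body is essential to the experiment it
reproduces: between and inside the strands the signal is void, so FA — a
ratio — becomes pure Rician noise there (median ≈ 0.9 in the simulation)
and no FA threshold can both retain the faintest strand and exclude the
body, while QA in the body stays near zero because ψ scales with the
(absent) signal. Ground truth (per-voxel orientations, strand masks,
centerlines) is recorded by construction.

What the phantoms do **not** emulate: restricted (non-Gaussian) diffusion,
T2 differences between compartments (except where a test constructs them
explicitly), eddy/susceptibility distortion, B1 inhomogeneity, and partial
volume geometry finer than the voxel grid. Passing tests therefore show the
indices' and tracker's behavior under ideal mixtures plus Rician noise, not
under scanner artifacts.

## Evaluation

Threshold calibration sweeps candidates and scores `map > t` against a
reference mask by Dice (Jaccard optional); Dice was chosen because "best
coverage" should balance coverage against leakage. Calibration is invariant
under strictly monotone transforms applied to both map and candidates.
Region statistics are linear-interpolation quartiles; regions under 4 voxels
are flagged low-confidence. Bootstrap CIs are simple percentile intervals
(2.5th/97.5th of resampled false-track percentages), matching the procedure
they mirror (resamples of size n with replacement; n = 2000 tracks, 1000
resamples in the reference protocol); at n = 2000, p = 0.5 the half-width
agrees with the binomial closed form within half a percentage point.

Expert identification of false tracks is not computable; on phantoms it is
replaced by construction ground truth: a track is false when more than 10 %
of its points leave its seed strand's mask dilated by one voxel (or when its
seed lies in no strand). The 10 %/1-voxel choice tolerates boundary
quantization while still catching strand-to-strand bridging.

## Problem sizes

The suite and examples run the crossing phantom at 20×20×3 voxels × 161
volumes and the spindle at 44×44×5 × 200 volumes, with 200 tracks per
tractography comparison and three phantom seeds — sizes chosen so every
stage (tensor fit, 642-direction GQI, q-ball order 8, tracking, calibration,
bootstrap) runs end-to-end in seconds while keeping every contrast the
full-size experiments rely on (crossing-region statistics, strand
separability, noise-dominated signal voids).

## Known limitations

- Axis-aligned affines only; no registration, eddy, or motion correction.
- No ODF sharpening/deconvolution — deliberately: QA is computed from the
  raw SDF.
- T2 shine-through and B1 inhomogeneity affect QA through spin density and
  are not corrected here.
- Probabilistic tracking and spline interpolation are out of scope; the
  propagation interpolator is trilinear or nearest only.
- The `auto` Z₀ rule assumes bright free water (see above); prefer an
  explicit free-water region whenever one is known.
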