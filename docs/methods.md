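# Methods

This note records the models, conventions and numerical choices behind
`tomomatch`, what the synthetic generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Matching model

The score is the masked, locally normalized cross-correlation ("fast local
correlation"): the rotated template is Fourier-weighted, mean-subtracted and
normalized under the rotated alignment mask, and correlated against the
tomogram with the tomogram's local mean and variance under the mask computed
by FFT convolutions. A perfect, noise-free match scores exactly 1 and an
inverted copy −1; the normalization applies the mask exactly once on each
side (template norm `Σ m (t−μ_t)²`, local variance `Σ m (f−μ_f)²/N`), which
is what makes the bound tight for tapered masks.

Under white Gaussian noise of width σ the unnormalized correlation
`Σ f·(RT)` equals the log-likelihood of the rotated/translated template
times σ², up to the `Σf²` and `Σ(RT)²` terms. The `Σ(RT)²` term is exactly
rotation-invariant only for lattice-commensurate rotations (90° multiples);
with trilinear interpolation it varies at the ~10⁻³ level, so the
likelihood-equivalence property is asserted on commensurate rotations where
it is exact.

Assumptions: the tomogram is already CTF-corrected (the acquisition weight is
applied to the template only); noise is additive and Gaussian; one template
per scan (multi-template runs are independent scans).

### Acquisition (Fourier) weight

Built on the template box from the wedge list. A Fourier voxel is sampled iff
the angle `atan2(k_x, k_z)` folded to (−90°, 90°] lies within the tilt span
(tilt axis y, beam along z at zero tilt); each sampled voxel carries the
|CTF| of the *nearest* tilt's defocus times that tilt's dose envelope. This
"continuous wedge + nearest-tilt envelope" composition is equivalent to
max-combining per-tilt slabs but gives the exact analytic wedge fraction
(±60° → 2/3 of the Nyquist sphere). The CTF is unastigmatic
(`χ = πλΔz k² − (π/2)Cs λ³k⁴`, Cs 2.7 mm, amplitude contrast 0.07, 300 kV
defaults, all overridable); the exposure envelope is
`exp(−d/2d_e)` with the standard empirical critical exposure
`d_e = 0.245 k^−1.665 + 2.81`. `wedge_on=False` yields the all-pass weight.

### Orientation grid

Latitude rings at θ = 0, s, 2s, … ≤ 180° with `ceil((360/s)·sin θ)` azimuth
samples per ring (single point at the poles), crossed with in-plane angles in
steps of s over [0, 360°/n) for Cn. The ceil rounding is the calibration
that yields 576/1944/15192/119952 orientations at s = 30/20/10/5° (C1).
Euler convention is intrinsic ZXZ, `R = Rz(ψ) Rx(θ) Rz(φ)`, φ in-plane —
the convention of the TOM/STOPGAP lineage.

### Numerical choices

- FFTs in float32 by default (float64 available and used in oracle tests);
  the scan precomputes the tomogram spectra once per run and the local
  variance once per run when the mask is rotation-invariant (detected by a
  probe rotation).
- Local variance floored at 10⁻¹² of the global variance; floored voxels get
  CC = 0.
- Rotation: trilinear interpolation about the voxel `n//2`, zero fill;
  matrix entries below 10⁻¹² are snapped so lattice-commensurate rotations
  permute the grid exactly.
- Orientation ties at equal CC: the lowest angle index wins (orientations are
  visited in list order with a strict-improvement update).
- Circular wraparound: voxels within half a template box of any face are
  flagged invalid for peak calling; the z-score statistics (μ, σ) are taken
  over the whole map, border included, matching the "across the entire map"
  definition.
- z-scores are undefined for constant maps (raised as an error) rather than
  returned as ±∞.

## Peak calling and evaluation

Peaks: voxels with z above threshold (default 5), greedily accepted in
descending z, each suppressing a ball of half the template diameter.
Matching to ground truth is one-to-one and greedy by distance (ties toward
lower indices), with the tolerance in nanometres. The ROC sensitivity axis is
TPR = TP/(TP+FN); precision TP/(TP+FP) is reported alongside (both
conventions circulate for picking metrics, and the printed formulas in parts
of the literature conflate them). The negative set for FPR is a dialect
choice: candidate peaks (extracted at a low threshold) that never match
ground truth; TN at a threshold counts the negatives it rejects. F1 =
2TP/(2TP+FP+FN) needs no negative set.

## In-silico peak analysis

Template-vs-itself (or vs a probe volume) matching with the same engine,
reported as raw CC, not z-scores — the z transform would hide the absolute
score drop that the angular-step rule needs. The per-orientation table holds
the CC and the density-overlap fraction (rotated density mask re-binarized at
0.5); for strictly 0/1 templates CC tracks the overlap fraction essentially
linearly, which is why overlap is a cheap predictor of the sampling
requirement. The angular-step recommendation takes, separately for cone and
in-plane rotations, the largest probed offset whose CC drop from the aligned
value stays below 40%. Hollow and elongated shapes (low solidity =
density-voxel count / voxel-center convex-hull volume, clipped at 1) fail
earlier and need finer sampling.

## Conformer assignment

Ratios x = cc_rot/cc_unrot of two per-particle scores are modeled as a
two-component 1D Gaussian mixture fitted by EM in closed form: E-step
posteriors, M-step weighted moments, stop at relative log-likelihood change
below 10⁻⁶ or 500 iterations. Initialization is deterministic (means at the
25th/75th percentiles, equal weights, pooled standard deviation); the seed
only drives optional random restarts (default 5, best likelihood kept). The
larger-mean component is labeled "rotated" by convention (the rotated
template scores relatively higher where the particle is rotated); exact
posterior ties are labeled "unassigned". Variance collapse below 10⁻⁸ and
all-identical inputs raise a degenerate-fit error instead of returning a
spurious fit. Either raw CC values or z-scores may be supplied; ratios are
scale-invariant, and the run manifest records which was used.

## Synthetic data

The generator realizes the noise model under which the CC statistic is the
maximum-likelihood solution: rotated phantom copies are planted at
non-overlapping integer positions (orientations drawn from a stated grid,
default 10°), white Gaussian noise is added in real space at a requested SNR
(variance of the signal volume over the noise variance, both over the full
box, measured pre-wedge), and the binary wedge of the wedge list is applied
in Fourier space. It does **not** emulate CTF oscillations in the data,
structural crowding, per-tilt misalignment, or reconstruction artifacts —
so a passing recovery test shows the statistic and its weighting are
implemented correctly under their own assumptions, not that any particular
real dataset will reach the same recall.

Phantom shapes: ball, hollow barrel, rod, bilayer slab, and a two-lobe
"ribosome" (large + small sphere plus a small off-axis knob). The knob is
load-bearing: two spheres alone are symmetric about their common axis, the
in-plane angle would be unidentifiable, and angular-error statistics would be
meaningless. Default alignment masks are tight spheres — farthest density
voxel + 1.5 voxels, cosine taper 2 voxels — since mask volume beyond
containment only adds background into the local statistics.

### Problem sizes

The recovery benchmark plants 20 two-lobe phantoms (18-voxel box, ≈17-voxel
diameter) in an 80³ volume at SNR 0.5 under a ±60° wedge and scans the
matched 10° grid (15 192 orientations). The box size is chosen so that
particle halos (mask-sized neighborhoods) occupy only a small fraction of
the volume: the global z-score σ is dominated by those halos once the fill
fraction grows, and real tomograms are sparse in exactly this sense — a few
hundred ribosomes fill a few percent of a tomogram. At 80³ with an 18-voxel
phantom the benchmark preserves that sparsity while the full-grid scan stays
around five minutes on one core. Oracle-equivalence checks run at 32³/8³
(full double-precision agreement to 10⁻⁶ against a no-FFT sliding-window
implementation); the likelihood-equivalence check enumerates all 512
translations × 4 commensurate rotations of an 8³ phantom.

## Known limitations

- Cn symmetry only (in-plane reduction); no dihedral or polyhedral groups.
- No astigmatic or tilt-dependent 3D CTF; the weight models |CTF| magnitude
  only.
- Peak positions are voxel-resolution (no subvoxel interpolation of peaks).
- The GMM is fixed at two components; intermediate states map onto the
  nearer component.
- Parallelism: the scan is a straightforward serial loop over orientations;
  results are independent of any batching by construction.
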