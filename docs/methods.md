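# Methods

`cyclophase` implements a hybrid cryo-EM / X-ray phasing workflow for cyclic
(Cn) ring assemblies — the portal-protein situation: a medium-resolution EM
reconstruction of the ring exists, a partial polyalanine model can be built
into it, and a crystal of the same assembly diffracts to moderate resolution
but cannot be phased directly. The workflow is: characterize the crystal,
detect the cyclic NCS order and axis from the self-rotation function, expand
the partial monomer to a Cn ring, place the ring by axis-constrained
molecular replacement, check for an EM magnification (pixel-size) error from
per-protomer rigid-body shifts, and recover an interpretable map by
NCS-averaging density modification with phase extension.

## Crystallographic substrate

Structure factors follow the convention `F(h) = sum_j f_j(s) exp(2 pi i h.x_j)`
with fractional coordinates and IT92 4-Gaussian + constant atomic scattering
factors (taken from gemmi's element tables); isotropic B factors are applied
as Gaussian smearing, so each term of atom j contributes a real-space
Gaussian with variance `(b_i + B_j) / (8 pi^2)`. Density is sampled on an
FFT-friendly grid with spacing `<= d_min / 4` for structure-factor
calculation (and never coarser than 1.25 A, so that atomic Gaussians are
resolved even when only low-resolution amplitudes are requested) and
`d_min / 3` for working maps. F(000) is excluded everywhere; crystal maps
are mean-zero and wrap periodically. Space groups P1 and P2₁2₁2₁ are
hard-coded as operator lists (validated against gemmi in the tests); the
symmetry-unique reflection set merges Friedel mates, with the
lexicographically largest orbit member as representative.

Matthews analysis uses the classic protein convention
`solvent = 1 - 1.23/Vm` (Vm in A^3/Da). For the reference ring-crystal cell
(119.85 x 238.57 x 265.61 A, z = 4) and a 13 x 59 kDa ring this gives
Vm = 2.48 and ~50% solvent, matching the published figure to within the
uncertainty of the monomer mass.

## Self-rotation function

The SRF is evaluated in direct space: `SRF(R) = sum_u P(u) P(Ru)` over a
spherical shell of Patterson grid nodes, with interpolation of the rotated
copy and normalization so the identity scores 100. Two properties drive the
parameter choices:

* the angular width of an SRF peak is roughly `resolution / vector length`,
  so discriminating chi = 30.0 / 27.7 / 25.7 deg sections (2.3 deg apart)
  requires Patterson vectors spanning the ring. The integration shell
  therefore runs from 15 A to 0.48 x the shortest cell edge (not the more
  common short shell, which cannot separate adjacent cyclic orders at desk
  scale);
* the smooth "cylinder ridge" of a ring-shaped molecule (any rotation about
  a direction near the axis scores well at low resolution) is suppressed by
  computing the Patterson from shell-normalized amplitudes
  (`F / sqrt(<F^2>_shell)`, 20 shells in s^2), the usual sharpening.

Sections are mapped on a 5 deg (theta, phi) grid with one local 2 deg
refinement pass around the top peaks. Order detection compares the best
non-crystallographic peak across candidate chi = 360/n sections and reports
an ambiguity (rather than guessing) when the top two candidates are within
2% or nothing reaches a normalized score of 15.

Equatorial twofold counting operationalizes the classic check for a Cn ring
whose axis is perpendicular to a crystal dyad: composing that dyad with the
n ring rotations yields n twofold directions on the great circle
perpendicular to the ring axis, spaced 180/n deg, one of which coincides
with the dyad itself (and is counted — it is an NCS twofold as well; the
other crystallographic dyads are off the circle by construction). The SRF is
profiled along that circle at 1 deg steps and circular local maxima are
counted when their prominence reaches 5.0 normalized score units (scores
put the identity at 100, so the cut is scale-free; across a bank of twelve
fixture realizations genuine dyad peaks have prominences 6.6-15 while
Fourier ripple stays below 3.8). On the bundled synthetic C13 and C12
crystals this yields exactly 13 and 12.

## Molecular replacement (axis-constrained)

With the axis known, the search reduces to the spin angle psi in
[0, 360/n) and a translation. For each psi, the quantities
`T_w(t) = sum_h w_h |Fc(h,t)|^2` and `T_1(t) = sum_h u_h |Fc(h,t)|^2` are
Fourier series in t (coefficients are products of the molecular transform at
symmetry-related indices), each mapped over the whole cell by one inverse
FFT. The weights make the ratio approximate an intensity correlation:
`w_h` is the shell-normalized, mean-centered observed intensity divided by
the shell scale of the translation-averaged calculated intensity, and
`u_h` that scale's inverse. The best 3000 grid nodes per psi are then
re-scored exactly with the Pearson correlation of shell-normalized
intensities (E^2-style; a raw |F|^2 correlation is dominated by the common
Wilson falloff and ranks pseudo-solutions above the true position).
Candidates are de-duplicated modulo the eight allowed P2₁2₁2₁ origin
shifts within a 5 A radius.

Selecting among the survivors needs care: polished scores of rival
solutions can differ by under 1% with the true one second. The workflow
therefore polishes the best four distinct placements (bounded whole-body
refinement, below) and ranks them by a short density-modification probe —
eight cycles of solvent flattening and NCS averaging at the phase-extension
start resolution. The true placement holds an NCS correlation around 0.9 in
the probe while impostors collapse to 0.5-0.7, a far cleaner discriminator
than any intensity score (and the same criterion by which full protocols
are compared). A solution is "unique" when the probe correlation exceeds
0.3 and leads the runner-up by at least 0.05; for raw search lists a
z-score >= 3 plus a relative score gap >= 5% is used instead (the z-score
alone misfires on flat decoy landscapes).

## Rigid-body refinement and the magnification diagnostic

Two refinement modes share one cached engine (per-chain structure-factor
contributions; translations are pure phase shifts, rotations re-sum the
chain):

* **whole-body** (used to polish a placement before density modification):
  6-parameter Powell minimization in two resolution stages — a low-resolution
  pass (to ~7-8 A) first, widening the capture radius to a few Angstrom and
  degrees, then the full window. Axis-by-axis coordinate descent and
  single-stage Powell both stall in the coupled rotation-translation valley
  for ~3 A / 5 deg starting errors; the two-stage scheme recovers such
  errors to < 0.01 A on noiseless data. When polishing an *incomplete*
  model the search is bounded to a trust region (±1.5 A, ±2 deg around the
  grid placement): the score optimum of a partial model is biased, and an
  unbounded polish can drift several Angstrom away from the true position
  while "improving" its score.
* **per-chain** (the diagnostic): derivative-free cyclic coordinate descent
  per protomer with step halving (translation steps 1.0 -> 0.02 A, optional
  rotation steps 1.0 -> 0.05 deg), accepting only global score improvements.

The magnification diagnostic reads the per-chain report: if every protomer
moved coherently toward (or away from) the ring axis, the starting model was
dilated (contracted) — the signature of an EM pixel-size calibration error.
The inferred factor is `s = <r_start> / <r_refined>` over chain-centroid
axis distances, and the diameter error of an object of size D is `D (s-1)`:
for s = 1.42/1.37 and D = 180 A, +6.57 A. On the synthetic dilated-ring
fixture, translation-only per-chain refinement recovers s to ~0.2%
(rotations refine to zero there and only add runtime). Note that per-chain
refinement of a *partial* (36%) model overfits — the score rises above the
true-placement value while chains drift ~1-2 A — so the workflow uses the
whole-body-refined model, which preserves the ring's internal Cn geometry,
as the density-modification starting point, and the per-chain result only
for the magnification report.

## Density modification

Each cycle synthesizes the FOM-weighted map `m |Fo| exp(i phi)`, then
applies, in order: solvent flattening (everything outside the
symmetry-expanded protein mask set to the solvent mean), histogram matching
(rank-preserving transform of protein-region densities to a reference CDF),
and n-fold NCS averaging (every ring-mask voxel replaced by the mean over
its orbit, cubic-spline interpolation with minimum-image unwrapping about
the ring center). Because averaging modifies one ring while its
crystallographic copies keep their old density, the modified map's
structure factors are read as the crystal-symmetry average
`F(h) = mean_s F_P1(h R_s) exp(2 pi i h.tau_s)` — reciprocal-space
symmetrization that reconstitutes all copies from the averaged ring at FFT
cost (omitting it discards most of the averaging signal and feeds
asymmetric bias back into the phases). The map is then recombined: observed
amplitudes are kept, phases come from the modified map, and Sim weights
`I1(X)/I0(X)` with `X = 2 |Fo||Fdm| / Sigma` (Sigma = shell mean of
`||Fo|^2 - |Fdm|^2|` after shell-wise scaling of Fdm to Fo) become the new
figures of merit. A sigma-A-style scheme is available
(`DMConfig.weights = "sigmaa"`) but the classic Sim weights are the default.
Amplitudes are never modified.

Phase extension runs in equal steps of 1/d from `d_start` (default 7.9 A)
to the data limit; the first block holds at `d_start` so the constraints
consolidate the starting phases before any new shell is admitted, and the
104 cycles are split evenly over the hold plus the (default 8) extension
blocks. Newly admitted reflections keep externally supplied phases if
present, otherwise they are phased from the current map with a starting
figure of merit of 0.2. The NCS correlation reported per cycle is the mean
pairwise Pearson correlation between the n images of the averaging-wedge
voxels, measured before averaging; it is invariant to map scale and offset.
A run aborts with a diagnostic if this correlation stays more than 0.02
below the running maximum of its extension block for 10 consecutive cycles
(a literal "decreasing for N cycles" rule trips on the benign slow drift
that accompanies extension).

Masks come from the EM side: the EM map is resampled into the crystal frame
through the placement transform (minimum-image aware, since the ring may
cross cell boundaries) and thresholded so one ring covers
`1.25 x (1 - solvent)/z` of the cell. The 1.25 "halo" reflects that a
7.8 A EM envelope is fatter than the close-packed Matthews volume; scans
over mask size showed tight masks truncate protein and collapse the NCS
correlation, while a moderate halo helps. The angular wedge of 360/n deg is
the averaging asymmetric unit for the correlation metric (averaging itself
uses the full ring mask; the two formulations are mathematically
equivalent). On the stated cadences (solvent every 50 cycles, NCS mask every
20) masks are re-derived from the smoothed current map near the previous
mask. The reference histogram defaults to the EM density inside the ring
mask rescaled to the current map's protein-region moments — it uses only
experiment-side inputs; a `reference_provider` hook accepts a
better-matched histogram (e.g. from a refined structure at the working
resolution) when one exists. A provider built from the placed partial model
was tested and rejected: the missing 60% of the model biases its density
distribution and degrades convergence.

## Synthetic fixtures

The generator builds fully known Cn "crystals": seeded bundles of ideal
polyalanine helices (rise 1.5 A, twist 100 deg, CA radius 2.3 A; atoms
N, CA, C, O, CB; B = 60 A^2) arranged as a protomer slab, expanded to a ring,
tilted so the axis lies in the ac plane 70 deg from c, and packed into a
P2₁2₁2₁ cell. Two construction details matter and were fixed after initial
versions proved unphysical: helix tilts are drawn from 5-38 deg (a
near-parallel bundle creates a helical-pitch pseudo-translation along the
axis that makes molecular replacement artificially degenerate), and the ring
position in the cell is chosen by a seeded search maximizing the minimum
inter-copy contact distance (>= 3.2 A target; an arbitrary center lets
symmetry copies interpenetrate, which no real crystal does and which
destroys the NCS of the crystal density). Observed amplitudes are computed
from the truth model (optional multiplicative Gaussian noise; the bundled
presets are noiseless baselines and noise is opt-in); the EM map is the
isolated ring rendered in a cubic box at 1.37 A/pixel and cosine-edge
low-passed to 7.8 A, with coordinates pre-scaled by the magnification error
when one is simulated; the partial model is the per-protomer helix subset
whose residue total is closest to the requested fraction (36% by default;
exhaustive over subsets, ties preferring fewer, longer helices — a model
builder traces the longest clear helices first), delivering 35.8% for
every seed of the default protomer.

Presets: `portal` (C13, 536-residue protomer, ~180 A ring, data to 3.74 A)
mirrors the full-size system and is provided for completeness;
`portal-mini` (C13, 134-residue protomer, ~90-100 A ring, data to 4.0 A)
and `c12-mini` are the desk-scale variants every test and the acceptance
script use — sizes chosen so a full 104-cycle density-modification run and
the SRF analyses complete in minutes on one core.

What the fixtures do *not* emulate: real protein folds and side chains,
measurement noise models beyond a flat multiplicative term, bulk-solvent
scattering, anisotropy, twinning, and cryo-EM image formation (CTF,
particle heterogeneity). Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under ideal-data
conditions at reduced scale, not their performance on experimental data.

## Numerical choices and degenerate inputs

* Trilinear interpolation everywhere except NCS averaging, which uses
  prefiltered cubic splines (repeated trilinear resampling low-passes the
  map over a hundred cycles).
* Antiparallel axis alignment picks the lowest-index perpendicular basis
  vector deterministically; ties in `choose_dm_protocol` go to the earlier
  candidate; peak merging treats undirected axes modulo 180 deg.
* Shells with fewer than 10 reflections merge into their lower-resolution
  neighbor before scaling/weighting.
* All randomness (fixture geometry, noise) flows from explicit integer
  seeds through `numpy.random.default_rng`; the workflow itself is
  deterministic, and reports contain no timestamps so a fixed config and
  seed reproduce byte-identical JSON.

## Known limitations

* Only P1 and P2₁2₁2₁ are supported; the equatorial-twofold count assumes
  an orthorhombic dyad perpendicular to the ring axis.
* The MR search is intensity-correlation based; it has no likelihood model,
  so its scores are not comparable to TFZ/LLG figures and no significance
  beyond the z-score/gap heuristic is claimed.
* The magnification factor is inferred from chain-centroid radii and
  assumes the error is a uniform isotropic dilation.
* Density modification assumes the EM map and the crystal molecule differ
  only by a rigid transform (plus optional uniform scale); conformational
  differences between solution and crystal forms are out of scope.
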