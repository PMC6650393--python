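# Methods

## The intrinsic lobe frame

An EF-lobe is two EF-hands (helix E, Ca²⁺-binding loop, helix F each)
related by an approximate two-fold axis.  For one model the frame is built
as follows:

1. **Residue pairing.**  The Cα of hand 1 are paired positionally with the
   Cα of hand 2 across the helixE + loop + helixF segments.  Where paired
   segments differ in length, each segment is truncated to the shorter
   one, keeping the loop-proximal residues (helix E keeps its C-terminal
   residues, helix F its N-terminal residues, the loop its first
   residues).  Loop-proximal truncation was chosen because the
   helix–loop junctions are the structurally conserved anchors of the
   motif; helix termini fray.
2. **Two-fold axis.**  hand 1 is superposed onto hand 2 by least-squares
   (Kabsch, SVD route with a determinant sign correction so the rotation
   is always proper).  The rotation axis of that superposition is the
   pseudo-two-fold; its rotation angle (near 180° for a well-formed lobe)
   is reported as `twofold_angle`.  Models whose angle falls below 120°
   are rejected as malformed — this gate catches wrong helix ranges or
   broken coordinates rather than borderline biology, since real lobes
   sit within a few degrees of 180°.
3. **Axes and origin.**  *z* is the two-fold axis, signed so that the mean
   of the two E-helix direction vectors has a positive *z*-component
   (this makes dE positive for canonical lobes).  *x* is the component of
   the hand-1→hand-2 centroid vector orthogonal to *z*; *y* = *z* × *x*.
   The origin is the midpoint of the two hand centroids.  The inter-hand
   interface therefore lies in the *yz*-plane, and the frame is
   equivariant under rigid motions of the model.

## Helix vectors and the two angles

Each helix is summarised by an SVD line fit to its Cα trace: the direction
is the principal axis of the centred coordinates, oriented N→C.  A caveat
worth knowing: for a short helix covering a partial number of turns the
z–(x,y) cross-moments of the trace do not vanish, so the fitted axis tilts
by up to ~2° from the geometric cylinder axis.  This is a property of any
line fit to a discrete helix, identical for all structures analysed with
the same convention, and it cancels from comparisons made in HVM
coordinates (the synthetic builder calibrates against the fitted axes, see
below).

The projected angle of a vector is atan2(v·z, v·y) in degrees — the angle
from +*y* to the vector's *yz*-projection, positive toward +*z*, range
(−180, 180].  Hand-2 helix vectors are first mapped through the two-fold
(rotated 180° about *z*) so both hands are measured in the hand-1
convention.  Then

- `dE_phi` = circular mean of the two E-helix angles,
- `dF_delta` = angle(F1) − angle(mapped F2), a plain signed difference.

Reading δdF as a *signed difference* (rather than an unsigned
"angle between") is the only reading consistent with published negative
values for open apo lobes; it is adopted throughout.  Exact two-fold
symmetry forces `dF_delta` = 0.

Angles are stored at full precision and written to TSV rounded to two
decimals.

## Calmodulin registry

Default helix ranges for the 148-residue vertebrate calmodulin (chain A):
E1 6–19, F1 29–38, E2 45–55, F2 65–75, E3 82–92, F3 102–111, E4 118–128,
F4 138–146, loops filling the gaps between E and F of each hand.  These
are canonical α-helix assignments, approximate to ±2 residues per
terminus; the original analyses never published their exact ranges, so the
registry is config-backed (`NAME = chain:start-end` lines) rather than
hard-coded.  PDB author numbering is used as-is; insertion codes are
rejected; alternate locations keep blank/'A' by default.

## Free-energy landscape

Densities are estimated with the classic binned 2D KDE: bilinear (linear
binning) assignment of points to a regular grid spanning the data range
padded by 3 bandwidths per axis, then convolution with a separable
Gaussian product kernel (truncated at 6 bandwidths), then explicit
renormalisation so that sum × cell-area = 1.  The implementation agrees
with R's `KernSmooth::bkde2D` to better than 0.1 % of the density maximum
on identical inputs, which a test asserts through `Rscript` when R is
available.

Default bandwidth per axis is the d=2 normal-reference rule
h = sd · n^(−1/6) (the n^(−1/(d+4)) rate for a 2-D product kernel); both
bandwidths and the 256×256 default grid are user-overridable, since the
appropriate smoothing depends on the sampling noise of the input.

Free energy is unitless: F = −ln(ρ/ρ_max), minimum exactly 0 at the
density mode.  All values are capped at 20 (zero-density cells would be
infinite; the global cap also keeps F weakly monotone in density, which a
zero-only cap would not).  Peaks are grid-node argmaxima of the *density*,
ties broken toward smaller dE then smaller δdF.  Contours default to
iso-F levels 1, 2, 3, … and are exported as polylines.

Pooling several runs concatenates their points into one KDE→F surface
(as when trajectories are summed into one ensemble) while each run also
gets its own KDE and peak.

## RMSD / RMSF

Both statistics are Cα-only and fitted on the selection itself, so a
lobe's numbers are unaffected by inter-lobe motion.  RMSD is the post-fit
Kabsch RMSD versus a reference model, per frame.  RMSF uses a two-pass
superposition — fit all frames to the first model, form the mean
structure, re-fit to the mean — and reports per-residue
√⟨|x_i − ⟨x_i⟩|²⟩ about the re-fitted mean.  Fitting to the mean rather
than the initial structure is the standard choice; for well-behaved
ensembles the difference is small.

## Synthetic generator

The builder places four ideal α-helices (1.5 Å rise, 100°/residue twist,
2.3 Å radius, 12 residues by default) as two hands related by an exact
two-fold about the lab *z*-axis: within hand 1, helix E is centred at
(−13, −6, 0) Å with axis (0, cos aE, sin aE) and helix F at (−5, +6, 0)
with axis angle 135° + δ/2; hand 2 is the two-fold image of a hand with F
at 135° − δ/2.  The x-stagger keeps helices from crossing for any target
angles in the supported range; configurations bringing helix Cα within
2 Å still raise an error.  Nine-residue loops and a four-residue
inter-hand linker (shallow arcs, excluded from all fits) complete a
70-residue Cα-only chain, residues numbered continuously.

Because the measured angles depend on the fitted helix axes and the
recovered frame, the builder does not trust its construction angles:
it **calibrates** them by a fixed-point iteration against the package's
own `hvm_point` (construct → measure → shift by the residual) until the
measured (dE, δdF) equal the targets within 5×10⁻⁴ degrees (5×10⁻³ for
trajectory frames).  Ground truth is therefore exact by construction.
The iteration converges in a handful of steps for dE ∈ ~[15°, 75°],
δdF ∈ ~[−35°, 35°]; trajectories warm-start each frame from the previous
frame's calibrated angles shifted by the change in targets.

Trajectories interpolate waypoints linearly in angle space and add
independent Gaussian noise per angle per frame — noise lives in angle
space, not Cartesian space, to give exact control over recovery
experiments.  The generator emulates the *geometry* of an opening/closing
EF-lobe only: no side chains, no force field, no solvent, no
thermodynamics.  Tests passing on it demonstrate that the mapping,
landscape and statistics stages are correct and self-consistent, not that
any physical system behaves this way; conclusions about real proteins
still require real ensembles.

## Problem sizes and numerical choices

- Parameter recovery is exercised on the grid dE ∈ {20…70}° × δdF ∈
  {−30, −15, 0, 15}°, tolerance 0.5°.
- The Monte-Carlo noise-propagation check uses 800 frames at (45°, 0°)
  with 5° noise; sample means are tested within 4 standard errors and
  standard deviations within 20 %.
- The KDE accuracy check uses 10 000 samples from a known 2-D Gaussian on
  the default 256×256 grid.  The L1 error of a fixed-bandwidth Gaussian
  KDE at this sample size is ≈0.055 ± 0.005 (bias–variance floor; halving
  convention, i.e. total-variation distance, gives ≈0.028).
- The end-to-end bimodal experiment uses two 300-frame runs at modes
  (35°, −5°) and (60°, 5°) with 2° noise, smoothed with 2° bandwidths on
  a 64×64 grid — smoothing is fixed at the noise scale so that the KDE
  mode is statistically tighter than a grid cell.
- Degenerate inputs: all-identical points reject KDE bandwidth selection;
  all-zero densities, empty selections, single-model RMSF, sub-5-residue
  helices and mismatched atom rosters all raise informative errors rather
  than propagating NaNs.

## Known limitations

- Helix axes are straight-line fits; kinked or strongly curved helices
  are summarised poorly (no per-turn local axes).
- The registry's helix ranges are canonical approximations; reference
  comparisons against published per-model values carry a ±1.5° tolerance
  for that reason.
- The two inferred open/close path lines seen in published landscape
  plots are *not* derived here; they can be overlaid by the caller as
  user-supplied polylines.
- Multi-model PDB is the only trajectory format; no periodic-boundary
  repair is attempted (fix trajectories upstream before export).
- mmCIF and binary trajectory formats (XTC/DCD) are out of scope.
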