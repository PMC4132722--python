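# Methods

This note records the models, conventions and numerical choices behind
polytomo, in the order the pipeline uses them. Lengths are nm, angles
degrees, mRNA lengths nucleotides (nt).

## Ribosome reference model

The reference density is procedural: a union of smooth ellipsoidal lobes
(logistic fall-off in normalised ellipsoidal radius, softness 0.08) for the
60S body, the 40S body, the 40S head with its beak, and the P1/P2 stalk,
plus fifteen fixed 2 nm "domain" bumps inside the two bodies. The bumps give
the map genuine spectral content at 3–6 nm scales; without them the map is
smooth at those frequencies and a resolution estimate in the few-nm regime
would be uninformative. No deposited map is used anywhere.

Body-frame conventions, declared once: centre of mass at the origin
(enforced by a second build pass shifted by minus the first pass's centre of
mass); 40S lobe on −y; stalk along +x; the mRNA channel spans the 40S lobe
along x with entry on + and exit on −, span 8 nm by default. The default
nominal diameter is 27 nm (mid-range for a eukaryotic 80S ribosome); the
built support measures 25–30 nm across. The construction has no rotational
self-symmetry — self-correlation under every rotation ≥ 30° stays below
0.95 (worst observed ≈ 0.90) — which is what makes per-particle orientation
recovery well-posed. Poses are proper rotations stored as unit quaternions
plus a translation; rotations are validated to orthonormality and
determinant +1 within 1e-6.

## Synthetic polyribosome fields

The generator emulates fields of 2–10-ribosome polysomes at configurable
mixture proportions of five topology classes. Geometric conventions (the
source data give no inter-ribosome distances; these are fixed once and
checked only for internal consistency):

| layout | constants |
|---|---|
| ring | chord 27 between centres, radius `27 / (2 sin(π/n))`, exits face the local tangent, 40S lobes face the ring interior |
| circular double row (flattened ring) | within-row spacing 23, rows 20 apart, path down row A and back row B, both path ends at one flank |
| zigzag (linear double row) | axial half-step 16, rows 16 apart, every link crosses rows, termini at opposite flanks |
| single row | spacing 26 |
| helix | radius 15, twist 60°/ribosome, centre spacing 27 (rise ≈ 22.4) |

Each ribosome is oriented so its exit faces the next ribosome along the
message (rings use the tangent so that even a square tetrasome's entry
angles stay smooth), then perturbed by the orientation jitter (rotation
vector with per-axis sd `jitter/√3`, so the expected magnitude matches the
configured degrees; default 5°).

Every consecutive (and, for circular forms, closing) exit→entry spacer must
fit the occupancy budget `(occupancy − footprint) × nm_per_nt` with
footprint 30 nt and 0.34 nm/nt (moderately extended ssRNA) — the two
declared constants that convert an nt budget into geometry. Occupancy is
drawn uniformly from 100–140 nt/ribosome, or set to `coding_length / n`
when a coding length is given. Layouts are built to 93% of the cap (so
jitter cannot push a link over it, with up to 20 jitter redraws as a
backstop) and are shrunk uniformly — never below 0.8 × diameter between
centres — when the budget is tight; infeasible combinations raise an error
rather than silently bending the rules.

Size-dependent substitutions, applied identically to the generated geometry
and to its ground-truth label so they introduce no label noise: circular
double rows of n ≤ 5 or odd n are built as rings (any 2×2 double row is a
rectangle, whose corners are always concyclic — the square tetrasome *is*
the circular form — and an odd flattened ring would need an apex ribosome
whose closing bend violates the kink cap); helices below n = 6 are built as
single rows (a 60°-twist helix under one turn is indistinguishable from a
planar zigzag by centre geometry). Neither substitution moves mass between
the circular and linear classes, so circular-fraction statistics are
unaffected. Topology counts use balanced (largest-remainder) allocation by
default so a condition's realised mixture equals the configured one; iid
sampling is available by flag.

Rendering sums trilinearly resampled copies of the reference at each pose
into per-polysome tiles (64³ voxels at 2 nm by default, enlarged when a
large polysome needs the margin), optionally zeroes the Fourier wedge
complementary to a ±66° tilt range (applied directly in Fourier space; the
mask is symmetric under k → −k so the volume stays real), and adds white
Gaussian noise with variance `var(signal)/SNR` measured on the
wedge-filtered signal. Particles closer than 0.8 × diameter warn but render:
crowding is physical. No CTF or dose model is included; the inference never
uses them.

## Subtomogram averaging

Subvolumes are cropped at the voxel nearest each picked position. Alignment
is expectation–maximization under `X_i = T_{R_i} A + ε`, ε white Gaussian:
responsibilities over a discrete rotation grid, then a joint M-step for the
average (rotations are norm-preserving, so the per-rotation weighted
particle sums are rotated back once each — one volume rotation per grid
element per iteration, independent of particle count) and for σ². σ² is
completed with the current average at the start of the next iteration, which
keeps the exact EM ascent property; the log-likelihood trace is asserted
non-decreasing within each pass (between passes the grid, i.e. the model,
changes).

The grid combines Fibonacci-distributed view directions with in-plane spins
at the same spacing, identity included: 15° (≈ 4400 rotations) refined
locally to 7.5° then 3.75° around each particle's responsibility mode.
The starting average is the mean of a random eighth of the particles — a
full mean is nearly rotationally symmetric, which is a fixed point of EM
(uniform responsibilities); a subset mean keeps enough asymmetry to break
that symmetry while using no external model. Translational alignment is a
±3-voxel integer cross-correlation search against each particle's
best-matching rotated average. The missing wedge is not compensated in the
likelihood: averages are intended per tomogram, where all particles share
one wedge; this is a documented simplification.

Orientations from a reference-free average are determined only up to one
global rotation (the gauge, acting on the right: `est_i = true_i ∘ h`);
angular errors are reported after estimating `h` by the chordal (quaternion
eigenvector) mean. Resolution is the FSC = 0.5 crossing (linear
interpolation between shells of width `1/(box × voxel)`) between even/odd
half-set averages computed from the final responsibilities, after a soft
spherical solvent mask (radius diameter/2 + 1 nm, 3 nm raised-cosine edge) —
the field's standard practice, since solvent voxels carry only noise and
depress the correlation of genuinely identical structure. Identical halves
give FSC ≡ 1 and Nyquist (2 × voxel); halves uncorrelated already in the
first shell give NaN. The half-sets share one alignment, making this a
same-alignment FSC (slightly optimistic against a gold-standard split).

At the conditions used in the acceptance suite — 150 particles, SNR 0.5,
24³ boxes at 2 nm — the pipeline recovers orientations to ≈ 2° median error
and the masked FSC(0.5) resolution reaches the 4–5 nm regime. These sizes
are the package's validation scale; the algorithm itself is
size-independent.

## Grouping and place-back

Polysome membership is single-linkage clustering of particle centres at
1.5 × diameter = 40.5 nm (polysomal neighbours are not in contact — the
mRNA alone holds them together — so the cutoff is looser than touching
distance; it is config-exposed). Particles from different tomograms never
group. Reconstruction places the average back at every recovered pose with
the same trilinear embedding as the forward model; on noiseless simulations
the round trip correlates > 0.95 voxelwise with the original tomogram.

## Path tracing and classification

Link feasibility: spacer ≤ budget, and no angle along the link above 120° —
between the two ribosomes' mRNA directions *and* between the straight
spacer segment and either direction. The second part is the full reading of
"no kinks": it rejects links whose geometry would force the message to
leave an exit and double back, which pure site-distance and
direction-vs-direction tests both admit.

The route is the exact minimum-total-spacer feasible Hamiltonian path and
tour: vectorised full enumeration up to n = 9 (candidates scanned in cost
order), Held–Karp subset dynamic programming for n = 10–12 (runner-up by
re-solving with each optimal edge excluded), refusal above 12. "Knots" are
rejected: two non-adjacent spacer segments closer than diameter/4. A fully
feasible tour is reported as closed (the conservative tie-break: equal-cost
open/closed resolves to closed only when the closing link is strictly
feasible); the uniqueness flag requires the best route to undercut the
runner-up by ≥ 5% of total cost, ties included.

Classification of the ordered centres, in order: n ≤ 3 or no feasible route
→ unassigned; closed + circle fit in the best plane (Kasa fit, radial RMS
< 0.25 × mean radius; the same test is the "square" criterion at n = 4) →
circular ring; closed + two antiparallel rows (best split of the second
principal coordinate, separation > max(0.3 × mean spacing, 2 × within-row
spread)) with exactly two cross-row links and planar centres → circular
double row; open + two rows + termini at opposite flanks + mostly
alternating cross-row links → linear double row; open + collinear (3D line
RMS < 0.25 × mean spacing) → single row; open + monotone rise along the
principal axis with consistently signed azimuth steps (each ≤ 150°, ruling
out planar flip patterns) totalling ≥ 90° → helical; otherwise → other
linear. Planarity for the double-row calls is out-of-plane RMS < 0.15 ×
mean spacing. The whole pipeline is invariant under global rigid transforms
and particle relabelling.

On noiseless, jitter-free synthetic polysomes of every generated topology,
classification is exact for n ≥ 4 (245/245 in the validation sweep,
including 5° jitter and random world rotations).

## Statistics

Circular fractions are reported under both weightings — per polysome and
per ribosome — because both phrasings are in use; unassigned polysomes
(dimers, trimers, unroutable groups) are excluded from the denominators.
Occupancy is `coding_length / n`. Condition reports carry label counts, the
confusion matrix against ground truth when available, and both true and
recovered fractions; fractions are invariant under pooling tomograms.

## What the synthetic data do and do not show

The generator reproduces the geometric essence of the problem — spacer
budgets, regular orientations with jitter, topology mixtures, the missing
wedge, Gaussian noise — but not CTF, dose damage, picking errors,
conformational heterogeneity, or polysome–polysome contact. Passing tests
therefore demonstrate that the inference chain is correct and
self-consistent under the declared forward model, not that it would reach
the same accuracy on real tomograms, where pose recovery (not geometry) is
the limiting step.

## Known limitations

* The path solver trusts recovered poses; it has no model of per-particle
  pose uncertainty.
* Closure is a geometric feasibility call; a generous spacer budget (long
  coding sequence, few ribosomes) can make a short linear polysome's return
  link geometrically admissible. The kink and knot screens remove the
  observed cases at the study conditions, but the call is only as sharp as
  the budget.
* The EM noise model is isotropic and wedge-blind; strong anisotropy would
  bias orientation recovery toward the wedge.
* Classification uses centre geometry only; orientation information, which
  the generator does produce, is used for tracing but not for the shape
  labels.
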