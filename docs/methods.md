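# Methods note

This note records the models implemented in `symanchor`, the parameter
choices and their defaults, what the synthetic generators do and do not
emulate, and the numerical decisions that affect results. Every number
quoted here is either a fixture constant defined in the source or an output
observed by running the shipped tests/scripts.

## 1. Geometric model

**Rigid bodies and symmetry.** Structures are rigid point sets; poses are
proper rigid transforms x → Rx + t with det R = +1 enforced at
construction (`RigidTransform`, tolerance-checked orthonormality). The
receptor's symmetry is a cyclic group C*n* about an axis in space
(`make_cn_group`); the orbit of a point is its set of images merged within
a tolerance, so an off-axis point yields *n* images and an on-axis point a
single image of multiplicity *n*. Axis detection for a homo-tetramer fits
the chain *i* → chain *i*+1 transforms by least squares, takes the
eigenvector of each rotation for eigenvalue +1, requires each rotation to
be within 15° of 90° and the mean residual to be < 1 Å, and averages the
per-pair axes and fixed points.

**Superposition.** The Kabsch closed form: SVD of the weighted covariance
of centered point sets, with the reflection guard D = diag(1, 1, sign det)
so the rotation is always proper. With fewer than 3 points or collinear
points (second singular value below sin 1° of the first) the result is
flagged `under_determined` and a warning is raised. The objective is RMS
distance; the literal mean/sum of distances is reported as a diagnostic
only. Rationale: least squares has a closed form, and for three points at
sub-ångström noise the two minimizers select the same assignment.

**Placement.** Observed peaks are first filtered against the symmetry axis
(default exclusion radius `min_axis_distance = 2.0 Å`) because axial
features in a cyclically averaged map are *n*-fold self-reinforced noise;
removals are reported, never silent. Each surviving peak is expanded to its
full C*n* orbit (deduplicated at 0.5 Å) so a single detected peak still
yields *n* candidate images. `exhaustive` mode enumerates the product space
of per-marker candidates (64 assignments for 3 markers × 4 images) and
keeps the minimal-RMSD fit; `seeded` mode picks, per marker, the candidate
nearest an initial pose's prediction, with ties broken to the lowest index
under a warning. The result carries all *n* equivalent poses g∘pose at
occupancy 1/*n* each; by construction pose *k* fits the *k*-th symmetry
image of the assigned peaks with residuals identical to the base fit (the
test suite checks this to 1e-9).

## 2. Interface and filter model

Contacts are residue–residue minimum atom distances within cutoffs:
hydrogen bond ≤ 3.5 Å with a donor/acceptor atom typing, electrostatic
≤ 6.0 Å between charged side-chain atoms, packing ≤ 4.5 Å otherwise. One
contact per (ligand residue, receptor residue, subunit), so "same residue
of another subunit" relationships are preserved. Residue-number transfer
between homologs uses global BLOSUM62 alignment (gap open 10, extend 0.5);
the shipped pore-region fragments align gap-free at a constant offset of
72 (Shaker 449 → chimera 377, 425 → 353, 445 → 373). The in-silico lysine
scan builds idealized side chains (bond lengths 1.49–1.53 Å, tetrahedral-
like angles, χ1–χ3 ∈ {−60°, 60°, 180°}, χ4 = 180°; 27 rotamers, NeRF
placement) and selects the rotamer whose NZ is nearest a target atom;
distances < 1.5 Å are flagged implausible.

Ion sites S1–S4 are defined purely geometrically: five layers of four
carbonyl oxygens, sorted along the axis with the extracellular side first;
site *k* is the midpoint of layer centroids *k* and *k*+1. Occupancy is
nearest-site assignment within a capture radius of 1.5 Å (half the ~3 Å
inter-site spacing) — geometric, never density-based. A probe "coordinates"
S1 when ≥ 3 of the four extracellular half-cage oxygens are within 3.5 Å.

## 3. Binding model

Unblocked current fraction I/Imax = floor + amplitude·(1 + [toxin]/Kd)⁻¹
with floor 0.1 and amplitude 0.9 fixed (floor + amplitude = 1 enforced; the
floor models the ~10% of channels inserted backwards, which the
extracellular blocker cannot reach). Kd is fitted by Levenberg–Marquardt
least squares on log Kd (scale-free across nM–µM), started from the
concentration nearest half-block; the standard error comes from the
Jacobian at the optimum via the delta method. Fitting requires ≥ 3 distinct
positive concentrations and at least one fraction below 0.99. Double-mutant-
cycle coupling is ΔΔG = ln[(Kd_mm·Kd_ww)/(Kd_mw·Kd_wm)] in kT
(0.5925 kcal/mol per kT at 298 K).

## 4. Crystallographic counting

For a tetragonal cell, 1/d² = (h²+k²)/a² + l²/c². Unique reflections for
Laue group 4/mmm are counted by exact enumeration of the asymmetric wedge
h ≥ k ≥ 0, l ≥ 0 (one representative per orbit, Friedel pairs merged),
minus the screw-axis absences of P4₂2₁2 (00l with l odd; h00 with h odd —
0k0 reduces to h00 inside the wedge). The naive estimate (resolution-sphere
volume / 16) undercounts by several percent because orbits on the mirror
boundaries h = k, k = 0, l = 0 are smaller than 16; the deficit is a
surface effect that shrinks as the sphere grows (measured: 17.7% at ~1600
reflections, < 10% at ~40,000). Observed outputs: 103,833 theoretical
unique at a = b = 144.200, c = 283.608 Å, dmin 2.50 Å → 99,784 expected at
96.1% completeness (reference value 99,907, −0.12%); 99,126 theoretical at
a = b = 145.434, c = 285.591, dmin 2.56 → 98,432 at 99.3% completeness
(reference 98,762, −0.33%).

## 5. Synthetic generators: scope and realism limits

All generators are pure functions of (spec, seed); fixture constants are
documented as such and make **no claim about real structures**:

- **Channel**: one protomer (five filter oxygens at ring radius 1.35 Å and
  layer heights 12.4/9.3/6.2/3.1/0.0 Å; a few named landmark residues; an
  80-atom CA shell) replicated by C4. Structure noise is specified as RMS
  atomic displacement (per-coordinate sd = noise/√3).
- **Toxin**: 37 CA atoms on a compact ~7 Å shell rotated so the probe
  lysine faces −z, with its NZ protruding 6 Å (4 Å for the
  methionine-like mutant); three marker atoms at fixed local positions
  (−8.0, −5.1, 1.0), (8.3, −4.3, 1.5), (−0.4, 9.2, 2.4) — a ~16 Å triangle
  with azimuths ~120° apart. That spacing is deliberate: 120° separations
  are maximally incompatible with the receptor's 90° rotations, so no
  mixed set of C4 images of the three markers is near-congruent with the
  true triangle (worst-case wrong-assignment fit leaves ≈ 2.1 Å RMSD) and
  the assignment search is well conditioned. No sequence threading, side
  chains, or real coordinates are attempted.
- **Peaks**: the C4 orbit of each posed marker plus isotropic Gaussian
  noise (per-coordinate sd), optionally one spurious on-axis peak. With
  `peaks_per_marker="single"` only one randomly chosen orbit member per
  marker is recorded — the disambiguated-peak situation, under which the
  noise calibration below holds. When the full noisy orbit is observed,
  orbit expansion yields 16 candidates per marker and the exhaustive
  minimum can mix independently noisy images of different observed peaks,
  biasing the fitted marker RMSD low (measured ≈ 0.13σ); this is a
  property of min-over-assignments on redundant noisy data, not a solver
  error.
- **Scenarios**: ions placed at exact site centers per condition (S2–S4
  for wild-type/K+; all four with the S1 ion at fractional occupancy 0.3 —
  an arbitrary fixture value — for the mutant; S1, S3, S4 for Cs+).
- **Dose-response**: model value + Gaussian noise (sd in fraction units,
  default 0.02), 3 replicates, truncated positive; means and SEMs returned.

## 6. Calibration and verification (measured)

From the shipped test suite (206 tests, ~34 s, one CPU) and scripts:

- Noise-free placement recovers the generating pose to < 1e-6 Å; the
  exhaustive search equals a brute-force re-enumeration on 50 seeded
  instances exactly.
- One-peak-per-marker calibration over 200 replicates per noise level:
  median marker RMSD / σ ≈ 0.84, 0.84, 0.84, 0.79 at σ = 0.25, 0.5, 1.0,
  2.0 Å (inside [0.5σ, 1.5σ]); median best-pose rotation error 1.7°, 3.4°,
  6.8°, 17.6°. Statistics run with the axis filter off, since no spurious
  peaks are generated and at σ = 2 a genuine peak occasionally wanders
  into the 2 Å exclusion zone.
- Kd recovery: median fitted Kd over 100 seeded repetitions at a 630 nM
  ground truth = 630.9 nM (seed 1) and 632.5 nM (seed 7).
- End-to-end scenario classification (occupancy pattern + pose class)
  succeeds in ≥ 99/100 seeded runs.

## 7. Limitations

- All performance statements hold for the synthetic geometry above
  (3 markers, C4, ~16 Å triangle, ≤ 2 Å noise); poorly separated or
  near-axial markers degrade conditioning, and the under-determined and
  axis-filter warnings are the intended signal for that.
- Occupancy classification is purely geometric; it cannot distinguish ion
  species or partial occupancy except as an attribute carried by the input.
- The lysine scan uses an idealized rotamer library with no energy model
  or clash detection beyond the 1.5 Å implausibility flag.
- The blocking fit holds floor and amplitude fixed; data from channels
  with a different wrong-way-insertion fraction would need those freed.
- Reflection counting supports Laue group 4/mmm with P4₂2₁2 axial
  absences only.
- Generators emulate statistical/geometric structure, not biochemistry:
  no real coordinates, no sequence-dependent geometry, no map simulation.

## 8. Problem sizes used in validation

Assignment searches of 64 (single-peak) to ~4096 (full-orbit, with
spurious) candidates; 1000 placements run in ≈ 15 s; reflection counting
at dmin 2.5 Å for a 144 × 144 × 284 Å cell enumerates ~10⁵ orbits in
milliseconds; the acceptance script completes in under a second.
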