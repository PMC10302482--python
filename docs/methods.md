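# Methods

This note documents the models implemented in `betafold`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when comparing results.

## Units and conventions

Coordinates are stored in nanometres, times in picoseconds, angles in
degrees. Residue indices are 1-based within each chain, so "an i→i+2
hydrogen bond" reads exactly as in the structural literature. Each
β-amino acid contributes the backbone atoms N, H (amide proton), CB, CA,
C, O; at most one amide H and one carbonyl O per residue enter the
analyses, which avoids double counting at termini. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; no global
PRNG state is used anywhere.

## The switching function

The continuous hydrogen-bond degree is the rational sigmoid

    s(d) = (1 − x^n) / (1 − x^m),   x = d / d0,   0 < n < m,

with the removable point x = 1 taking its limit n/m and the score clamped
to its maximum 1 at contact. It is continuous, strictly decreasing and
maps [0, ∞) onto (0, 1]; the tail decays as x^(n−m).

Defaults: d0 = 0.25 nm, n = 6, m = 10. This exponent pair is the unique
small-integer choice for which the curve crosses 50% at 0.27 nm and 10% at
0.44 nm (to two decimals: the crossings sit at 0.2714 and 0.4413 nm),
which are the conventional anchor levels for amide H···O hydrogen
bonding. The anchors, not the exponents, are the contract: the test suite
pins the two crossings and the values at the anchor distances, so any
re-parametrization must preserve them.

Two distance conventions coexist deliberately. The continuous scores
(helicity, hairpin likeness) use the hydrogen-to-acceptor-oxygen distance;
the discrete detector uses the donor(N)–acceptor(O) heavy-atom distance
together with the D–H–A angle and the N–H covalent check. The two tracks
are never mixed.

## Helicity and hairpin likeness

For an N-residue chain the helicity per frame is the mean switching score
over the N−2 possible H(i)···O(i+2) distances. N−2 is the natural
normalization because it is the largest possible number of i→i+2 bonds;
residues whose amide H or carbonyl O is genuinely absent from the topology
(proline-like) drop out of both the sum and the normalization, while any
other missing atom is an error. The hairpin score is the same construction
over a designated bond list; the default six-residue ladder (1→6, 2→5,
3→4) is replaceable per fold, since designed hairpins differ in which
bonds are diagnostic. Both scores are rigid-motion invariant and are the
plain frame-wise mean — no smoothing is applied anywhere.

## Discrete hydrogen bonds and occupancy

A donor/hydrogen/acceptor triple is counted when d(N,O) < 0.3 nm, the
D–H–A angle exceeds 150°, and d(N,H) < 0.12 nm — standard geometric
cutoffs for backbone amides. When a periodic box is present, every
distance and the angle vectors use the orthorhombic minimum-image
convention. Occupancy maps pool frames across independent runs sharing a
topology; entry (i, j) is the percentage of pooled frames in which donor
residue i is bonded to acceptor residue j, so the map of concatenated runs
equals the frame-weighted average of per-run maps (a property test). The
common "label only cells ≥ 10%" display rule is presentation-only; the
matrix always stores exact values.

## Associate detection and lifetimes

Per frame, an edge joins two chains when at least one interchain hydrogen
bond (discrete criterion, either direction) links them; equivalence
classes are computed with a union-find pass — the Hoshen–Kopelman scheme —
and verified against independent graph-component oracles on random
instances.

Lifetimes require matching components across frames, which the underlying
per-frame labeling does not define. The package uses the minimal
deterministic rule: a component of ≥ 2 chains inherits the lineage of the
previous-frame component with the largest member overlap; ties go to the
component containing the smallest chain id, then to the lineage containing
the smallest chain id. Within a lineage, an order-k event is alive while
the lineage holds ≥ k chains, so the underlying dimer stays alive inside a
trimer — growth and shrinkage of an associate do not reset the clock of
its smaller cores. A single frame of disconnection ends an event
(configurable `gap` parameter, default 0). Events alive at the final frame
are flagged open and counted with their observed, right-censored length;
no censoring correction is applied, as the statistics are descriptive.
Death times are exclusive: an event alive in frames f..g has lifetime
(g − f + 1) frame intervals. Statistics per order are the median and
maximum lifetime (ns), the percentage of the run covered by ≥ 1 alive
event of that order (union of intervals, no double counting), and events
per 1000 ns. Orders with no events are omitted from the table.

One caveat follows from the tie rule: statistics are invariant under chain
relabeling except in exactly-tied merges/splits, where the smallest-id
rule picks a survivor. The choice is deterministic and documented; any
rule must pick something.

## NOE violations

For restraint groups of chemically equivalent protons the per-frame
distance is the minimum over all cross-group pairs, taken *before* time
averaging — the spin closest to the partner dominates relaxation. The
effective distance is ⟨r⁻⁶⟩⁻¹/⁶ over the averaging window, which is never
larger than the arithmetic mean distance (equality only for constant
series; a property test). The violation is the signed difference to the
experimental upper bound; only positive values breach the bound, and the
report flags them. The default window is the final 60% of the trajectory,
discarding the initial transient — a run that equilibrates for the first
two fifths of its length keeps the same fraction regardless of scale.

## Superposition and clustering

Optimal least-squares superposition uses the Kabsch algorithm via SVD with
a determinant correction, guaranteeing a proper rotation; the attained
RMSD is recomputed from the transformed coordinates (residual ~1e-15 nm on
rigid-motion copies) rather than taken from an intermediate. Near-collinear
references are flagged degenerate — the RMSD is still valid, the rotation
is not unique.

Daura-style clustering computes all pairwise superposed RMSDs on a
selection — by default the Cα atoms of all residues except the first and
last of each chain, since chain ends fray and would blur the
classification — then repeatedly extracts the frame with the most
neighbours within the cutoff (default 0.1 nm) as a centre, removing it and
its neighbours. Ties in the neighbour count go to the earliest frame,
making the procedure fully deterministic. The cumulative count of distinct
clusters visited up to each time is monotone and ends at the total cluster
count; its plateau is the convergence diagnostic. The implementation is
tested against a literal independent transcription of the procedure on
random frame sets.

## The synthetic-data generator

The generator emulates the *statistical structure* of folding/association
trajectories, not their physics. Chains are built by internal-coordinate
(NeRF) placement from residue templates with standard amide geometry
(N–C 0.133 nm, N–CB 0.146, CB–CA 0.153, CA–C 0.152, C=O 0.123 nm); side
chains are not modelled, and cyclic residues (ACPC/ACHC-like) are
represented by clamping the CB–CA torsion θ to a ring-imposed value rather
than building the ring, which suffices for backbone hydrogen-bond
analytics. Building is exactly invertible: torsions measured from built
coordinates reproduce the inputs to < 1e-3 degrees, and mirror-image
torsions give mirror-image structures.

Torsion presets are frozen configuration data, calibrated once by
optimizing the designated hydrogen-bond geometry of each fold — H···O
0.16 nm with near-collinear N–H···O — subject to a steric penalty, and
validated functionally (bond distances and scores), never by matching
specific angle values. The calibration makes the designated bonds tight
enough that both the continuous scores (≥ 0.9) and the discrete detector
fire on the ideal geometry; real helices have somewhat longer bonds
(~0.19–0.21 nm) and correspondingly lower plateau scores.

Pseudo-trajectories interpolate torsions between two endpoint
conformations along the shorter arc, carry each chain's rigid placement by
quaternion slerp plus linear translation, and add i.i.d. Gaussian
displacements per atom coordinate (default σ = 0.01 nm, the order of a
compressed-trajectory rounding; 0.005 nm is used for "ideal fold"
fixtures). Endpoints are reproduced exactly in the noiseless case.
Multichain boxes place randomly rotated copies on a cubic grid (default
2×2×2, 3 nm spacing); association episodes are scripted by rigidly
docking donor chains so that one N–H···O contact forms collinearly at
0.285 nm.

What this does *not* emulate: Boltzmann-weighted conformational ensembles,
realistic transition kinetics, solvent, periodic wrapping of chains, or
correlated thermal motion. Passing tests therefore demonstrate the
correctness of the *analyses* on data with known ground truth — they say
nothing about force-field quality, and the lifetime/occupancy numbers of
the demo are illustrative, not predictions. Long-timescale observables of
real systems (hundreds of ns of explicit-solvent MD) are out of reach of
the generator by design; the package reproduces the computations, not
published trajectory statistics.

## Problem sizes

Default analysis fixtures use 6-residue chains (36 backbone atoms),
trajectories of 100–1000 frames at 100 ps spacing, and 8-chain boxes of
~300 atoms over ~100 frames; pairwise-RMSD clustering is quadratic in
frames and is subsampled accordingly in the demo pipeline. These sizes
make every analysis stage run in seconds while leaving all code paths —
multi-run pooling, periodic boxes, multichain tracking — exercised.
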