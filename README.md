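# betafold

Analysis toolkit for β-peptide folding and self-association in molecular
simulation trajectories, bundled with a synthetic structure/trajectory
generator so every stage can be exercised — and tested — at desk scale.

β-peptides (peptides of β-amino acids, with one extra backbone carbon and
torsions φ/θ/ψ per residue) fold into secondary structures held together by
backbone hydrogen bonds: the 3₁₄ helix with its NH(i)···O=C(i+2)
fingerprint, the 2.5₁₂ helix with i→i−3 bonding, and designed hairpins
with a cross-strand bond ladder. The same amides drive self-association of
strand-forming sequences into transient dimers, trimers and larger
oligomers. This package implements the quantitative analyses a simulator
needs to follow those processes, for people who study foldamer stability
and aggregation in MD trajectories.

## What it computes

**Continuous hydrogen-bond score.** The degree of formation of a hydrogen
bond at hydrogen–acceptor distance *d* is the rational switching function

    s(d) = (1 − (d/d₀)ⁿ) / (1 − (d/d₀)ᵐ),   0 < n < m,

smooth and strictly decreasing from 1 to 0. The defaults d₀ = 0.25 nm,
n = 6, m = 10 are calibrated so that the score crosses 50% at 0.27 nm and
10% at 0.44 nm, the conventional anchor levels for amide H···O bonding.

**Helicity.** For an N-residue chain, the 3₁₄-helical propensity per frame
is

    Z = (1/(N−2)) · Σᵢ s(d(Hᵢ, Oᵢ₊₂)),   i = 1…N−2,

the mean switching score over all possible i→i+2 bonds (N−2 is the largest
number of such bonds). A hairpin-likeness score is the same mean over the
fold's designated bonds (default ladder 1→6, 2→5, 3→4; user-overridable).

**Discrete hydrogen bonds and occupancy maps.** The classic geometric
criterion — donor–acceptor distance < 0.3 nm, D–H–A angle > 150°, H within
0.12 nm of its donor — yields per-frame events and residue–residue
occupancy maps: the percentage of pooled simulation frames (including
independent reruns) in which a residue pair is bonded.

**Oligomer lifetimes.** Per frame, chains are sorted into associates by
Hoshen–Kopelman cluster labeling over the interchain hydrogen-bond graph.
Components are matched frame-to-frame into lineages; an order-k associate
(dimer, trimer, …) is alive while its lineage holds ≥ k chains, so a dimer
stays "alive" inside the trimer it grew into. Per order the package
reports median/longest lifetime, trajectory coverage and events per
1000 ns.

**NOE violations.** For each restraint, the effective interproton distance
⟨r⁻⁶⟩⁻¹/⁶ (per-frame minimum over chemically equivalent atoms, then time
average over a configurable window) minus the experimental upper bound.

**Conformational clustering.** Least-squares superposition RMSD (Kabsch),
Daura-style greedy clustering (default: Cα atoms of the central residues,
0.1 nm cutoff) and the cumulative count of distinct clusters over time,
whose plateau indicates sampling convergence.

**Synthetic data.** Backbones are built from per-residue torsion presets by
internal-coordinate (NeRF) placement; pseudo-trajectories interpolate
torsions between two conformations and add Gaussian coordinate noise;
8-chain boxes place randomly rotated copies on a 2×2×2 grid. Preset
torsions are calibrated so each fold's designated hydrogen bonds are
tightly formed.

## Worked example

```sh
$ betafold synth --preset helix314 --frames 50 --noise 0.005 --seed 1 -o traj.pdb
wrote 50 frames of helix314 to traj.pdb
$ betafold helicity traj.pdb -o hel.csv
mean helicity 93.9% -> hel.csv
$ head -3 hel.csv
time_ps,score
0.0,0.9423283465587531
100.0,0.949731753382882
```

A synthetic ideal 3₁₄ helix with 0.005 nm coordinate noise scores ~94%
helicity — below 100% because the switching function penalizes even ideal
bond lengths slightly, exactly as it does for real helices. The full demo
pipeline regenerates every analysis product from synthetic data:

```sh
$ betafold demo --seed 1 --out demo --frames 120
INFO:betafold:helicity: mean 49.4% over 120 frames
INFO:betafold:occupancy: 4 cells > 10%
INFO:betafold:NOE: 4/4 positive violations
INFO:betafold:clustering: 3 clusters over 40 frames
INFO:betafold:association: 2 events, orders [2, 3]
demo complete; 9 outputs in demo
$ cat demo/lifetimes.csv
associate,median_lifetime_ns,longest_lifetime_ns,trajectory_percentage,associates_per_1000ns
dimer,6.0,6.0,50.0,83.33333333333333
trimer,1.8,1.8,15.0,83.33333333333333
```

The single-chain trajectory folds a helix for half its length and unwinds
it (hence ~49% mean helicity and 3 conformational clusters); the 8-chain
box forms a scripted transient dimer that temporarily grows into a trimer
— the dimer's 50% coverage includes the trimer episode, illustrating the
sub-associate rule.

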