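# Methods

This note documents the models, conventions and numerical choices behind
`gyrmotion`, and what the synthetic-data tests do and do not demonstrate.

## Superposition and RMSD

Superposition is the SVD solution of the orthogonal Procrustes problem
(Kabsch): centre both coordinate sets, H = A₀ᵀB₀, H = UΣVᵀ, R = V·diag(1,1,
det(VUᵀ))·Uᵀ. The determinant correction flips the smallest singular vector
whenever the unconstrained optimum is a reflection, so the result is always
a proper rotation. No outlier rejection or iterative trimming is applied:
reported RMSDs are plain least-squares residuals over all paired atoms.
Point sets whose centred rank is below 2 (coincident or collinear atoms)
are rejected as degenerate; the threshold is a relative second singular
value of 1e-8.

Two RMSD flavours are distinguished deliberately. The *direct-fit* RMSD
answers "how similar are two copies of this rigid body"; the *anchored*
RMSD (fit on the anchor domain, measure the other domain without
refitting) answers "how far has this domain moved relative to the anchor".
Domain definitions are inclusive residue ranges on one chain, Cα by
default; residue equivalence between structures is by residue number only
(all states of one study share a numbering scheme), so residues missing
from either model simply drop out of the intersection.

## Rotation descriptors

Rotation matrices are converted to axis–angle through a unit quaternion
(Shepperd's method, numerically stable at all angles including near 180°).
κ is canonical in [0°, 180°]; the axis sign is whatever makes that true,
and all axis comparisons (`angle_between_axes`) are therefore made between
unsigned lines, arccos|û·v̂|, computed in atan2 form for full precision
near 0° and 90°.

The screw (Chasles) decomposition splits the translation into its
component along the rotation axis (the screw translation) and a
perpendicular remainder, which fixes the axis location via the minimum-norm
solution of (I − R)x = t_perp (the null space of I − R is the axis
direction, so the least-squares solution is automatically perpendicular to
it). The reported axis point is then slid along the axis to the point
nearest a reference (the mobile-domain centroid for domain motions, the
dimer centroid for dyads). Below κ = 0.1° the axis location is numerically
meaningless; descriptors are flagged degenerate and carry a conventional +z
axis.

Polar angles are reported under a declared convention — inclination Ω from
the crystal b direction when a cell is known (+z otherwise), azimuth φ from
a towards c — because the convention of the original analysis software is
unpublished. The unit vector is always reported alongside so any consumer
can re-derive angles under their own convention.

## Dimer dyad and distance tables

A C2 dimer is accepted as such only if the transform superimposing subunit
A onto subunit B is a rotation of at least 175°; the residual 180° − κ is
reported as the dyad quality. Crystallographic dimers are built by applying
a space-group operator (which must square to the identity in fractional
space) with the lattice translation that brings the mate's centroid closest
to the source. Inter-subunit distance tables measure, per residue, the
distance between the two symmetry-equivalent Cα atoms in each state;
residues missing from either state produce flagged absent rows rather than
errors, since different crystal forms routinely lose different disordered
segments.

## Site geometry

All contact criteria are heavy-atom distances: deposited models carry no
hydrogens, so hydrogen bonds are N/O/F pairs within 3.5 Å (no angle term)
excluding same-residue pairs, and Mg²⁺ coordination distinguishes
inner-sphere partners (≤ 2.6 Å; crystallographic Mg–O bonds cluster near
2.1 Å) from weak/distorted contacts out to 3.4 Å. Cross-state measurements
(side-chain displacement, virtual clash) first superimpose the two states
on an anchor domain, then measure in that common frame; the virtual clash
is a bare minimum interatomic distance, not a van-der-Waals overlap energy.

## Surface areas and packing

SASA uses the Shrake–Rupley numeric scheme on a deterministic golden-spiral
point set (960 points per atom by default; the isolated-atom quadrature is
exact, and two-body occlusion converges to the analytic spherical-cap value
within ~1% at 4000 points). Van-der-Waals radii come from a single
element-keyed table (C 1.70, N 1.55, O 1.52, S/P 1.80 Å, default 1.80 with
a warning); interface areas follow the half-buried-surface convention with
the full ΔSASA available by switch. Waters and ligands are excluded from
interface selections by default. Interface areas are convention-dependent
at the ~10% level (radius table, point density, halving convention), which
is why all area comparisons in the tests use generous tolerances. The
symmetry-mate search covers all operators × lattice translations within ±1
cell, sufficient for contact detection at the cell sizes of interest.

## Synthetic generator

The generator emulates exactly the features the analysis consumes: two
rigid domains (201 + 172 residues, numbered 20–220 / 221–392, mirroring
GyrB43), a controllable screw motion of the mobile domain, i.i.d. isotropic
Gaussian coordinate noise applied after the motion (the simplest model
consistent with interpreting RMSD as coordinate error), missing-residue
gaps, C2 dimers with exact or offset dyads placed in a crystal cell, and a
toy nucleotide site whose distances (P–P 4.5 Å, short H-bond 2.50 Å, Mg–O
3.1 Å, Be–P 2.9 Å) hold exactly by construction. The default motion axis is
the principal axis of the Cα cloud through the inter-domain centroid — the
geometry described for the transducer motion (along the long axis of the
monomer, through the domain interface). The dimer-opening fixture swings
each subunit's mobile domain about an axis parallel to the dyad through its
domain interface, so both arms move symmetrically.

The backbone fold is idealized — α-helical segments (1.5 Å rise, 2.3 Å
radius, 100°/residue) whose axis re-aims smoothly every 15 residues along a
seeded random walk, with N/C/O atoms laid down from local frame offsets.
This yields generic, non-degenerate Cα clouds of realistic density but no
real secondary-structure topology, side chains, or chemically sensible
geometry. Consequently, passing recovery tests demonstrates the
correctness of the geometry pipeline (superposition, decomposition, dyad
and distance bookkeeping) under realistic noise and missing data; it does
not probe sequence-alignment issues, alternate conformations, or the
domain-definition choices that real structures require. Everything is a
pure function of (spec, seed): identical specs write byte-identical PDB
files.

## Problem sizes and tolerances

Stochastic assertions use medians over replicate seeds: 100 seeds for
monomer rotation recovery (κ within 0.5° at σ = 0.3 Å), 50 seeds for dyad
axis recovery (within 0.5° at σ = 0.2 Å), 50 replicates per estimate in the
acceptance script. Exact-construction assertions (noise-free recovery,
toy-site distances, fractional dyad position) use tolerances of 1e-6 or
tighter. Kabsch/axis-angle kernels are verified against scipy's
quaternion-based implementations to 1e-9 over hundreds of random
instances.

## Known limitations

* Residue pairing is numbering-based; structures with different numbering
  schemes need renumbering upstream.
* Only the first model of multi-model files is read; alternate locations
  other than blank/'A' are dropped at read time.
* The PDB writer emits a minimal record set (CRYST1, ATOM/HETATM, END);
  chain identifiers are single characters.
* SASA is O(n·points·neighbours) pure numpy; adequate for crystal-contact
  analyses (thousands of atoms), not tuned for trajectories.
* No automatic domain decomposition: domains are user-defined ranges, as
  in the motivating analysis.
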