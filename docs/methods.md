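# Methods

This note records the conventions, parameter choices and limitations behind
`npmem`'s observables, and what the synthetic-trajectory tests do and do not
demonstrate about real MD data.

## Coordinate model

All coordinates are handled in nm and times in ps (GRO native; Å-based
formats are converted on read and write). Only orthorhombic periodic boxes
are supported; triclinic input raises an explicit format error. Minimum-image
displacements map each component into (−L/2, L/2]. Before any centre-of-mass
or vector computation, molecules are made whole by unwrapping each residue
about its first atom — a COM taken across a periodic boundary is otherwise
meaningless. This convention assumes every molecule is smaller than half the
box in each dimension, which holds for ligand chains and single lipids but
not for the bilayer as a sheet; the membrane COM is therefore computed
minimum-image about a reference phosphate rather than via make-whole.
Leaflet assignment and thickness maps use raw phosphate z-coordinates and
assume the bilayer is not wrapped across the z boundary.

## Role annotation

A topology becomes useful only once atoms have roles: gold core, ligand
chains with their cationic headgroups, hydrogen-bond donor triplets, acceptor
sets, lipid P/N sites with tail chains, waters, counterions. Roles come from
a small declarative config (YAML) mapping residue/atom-name patterns to
roles, so the same analysis code runs on force-field topologies with any
naming scheme. A pattern matching zero atoms is a warning (the species may
legitimately be absent); a lipid without its P or N site is an error naming
the residue, because every headgroup-orientation statistic would silently
lose that lipid otherwise.

## Hydrogen bonds

Bonds are detected by the geometric criterion of the standard Gromacs
H-bond utility: donor–acceptor distance ≤ 0.35 nm and hydrogen–donor–acceptor
angle ≤ 30°, both inclusive and both configurable. Counts are per
(donor, hydrogen, acceptor) triplet, so one guanidinium can form up to five
bonds (two per terminal η nitrogen, one on the linking ε nitrogen). The two
η nitrogens are pooled into one class because their counts are reported
summed in this field; the ε nitrogen is its own class. Phosphate acceptors
default to the configured phosphate oxygens of the lipid headgroups, with
ester/carbonyl oxygens excluded unless configured in. Donor–acceptor pairs
within the same residue are excluded by default, so nanoparticle-internal
pairing does not inflate the ledger. Candidate pairs come from a periodic
k-d tree; this acceleration is exact (verified against an all-pairs oracle),
not approximate. The ledger partitions per-frame counts into
(η, ε) × (water, phosphate); the nanoparticle–bilayer total is the sum over
phosphate-class acceptors, and the grand total always equals the sum of the
four cells.

## Monolayer statistics

The headgroup RDF uses one representative atom per headgroup (the central
guanidinium carbon by default, configurable) and reports the mean number
density n(r)/(4π r² Δr) in nm⁻³; a dimensionless bulk-normalised variant
would only rescale the profile, and peak positions — the quantity of
interest — are identical, so the raw density is the default with the raw
per-bin counts available. Coiled ligands are those whose representative
falls below r = 1.55 nm from the core COM, the midpoint between the coiled
(1.3 nm) and extended (1.8 nm) shell modes; the coiled fraction is coiled
ligand-frames over total ligand-frames. The polar density ratio divides each
bin's share of counts by its share of solid angle, so 1 means uniform. The
polar axis points from the membrane COM to the core COM, putting the
membrane-facing region at θ = 180°; membrane-free systems fall back to the
box +Z axis. Default shell bounds (core radius to 2.2 nm) and 18 polar bins
are package choices, configurable.

## Membrane observables

α is the angle between the P→N headgroup vector and the *outward* leaflet
normal (+Z upper, −Z lower), without taking absolute values — phosphates
"fished" out of the plane show up as a genuine shift rather than being
folded back. β takes the XY projections of (nanoparticle COM → P) and
(P → N); under random headgroup azimuths its mean is 90°, and values below
90° mean the choline nitrogen points away from the nanoparticle. The
direction conventions (v_PN = N − P; v₁ = P − NP COM) are fixed here as a
package choice. Lipids whose projections are shorter than 10⁻⁶ nm are
skipped and counted. Leaflets are assigned per frame by the sign of
z_P − z_midplane (midplane = mean phosphate z); lipids within 0.3 nm of the
midplane are flagged "mid" and excluded from leaflet-dependent maps. Maps
accumulate per-lipid values into the XY cell of the P site on a 26×26
default grid with a 2.5 nm contact radius around the nanoparticle's XY
projection for the contact-vs-far-field summary; none of these three numbers
is dictated by the physics, all are config keys. Thickness is the per-cell
mean upper-phosphate z minus lower-phosphate z; note this is a z-distance,
so a rigidly tilted membrane reads thicker by 1/cos(tilt) even though its
normal-projected thickness is unchanged. Cells seen by only one leaflet are
flagged empty (NaN), never zero. The order parameter uses the
C_{i−1}→C_{i+1} segment vector per tail position (the usual reconstruction
convention for united-atom tails) against the z axis.

## Binding detection

A frame is "in contact" when any ligand headgroup atom is within
d_contact = 0.4 nm of any lipid phosphorus site. The binding event is the
first contact episode whose initial unbroken run lasts at least the
persistence time (default 10 ns) and whose occupancy from its start to the
end of the trajectory is at least 90%. The literature describes stable
binding narratively rather than numerically, so all three parameters are
package choices and every reported event carries them. Reported binding
times are therefore threshold-dependent by construction. The COM distance
trace is the full 3D minimum-image distance between the membrane COM and
the gold-core COM (a |Δz| mode is available); RMSD traces use Kabsch
superposition with the rotation determinant forced to +1.

## The synthetic generator

`npmem.synth` builds kinematic systems: a centrosymmetric pseudo-gold core
(surface atoms in antipodal pairs, so the core COM is exactly the geometric
centre and planted headgroup radii are exact), 60 ligand chains at the
extended radius (1.8 nm) with a configurable number folded to the coiled
radius (1.3 nm), guanidinium-style headgroups carrying 2+2+1 donor
hydrogens, a two-leaflet lipid grid (16×16 per leaflet at 0.8 nm spacing,
4 nm phosphate-to-phosphate separation) with P→N vectors drawn from a polar
law (delta, uniform-cone or empirical) and an azimuth law (random,
point-outward, fixed-offset), tail beads with a delta or isotropic tilt law,
optional Gaussian thinning of the upper leaflet, bulk water/counterion
clouds, and a prescribed nanoparticle height-vs-time course sampled every
10 ps by default. One ligand can be pinned to the exact south pole above a
lipid grid node so contact distances are analytic. Planted H-bond triplets
place a dedicated acceptor atom at the exact requested distance and angle
from a chosen donor hydrogen, searching placement azimuths (and falling
back to the next free hydrogen) until no *other* donor sees the acceptor
inside the cutoffs — planted ledger counts are therefore exact, not
approximate. The lone ε hydrogen points out of the (otherwise planar)
guanidinium heavy-atom plane to keep its bond cone clear of the η donors.
Each sub-builder draws from its own RNG stream spawned from the master
seed, so adding one species never perturbs another, and identical specs are
bit-identical.

What the generator does *not* emulate: thermal disorder, solvent structure,
lipid diffusion and undulations, ligand conformational dynamics, or any
energetics — trajectories are rigid-body constructions. Passing tests
therefore demonstrate that the *estimators* are correct (conventions, bin
normalisations, window bookkeeping, exactness of accelerated searches), not
that a force field or sampling protocol is adequate. Statistics whose
reference values are literature MD results (e.g. absolute H-bond numbers of
a solvated nanoparticle) can only be reproduced from the corresponding
deposited trajectories, which this package can ingest but does not ship.

## Pipeline

The pipeline discards an equilibration window (default 25 ns), computes the
monolayer statistics, the approach trace and binding event, then H-bond
ledgers for the before-binding window and for 300 ns after binding
(clipped to the trajectory end), and finally the membrane maps and order
parameters over the post-binding window. If no binding is detected, the
membrane stages run over the whole analysis window in "unbound" mode with a
warning; warnings never silently change numerical settings. All outputs are
stamped with the package version and a hash of the analysis parameters
(the output directory is excluded from the hash, so identical analyses in
different locations are byte-identical).

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances: membranes of 512–10 082 lipids, 60-ligand shells, trajectories
of 1–301 frames, with the planted binding-time run sampled at 1 ns per
frame over 300 ns. These sizes make every check exact or tightly bounded
(3σ of the relevant counting statistics) while keeping full runs in
seconds to minutes.
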