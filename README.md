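# npmem

Trajectory analysis of cationic, ligand-protected gold nanoparticles
interacting with phosphatidylcholine (PC) bilayers — the "arginine magic"
problem: guanidinium-terminated monolayers bind membranes where ammonium
ones do not, through cooperative, bidentate hydrogen bonding to lipid
phosphates. `npmem` is written for computational chemists and biophysicists
who have MD trajectories of a nanoparticle near a bilayer (GRO/PDB topology;
XTC, DCD or XYZ frames) and want the standard battery of structural
observables for this system, each one testable against synthetic
trajectories with planted, analytically known structure.

## What it computes

* **Ligand-shell structure.** Headgroup radial distribution about the gold
  core COM, g(r) = ⟨n(r)⟩ / (4π r² Δr); classification of *coiled* ligands
  (headgroup radius below a threshold, default the midpoint of the 1.3 nm
  coiled and 1.8 nm extended shell radii); polar angular number density
  relative to a uniform sphere, ratioᵢ = (countᵢ/Σcount) / (ΔΩᵢ/4π) with
  ΔΩᵢ = 2π(cos θᵢ − cos θᵢ₊₁), with the "south pole" (θ = 180°) facing the
  membrane; shell occupancy counts for counterions and waters.
* **Hydrogen-bond ledgers.** Geometric criterion — donor–acceptor distance
  ≤ 0.35 nm *and* H–donor–acceptor angle ≤ 30° (both configurable) — with
  per-frame counts partitioned by guanidinium donor position (the two
  terminal η nitrogens pooled vs the linking ε nitrogen) and acceptor class
  (water vs lipid phosphate), windowed before/after membrane binding.
* **Membrane deformation.** The headgroup tilt α = arccos(v̂_PN · n̂)
  against the outward leaflet normal; the in-plane angle
  β = ∠(proj_XY(r_P − r_NP), proj_XY(r_N − r_P)), 90° under random
  azimuths; XY maps of both plus phosphate-to-phosphate thickness maps and
  the tail order parameter S = ⟨(3 cos²θ − 1)/2⟩.
* **Binding events.** Membrane–core COM distance traces and detection of the
  first persistent contact episode (any headgroup atom within 0.4 nm of a
  lipid phosphorus, persisting ≥ 10 ns with ≥ 90% occupancy to the end of
  the run; all three parameters are reported with every event). Kabsch
  superposition RMSD traces for convergence checks.
* **Synthetic systems.** `npmem.synth` builds annotated nanoparticle +
  bilayer systems and kinematic trajectories where every one of the above
  observables has a planted ground-truth value — delta-law headgroup tilts,
  exact H-bond triplet geometry, prescribed binding times, Gaussian
  thickness dimples. These are first-class, seeded, bit-reproducible
  constructions, used by the test suite and usable as fixtures elsewhere.

## Worked example

Analyse a synthetic bound-state trajectory in which the nanoparticle drops
onto the membrane at 0.1 ns and forms a planted H-bond partition of
159/23/38/4 bonds per frame (η–water / η–phosphate / ε–water / ε–phosphate):

```python
from npmem import AnalysisConfig, HBondPlant, SyntheticSpec, run_pipeline

cells = {("eta", "water"): 159, ("eta", "phosphate"): 23,
         ("epsilon", "water"): 38, ("epsilon", "phosphate"): 4}
spec = SyntheticSpec(
    seed=1, n_frames=40,
    np_path=((0.0, 6.0), (90.0, 6.0), (100.0, 4.317), (390.0, 4.317)),
    hbond_plants=tuple(HBondPlant(0.30, 10.0, dc, ac, count=n, active_from_ps=100.0)
                       for (dc, ac), n in cells.items()),
)
cfg = AnalysisConfig(synthetic=spec, out_dir="demo_out", equilibration_ns=0.0,
                     persistence_ns=0.05, post_binding_ns=1.0, block_frames=5)
report = run_pipeline(cfg)
print(report["binding"]["binding_time_ns"])                      # 0.1
print(report["rdf"]["peak_nm"])                                  # 1.775
print(round(report["coiled"]["fraction"], 4))                    # 0.0333
print(report["hbonds"]["after_binding"]["grand_total"])          # 224.0
print(report["hbonds"]["after_binding"]["np_bilayer_total"])     # 27.0
print(report["membrane"]["alpha"]["global_mean_deg"])            # 67.0
print(report["membrane"]["thickness"]["global_mean_nm"])         # 4.0
```

The binding detector recovers the planted 0.1 ns drop; the RDF peak sits in
the bin containing the planted 1.8 nm extended-shell radius (bin centre
1.775 at Δr = 0.05); the coiled fraction is exactly 2/60; the after-binding
ledger reproduces the planted partition, summing to η 182, ε 42,
nanoparticle–bilayer 27 and a grand total of 224 bonds; the delta-law
membrane maps back to α = 67° and 4.0 nm thickness in every cell. Output
files (CSV tables, CSV grid maps, JSON summaries, `report.json` stamped
with the config hash) land in `demo_out/`.

The same pipeline runs on real data from the shell:

```sh
npmem analyze --topology system.gro --trajectory traj.xtc --config analysis.yaml --out run1/
npmem synth   --spec synthetic.yaml --out synth_out/
npmem report  --out run1/ --out run2/ --summary summary.json
```

## Layout

```
src/npmem/
  geometry.py   minimum-image and make-whole primitives (orthorhombic boxes)
  system.py     role-annotated topology model + selection grammar
  io.py         GRO/PDB/XTC/DCD/XYZ readers and writers (via MDAnalysis)
  synth.py      synthetic systems and trajectories with planted truth
  monolayer.py  RDF, coiled classification, polar density, shell occupancy
  hbonds.py     geometric H-bond detection and partitioned ledgers
  membrane.py   alpha/beta angles, XY maps, thickness, order parameters
  binding.py    COM traces, binding-event detection, Kabsch RMSD
  pipeline.py   config-driven end-to-end protocol
  cli.py        `npmem analyze | synth | report`
docs/methods.md   model conventions, parameter choices, limitations
```
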