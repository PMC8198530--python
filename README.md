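# trimertrace

Detection and quantification of **subunit asymmetry in homotrimeric
proteins** from multi-frame structures, built around residue contact
networks and spectral graph partitioning. The motivating system is the kind
of mushroom-shaped homotrimer exemplified by the TRAF2 C-terminal domain,
where thermal dynamics can break the C3 symmetry so that two subunits stay
tightly coupled while the third drifts away — a **2:1 clusterization** that
shows up in contact networks, interface maps and centre-of-mass distances
long before any dissociation event.

## What it computes

**Protein contact network (PCN).** For each frame, residues are nodes
(C-alpha positions) and an edge joins residues *i*, *j* whenever

```
4 Å ≤ ‖CA_i − CA_j‖ ≤ 8 Å
```

The lower cutoff excludes covalently bonded neighbours (consecutive
C-alphas sit near 3.8 Å), the upper keeps genuine noncovalent contacts.

**Fiedler bipartition.** With adjacency `A`, degree matrix `D` and graph
Laplacian `L = D − A`, the eigenvector `v2` of the second-smallest
eigenvalue (`λ2`, the algebraic connectivity) two-colours residues by
`sign(v2_i)`. Chains take the majority label of their residues, giving the
paired chains, the lone chain and a partition purity per frame; a whole
trajectory becomes a pairing trace with switch events and occupancies.

**Interface maps.** Per chain pair, the matrix of minimum inter-residue
distances (C-alpha or all heavy atoms), classified into nested ranges
(≤7, ≤10, ≤13, ≤16 Å), typed hydrophobic / hydrophilic / mixed, with
difference maps between frames and sliding-window hotspot segments.

**Geometry.** Pairwise subunit centre-of-mass distances, gyration radius
(relative to frame 0), RMSD with optimal superposition, and mean-square
displacement with the diffusion coefficient from `MSD = 6Dt`.

**Hydrodynamics and statistics.** Stokes–Einstein radius
`R_H = k_B T / (6πηD)`, hydrated equivalent-sphere diameter, DLS particle
dispersity `Σ(D_i − ⟨D⟩)² q_i/100 / ⟨D⟩²`, Gaussian fits of size
histograms, and the mass-action trimer–monomer equilibrium
(`3M ⇌ T`, `K_d = [M]³/[T]`).

A **synthetic-data module** generates three-chain ensembles with planted
geometric asymmetry (an approaching pair, a distancing lone chain, optional
scheduled pair switches, per-atom thermal noise) plus ground-truth labels,
so every stage is testable without external trajectories.

## Worked example

```python
from trimertrace.synthetic import TrimerGeometrySpec, generate_trimer_ensemble
from trimertrace import contact_network as cn

spec = TrimerGeometrySpec(n_frames=100, approach_delta=-6.0, noise_sigma=0.3,
                          pair_schedule=((0, ("A", "C")), (50, ("A", "B"))),
                          seed=0)
ensemble, truth = generate_trimer_ensemble(spec)
trace = cn.cluster_trace(ensemble)
print({"".join(sorted(p)): f for p, f in trace.occupancy.items()})
print(trace.switch_events)
```

prints

```
{'AB': 0.5, 'AC': 0.5}
[50]
```

— the planted pair (A,C) for the first 50 frames, (A,B) afterwards, with
the single switch event localized exactly at the scheduled frame. The same
workflow is available from the shell (`trimertrace synth`, `trimertrace
cluster`, `trimertrace run`), and the numbered scripts under `analysis/`
drive the full study: `01_simulate_ensembles.py` writes the canonical
synthetic inputs, `02`–`05` run clustering, interface, geometry and
hydrodynamics stages, printing their findings and writing tables under
`results/`.

A scalar example:

```python
from trimertrace import hydro
r = hydro.hydrodynamic_radius(hydro.HydroParams(7e-11, 310.0, 6.9e-4))
print(round(r * 1e9, 2))   # 4.7  (nm)
```

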