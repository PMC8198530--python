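# Methods

## The model: 2:1 clusterization of a homotrimer

A homotrimer in solution is nominally C3-symmetric, but its thermal
dynamics need not be: two subunits can remain tightly coupled while the
third loosens its interfaces. This package detects that state from
structure ensembles alone. Each frame is reduced to a protein contact
network — nodes are residues at their C-alpha positions, edges join pairs
whose distance lies in the noncovalent band `[4, 8]` Å. The lower edge
excludes covalent backbone neighbours (consecutive C-alphas sit near
3.8 Å, peptide-bond geometry), making a sequence-separation filter
unnecessary; the upper edge keeps first-shell contacts (the optimal single
cutoff for contact networks is generally near 5 Å, comfortably inside the
band). Intra- and inter-chain pairs pass through the same rule.

The network is bipartitioned spectrally: with `L = D − A`, the eigenvector
`v2` of the second-smallest eigenvalue splits residues by the sign of its
components, and `λ2` (algebraic connectivity) measures how tightly the two
halves are coupled. On a trimer with dynamic asymmetry the cut falls along
the weakest interfaces and isolates one chain: chains take the majority
label of their residues, the two sharing a label are the pair, and the
fraction of residues agreeing with their chain's majority (purity) exposes
borderline frames. Per-frame results concatenate into a pairing trace with
switch events and occupancy fractions.

Assumptions worth stating: frames are whole, unwrapped molecules in a
single coordinate frame (no periodic box handling); residues are the unit
of the network (C-alpha geometry only); the partition is always into
exactly two clusters (`k = 2` spectral clustering; a symmetric trimer has
no stable 2:1 split and is reported with low purity and, under exact
degeneracy, a deterministic tie-break rather than a meaningful pairing).

## Numerical choices

- **Eigensolver.** Dense symmetric `scipy.linalg.eigh` on the full
  Laplacian; networks here are a few hundred nodes, where the dense solver
  is both fast and bit-stable. Eigenvalue ties at `λ2` (within `1e-10`
  relative to the spectral range) are resolved by choosing, among the
  degenerate eigenvectors, the sign pattern with the most balanced cut,
  then the lexicographically smallest labelling.
- **Sign conventions.** `v2` is flipped so the first chain's mean component
  is non-negative (stable labels across frames); components within
  `1e-12·‖v2‖∞` of zero join the positive class.
- **Disconnected frames.** When the graph is disconnected the zero
  eigenvalue is degenerate and a numerical eigenbasis is an arbitrary
  rotation of the component indicators, so the component-separating vector
  is constructed directly (components greedily balanced by size); `λ2 ≈ 0`
  and the frame is flagged. A frame with no inter-chain edges at all gets
  an arbitrary lexicographic pairing flagged `disconnected`.
- **Chain assignment fallback.** If all three chains share one majority
  label there is no 2:1 spectral signal; the two chains with the most
  inter-chain contacts are paired and the frame flagged low-confidence.
- **Sign rounding is a relaxation.** The sign-based Fiedler cut is exactly
  the minimum ratio cut on cleanly separable graphs (the worked path and
  joined-triangle examples in the tests) but carries no general optimality
  guarantee — on random connected graphs its ratio-cut objective is
  typically within a small factor (measured ≤ 3×) of the exhaustive
  optimum but not always among the best two values. The test suite asserts
  exactly this: optimality on the worked examples, near-optimality (factor
  ≤ 4) on a fixed random ensemble, and the acceptance script reports the
  measured top-2 rate rather than assuming it.
- **Superposition.** RMSD uses the standard SVD (Kabsch) construction with
  reflection correction; per-chain mode superposes each chain
  independently.
- **MSD.** The curve is the displacement-from-origin statistic
  `⟨(r(t) − r(0))²⟩`, ensemble-averaged over particles when several series
  are given — for a rigid diffusing body the average over its atoms is the
  natural reading. `D` comes from a least-squares line through the origin
  (`MSD = 6Dt`) over a configurable lag window; the fit's `R²` is reported
  and visibly non-linear curves (`R² < 0.99`, e.g. ballistic motion) are
  flagged. A sliding-origin window average exists behind a flag for
  variance reduction and is off by default. Unit conversion is exact:
  1 Å²/ns = 1e-11 m²/s.
- **Equilibrium solver.** `3M ⇌ T` with `K_d = [M]³/[T]` (units M², the
  only unit-consistent single-step reading) reduces under mass balance to
  `m³ = K_d (c − m)/3`, solved by Brent bracketing on `[0, c]` at relative
  tolerance ~9e-16; a fixed-point iteration serves as the independent
  cross-check in the tests. For `K_d = 1.4e-16 M²` at `c = 2 µM` the model
  yields ≈97.7% of protein mass in trimers. No dimer intermediate is
  modelled.
- **Constants.** `k_B = 1.380649e-23` J/K and `N_A = 6.02214076e23` /mol
  (exact SI); °C converts as `K = °C + 273.15`. Viscosity is always an
  explicit input (6.9e-4 Pa·s for water at 37 °C, 8.9e-4 at 25 °C are the
  conventional values used in examples), never looked up silently.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cutoff_low`, `cutoff_high` | 4, 8 Å | noncovalent PCN band |
| contact-map bins | 7, 10, 13, 16 Å | nested distance classes, upper edges inclusive |
| hydrophobic set | A V L I M F W P C G Y | contact typing (configurable); both-in = hydrophobic, both-out = hydrophilic |
| COM weighting | residue mass | each C-alpha carries its residue's average mass; `uniform_ca` as audited alternative |
| `v̄`, hydration | 0.73 cm³/g, 0.35 g/g | hydrated-sphere defaults for globular proteins |

The inclusive upper-edge convention for contact classes (`d ≤ 7` is class
1, `7 < d ≤ 10` class 2, …) is fixed and deliberate, so the class of a
distance is a pure function of the bin edges.

## The synthetic generator

The generator emulates only the geometry of subunit asymmetry, nothing
else: one subunit trace (a smoothed self-avoiding walk with exact 3.8 Å
C-alpha spacing confined to a sphere of radius `3.4 n^{1/3}` Å — roughly
globular packing density — or an ideal helix-like trace) is rigidly placed
three times around the z-axis. The default ring radius puts neighbouring
subunit centroids at `2 r_blob − 3` Å so the symmetric state shares a
sparse contact fringe across all three interfaces. Planted signal enters
as radial offsets: `approach_delta` on both chains of the planted pair
(negative brings them together), `asymmetry_delta` on the lone chain,
optionally scaled per frame by a drift schedule and re-planted by a pair
schedule; per-coordinate Gaussian noise is added after rigid placement so
inter-subunit signal is not confounded with intra-subunit flexibility.
Every frame's planted pairing (or the symmetric sentinel when both deltas
vanish) is recorded as ground truth.

What this does **not** emulate: force fields, solvent, secondary-structure
rearrangement, correlated (non-white) thermal motion, and any coupling
between interface chemistry and geometry — residue identities are a random
homotrimer sequence used only for mass weighting and contact typing.
Passing tests therefore demonstrate that the analysis recovers *geometric*
asymmetry of the planted kind at realistic backbone spacing and noise, not
that it would resolve every asymmetry a physical trajectory can produce.
Consecutive-spacing guarantees hold for the rigid geometry; added noise
perturbs them by its own magnitude.

Noise-free symmetric specs are C3-exact to machine precision, which makes
the spectral problem degenerate by construction; such frames exercise the
deterministic tie-break path. With noise, per-frame clustering of a
symmetric trimer flickers among the three pairings (no pairing dominates
on average), while a planted approach of 4 Å or more against 0.5 Å noise
is recovered in ≥95% of frames; single-frame flickers (~2%) can appear
even at strong signal, so switch events are best read jointly with purity.

## Problem sizes

Tests and the acceptance script run on ensembles of 3 × 40 residues and up
to 100 frames, random graphs of ≤10 nodes for exhaustive ratio-cut
enumeration, 500-bin histograms for the fine-bin dispersity identity, and
Brownian ensembles of 25 walkers × 10⁴ steps × 50 seeds — sizes chosen so
each statistical check has comfortable resolving power while the whole
suite stays interactive.

## Known limitations

- The 2:1 assignment is trimer-specific by design; other stoichiometries
  need a different chain-level rule.
- Contact-map all-atom mode uses heavy atoms as parsed; no hydrogen
  placement, no structure repair.
- PDB is the only structure format (multi-MODEL for ensembles); trajectory
  formats would slot behind the same ensemble contract but are not
  implemented.
- Relative (not absolute) gyration radius is the meaningful output for
  C-alpha-only input, since mass-weighting over all atoms would shift the
  absolute value slightly.
- The equilibrium model's ≈97.7% at 2 µM follows from the stated
  single-step mass-action definition; conventions that average over a
  dimer intermediate or quote molar rather than mass fractions will differ.
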