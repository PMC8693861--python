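# Methods

This note records the models, conventions and numerical choices behind each
analysis, what the synthetic generators do and do not emulate, and the design
decisions taken where more than one reasonable convention exists. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units, indexing and file conventions

All internal lengths are ångström; GRO files (nm) are converted on read and
write, and bilayer widths are reported in nm only at the summary layer, since
membrane widths are conventionally quoted in nm while atomic distances are
quoted in Å. Times are ns (GRO `t=` headers, which are in ps by GROMACS
convention, are divided by 1000 on read). Atom and residue numbers stay
1-based as in the source files; every index the API returns is 0-based.

PDB parsing is fixed-column; HETATM records (heme, acyl-CoA analogs, waters)
are kept as ordinary atoms because ligands are first-class in every analysis
here. Van der Waals radii come from the bundled Bondi set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20, Fe 2.00 Å); unknown elements fall back to
1.70 Å with a warning. Coarse-grained bead names (PO4, BB, SC1, …) get
MARTINI-style bead radii (2.64 Å regular, 2.30 Å small) keyed by name.

The `xyzt` trajectory dialect (`N T` header; per frame a `t=<ns>
box=<lx> <ly> <lz>` line followed by `name x y z` atom lines in Å) exists so
that trajectories used in tests and examples are plain text and fully
self-contained. Its writer prints `%.6f`, and write∘read is bitwise-stable.

The selection language (`chain`/`resid`/`resname`/`name`/`element` terms,
multi-valued, combined with `and`/`or`/`not` and parentheses) houses every
atom-identification string the metrics need, e.g. `"resid 335 and name CH2"`
for a tryptophan Cη2 (PDB nomenclature `CH2`) or
`"resname HOH SOL TIP3 WAT and name O OW OH2"` for water oxygens. Evaluation
always returns a sorted index list, so downstream computations are
order-deterministic.

## Gating metrics

The gate is quantified three ways, all per frame:

- **Pair distance** between two single atoms. Minimum-image wrapping is off by
  default: the gate atoms are intra-protein and never split across periodic
  boundaries, while bilayer analyses (where wrapping matters) enable it.
- **Moving-sphere occupancy**: waters are counted inside a sphere (default
  radius 4 Å) centred on the per-frame centre of geometry of the gate
  residues' Cα atoms. "A water" defaults to the water-oxygen selection above
  (user-overridable); the boundary is closed (≤ r), matching common
  neighbour-search semantics. Counting oxygens only makes the count an integer
  number of molecules rather than of atoms.
- **Plane angle**: the angle between a side-chain Cα→Cγ vector and the plane
  of three backbone Cα atoms is arcsin of the normalised dot product with the
  plane unit normal n = (p2−p1)×(p3−p1)/|…|, signed positive toward n. The
  sign convention is fixed by the plane-atom order via the right-hand rule;
  reordering the plane atoms flips the sign.

A frame-stride or equilibration skip is never applied implicitly; both are
caller choices (`times`/slicing upstream, `skip` in the pKa aggregator,
default 0).

Rolling means (used only for presentation of noisy traces) are centred with
truncated windows at the edges, so output length equals input length; the
default window is 50 frames. Kabsch superposition uses the SVD construction
with the determinant correction, so the returned matrix is always a proper
rotation even for reflected inputs; configurations with fewer than 3 points
or rank < 2 are rejected.

## Density grids

`average_density` optionally superposes every frame onto frame 0 (Kabsch on
an alignment selection of ≥ 3 atoms) and bins target atoms into voxels
(default spacing 1 Å). Values are occupancy counts divided by the number of
frames; atoms outside the grid are tallied in a `spill` counter so the
counting identity `sum(values)·n_frames + spill = n_frames·n_targets` holds
exactly on every input — this identity is asserted in the tests rather than
any approximate normalisation. Auto-extent pads the bounding box by half a
voxel so a static atom sits at a voxel centre. Grids serialize to OpenDX
("gridpositions counts", z fastest), readable by standard visualization
tools.

## Bilayer width and deformation

"Bilayer width" is defined as the phosphate-to-phosphate leaflet separation
(CG PO4 beads or atomistic P atoms), since phosphate positions are what
density maps of lipid headgroups resolve. Leaflets are assigned per frame by
the sign of z relative to the instantaneous mean phosphate z; inputs where
>90% of beads lie within 0.1 Å of the midplane are rejected as non-bilayers.

Width maps accumulate the *time-mean* z of each leaflet per xy-bin (default
bin 2 Å) and then difference the two surfaces, rather than averaging
per-frame widths; for small fluctuations the two differ only at second
order, and the surface-mean form is robust to frames where a bin sees only
one leaflet. Bins lacking either leaflet are undefined (NaN). When a map is
anchored on a protein, frames are re-centred in xy on the anchor selection
and beads wrapped by minimum image; the synthetic bilayer needs no anchor.

The deformation summary takes bulk width as the mean over defined bins at
radial distance ≥ 30 Å from the chosen centre (a 14 nm box leaves an ample
bulk annulus), and the minimum width as the smallest defined bin inside that
radius; it reports bulk, minimum, reduction = bulk − minimum, and
reduction % — both the "reduction amount" and the "reduced width" readings of
a thinning statement are therefore directly checkable. Note the minimum over
noisy bins is biased slightly low (extreme-value bias of order
σ_noise/√(samples per bin)), which is why depth recovery is validated at the
5% level while bulk recovery holds at 2%.

## Cavity and tunnel detection

A clearance grid stores, at every node of a regular grid over the padded
bounding box (default spacing 0.5 Å, padding 3 Å), the exact distance to the
nearest atom *surface*: one KD-tree per distinct van der Waals radius, taking
the minimum of (centre distance − radius) across radius groups. This is exact
for arbitrary mixed radii, unlike nearest-centre approximations.

Tunnels use a regular-grid maximin formulation rather than the Voronoi
construction of classical channel-finding tools: it is deterministic,
trivially testable against brute force, and its fidelity is controlled by a
single spacing parameter (the phantom tests verify |bottleneck − true bore|
≤ spacing for spacings 1.0/0.5/0.25 Å). The probe-accessible set is
{clearance ≥ probe radius} (default probe 1.4 Å, a water); moves use
26-connectivity, entering a voxel only if it is accessible, with true
Euclidean inter-node path lengths. The maximin bottleneck is computed exactly
by bisection over the sorted node clearances with connected-component
labelling; the reported path is then the shortest path (Dijkstra on the
above-threshold set), so among widest paths a shortest one is returned, and
identical inputs give identical paths. Seeds are snapped to the widest node
within 3 Å when their own node is tighter than the probe; if no such node
fits the probe, `find_tunnel` returns None and `path_exists` returns False
(the probe cannot fit), while a seed outside the grid raises. Hydrogens are
included when present; CG beads use their bead radii.

## Activity pipeline

Wells are fit by ordinary least squares in closed form (the batch path uses
the identical normal-equation arithmetic in one vectorized pass, and the two
are asserted equal in tests). The pipeline is: per-well slope → subtract the
mean −cofactor slope of the *same condition* (zero with a warning when a
condition lacks background wells) → mean over each replicate's wells →
divide by the matching reference replicate's mean → mean ± SEM across
replicates. Replicate-matched normalization makes the reference exactly 1.0
with SEM 0 by construction. SEM is sd(n−1)/√n; with one replicate the SEM is
undefined and reported as missing, never 0. Negative normalized activities
are reported as-is. The replicate structure "n biological replicates of m
wells" treats wells as technical replicates; error bars are between
biological replicates.

pKa traces from an external per-frame predictor are aggregated the same way:
each replicate is reduced to its time mean (optional equilibration skip,
default 0), then mean ± SEM across replicates. The per-frame predictor itself
is outside this package's scope and is injected as data.

## Synthetic generators: what they emulate, and what they do not

All generators draw from one `numpy.random.default_rng(seed)` stream, are
bit-reproducible, and emit a JSON-serializable truth sidecar.

- **Gating trajectory**: a symmetric 2-state Markov chain (switch probability
  0.01/frame, starting open) drives both the gate distance
  (N(μ_state, σ); defaults μ_open 11 Å, μ_closed 5 Å, σ 0.5 Å) and the
  in-sphere water count (Poisson(λ_state); defaults λ_open 8,
  λ_closed 1). Waters drawn for a frame are placed strictly inside the 4 Å
  sphere; a parked pool and 200 decoy waters sit strictly outside
  (5–15 Å), so counting is tested against non-trivial exclusion and the
  sphere count reproduces the truth exactly. The gate pair is symmetric about
  the origin, so the sphere centre is exactly the origin every frame. This
  emulates the open/closed statistics of a gating side chain — not its
  physics: there is no protein, no excluded volume, and distance and count
  are conditionally independent given the state.
- **Funnel bilayer**: PO4 beads on an 8 Å square lattice (≈0.64 nm² per
  lipid) in a 14 nm box; leaflet surfaces at ±bulk/2 ∓ (depth/2)·exp(−r²/2σ_r²)
  with per-frame Gaussian z noise (2 Å). Defaults (bulk 38 Å, depth 17 Å,
  σ_r 10 Å, 100 frames) produce a 3.8 nm membrane thinned by 1.7 nm at the
  centre. Beads do not diffuse laterally and carry no lipid chemistry; the
  generator tests geometry recovery, not membrane mechanics.
- **Tunnel phantom**: atoms of radius 1.7 Å packed on a cubic lattice
  (spacing = atom radius, leaving no probe-sized voids in the wall) in a
  slab, excluded from a cylinder of radius bore + atom radius about z, so the
  accessible bore radius equals the nominal bore up to a packing protrusion
  ≤ half the lattice spacing (recorded in the truth sidecar).
- **Plate**: 31 time points over 0–60 min (1 h at 2-min intervals); +cofactor
  wells grow at background + activity·slope_wt (defaults slope_wt 2, background
  0.2, intercept 60, in polarization units and minutes), −cofactor wells at
  background alone; independent Gaussian read noise per point (default
  2 units). Defaults use 2 biological replicates of 4 wells, the assay's
  replicate structure. An optional `replicate_sd` adds per-(condition,
  replicate) activity scatter: with only well-level noise, the background
  estimate is shared across replicates and the between-replicate SEM
  understates the total error, so the confidence-interval coverage property
  is meaningful only when replicate-level variability dominates — the
  coverage study therefore runs with `replicate_sd` 0.05 and 40 replicates,
  where ±1.96·SEM covers truth at the ≈95% level expected from the
  t-distribution (t-based intervals at n = 2 would cover only ≈70%, a
  property of small-sample statistics, not of the pipeline).

Because the generators are statistical emulations, passing tests demonstrate
that the analyses recover programmed parameters under the stated noise
models — they do not validate force fields, sampling convergence, or the
biology of any particular protein.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale by choice: gating
recovery on 4000 frames (state classification at exactly 6σ mean separation,
expected accuracy ≥99%), bilayer recovery on 100 frames × 578 beads, tunnel
convergence down to 0.25 Å spacing on a ~600-atom phantom, and 200 synthetic
plates for interval coverage. Oracle comparisons are exact for integer counts
and ≤1e-9 Å for distances/clearances; rigid-motion invariance is asserted to
1e-9. Collinearity in plane definitions and degenerate Kabsch inputs are
rejected with the offending frame named.

## Known limitations

- Binary trajectory formats (XTC/DCD) and mmCIF are out of scope; external
  readers can feed `Trajectory` arrays directly.
- The grid tunnel search reports one widest (then shortest) path, not a
  clustered ensemble of tunnels, and has no time-resolved mode.
- Density grids are count-based; conversion to physical concentration is left
  to the caller (divide by voxel volume).
- Leaflet assignment assumes a single bilayer roughly normal to z; strongly
  curved or vesicular membranes are not handled.
- The width-map minimum is an extreme statistic and inherits a small negative
  noise bias; report it together with the bin counts when σ_noise is large.
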