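# memgate

Analysis toolkit for membrane-protein structures and molecular-dynamics
trajectories, built around the computations used to characterise a
substrate-gating acyltransferase embedded in the ER membrane: gating-residue
geometry, local water occupancy, time-averaged density grids, bilayer-thinning
maps, probe-accessible tunnel detection, and the kinetic-slope normalization
pipeline of a fluorescence-polarization activity assay. Every analysis is
exercisable end-to-end on seeded synthetic data with exported ground truth.

## Who this is for

Structural biologists and simulators who need small, testable building blocks
for questions like: *does this side chain gate the substrate tunnel?* (atom-pair
distance + waters inside a moving sphere), *does the protein thin the bilayer
toward its reaction centre?* (leaflet-separation maps), *is there a continuous
probe-accessible cavity through the protein, and how wide is its bottleneck?*
(grid maximin search), and *what is a mutant's activity relative to wild type,
with honest error bars?* (slope → background → normalization → mean ± SEM).

## The core computations

- **Gate distance** — per-frame Euclidean distance between two selected atoms
  (e.g. the gating tryptophan's Cη2 and a facing phenylalanine's Cα), with
  optional minimum-image treatment for orthorhombic boxes.
- **Moving-sphere water count** — number of water oxygens within a sphere of
  radius *r* (default 4 Å) centred on the per-frame centre of geometry of the
  gate residues' Cα atoms; the boundary is closed (≤ *r*).
- **Side-chain plane angle** — signed angle θ = arcsin(v̂·n̂) ∈ [−90°, +90°]
  of a Cα→Cγ vector against the plane through three backbone Cα atoms, with the
  right-hand-rule normal fixing the sign.
- **Time-averaged density** — each frame is optionally Kabsch-superposed onto
  frame 0, selected atoms are binned into voxels, and counts are divided by the
  number of frames; the counting identity
  `sum(values)·n_frames + spill = n_frames·n_atoms` holds exactly. Grids are
  serialized as OpenDX.
- **Bilayer width map** — phosphate beads are split into leaflets about the
  instantaneous midplane; per xy-bin, width = mean z(upper) − mean z(lower).
  A deformation summary contrasts the bulk width (bins ≥ 30 Å from the centre)
  with the thinnest nearby bin and reports bulk, minimum, reduction and
  reduction % in nm.
- **Tunnel detection** — a clearance grid stores each node's exact distance to
  the nearest van der Waals surface; the widest (maximin-bottleneck) path from
  a seed to the surface, or between two points, is found by bisecting over node
  clearances with 26-connected component labelling, then returning the shortest
  path within the above-threshold set. The bottleneck radius is the tunnel's
  narrowest clearance.
- **Activity pipeline** — per-well OLS slopes; background subtraction by each
  condition's own −cofactor wells; replicate-matched normalization to the
  reference (wild type ≡ 1.0); mean ± SEM (sd with n−1, over √n) across
  replicates.

## Worked example

Generate a funnel-deformed coarse-grained bilayer (bulk width 3.8 nm, 1.7 nm
deep Gaussian funnel, 14 nm box, 100 frames) and quantify the deformation:

```sh
memgate synth bilayer --seed 1 --out bl
memgate bilayer-map bl/bilayer.xyzt --phosphates "name PO4" --bin 2.0 --out-prefix bl/out
```

```
{
 "bulk_width_nm": 3.8015718965081966,
 "min_width_nm": 2.081679746,
 "reduction_nm": 1.7198921505081968,
 "reduction_pct": 45.24160524460802,
 ...
}
```

The map recovers the programmed bulk width (3.80 vs 3.8 nm) and funnel depth
(1.72 vs 1.7 nm): the membrane is locally thinned by ~45% at the funnel centre.

Tunnel detection on a phantom with a 3 Å bore:

```sh
memgate synth phantom --seed 0 --out ph
memgate tunnel ph/phantom.pdb --seed 0,0,0 --probe 1.4 --spacing 0.5
# bottleneck 3.11 A, length 8.9 A, 18 nodes
memgate connectivity ph/phantom.pdb --a 0,0,5 --b 0,0,-5
# connected (bottleneck 3.11 A)
```

The bottleneck matches the analytic bore radius to within one grid spacing.
An activity plate with programmed relative activities {WT 1.0, mutA 0.5,
mutB 0.0}:

```sh
memgate synth plate --seed 2 --out pl
memgate assay pl/plate.csv
```

```
condition  mean_activity  sem          n_replicates
WT         1              0            2
mutA       0.504591       0.000850618  2
mutB       0.00933848     0.0054798    2
```

## Library layout

| module | contents |
| --- | --- |
| `memgate.structio` | PDB/GRO/xyzt/OpenDX/CSV I/O, selection language |
| `memgate.geometry` | distances, sphere counts, plane angles, Kabsch, rolling mean |
| `memgate.fields` | density grids, leaflet assignment, width maps, summaries |
| `memgate.cavities` | clearance grids, tunnels, connectivity |
| `memgate.assaystats` | slope fits, activity pipeline, replicate mean ± SEM |
| `memgate.synthgen` | seeded generators with truth sidecars |

See `docs/methods.md` for the models, conventions and numerical choices.
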