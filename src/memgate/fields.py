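"""Time-averaged density grids and bilayer-width deformation maps.

``average_density`` bins selected atoms of every (optionally superposed)
frame into a regular voxel grid and divides by the number of frames, so a
voxel value of 1.0 means "occupied by one selected atom in every frame" —
the construction behind time-averaged solvent or lipid-phosphate maps.

The bilayer mapping routines measure membrane deformation: phosphate
beads/atoms are split into leaflets about the instantaneous midplane, the
time-mean z of each leaflet is accumulated on an xy grid, and the local
bilayer width is the upper-minus-lower surface separation. A summary then
contrasts the width far from a chosen centre ("bulk") with the thinnest
bin near it, the standard way to quantify protein-induced thinning.

Lengths are Å except in :class:`DeformationSummary`, which reports nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import apply_transform, superpose_kabsch
from .structio import DensityGrid, Trajectory

__all__ = [
    "BilayerMap",
    "DeformationSummary",
    "average_density",
    "assign_leaflets",
    "bilayer_width_map",
    "deformation_summary",
    "radial_width_profile",
]


@dataclass
class BilayerMap:
    """2D binned map of local bilayer width (Å) with per-bin sample counts.

    ``width`` is NaN wherever either leaflet contributed no samples;
    ``counts`` is the total number of bead observations per bin.
    """

    bin_size: float
    origin_xy: np.ndarray
    width: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.origin_xy = np.asarray(self.origin_xy, dtype=float).reshape(2)
        self.width = np.asarray(self.width, dtype=float)
        self.counts = np.asarray(self.counts)
        defined = np.isfinite(self.width)
        if defined.any() and not (self.width[defined] > 0).all():
            raise ValueError("defined bilayer widths must be positive")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.width)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.width.shape
        x = self.origin_xy[0] + (np.arange(nx) + 0.5) * self.bin_size
        y = self.origin_xy[1] + (np.arange(ny) + 0.5) * self.bin_size
        return x, y


@dataclass
class DeformationSummary:
    """Bulk vs minimum bilayer width, in nm; min_location in Å."""

    bulk_width: float
    min_width: float
    reduction: float
    reduction_pct: float
    min_location: np.ndarray

    def __post_init__(self) -> None:
        if not (0 < self.min_width <= self.bulk_width):
            raise ValueError("require 0 < min_width <= bulk_width")
        if abs(self.reduction_pct - 100.0 * self.reduction / self.bulk_width) > 1e-9:
            raise ValueError("reduction_pct inconsistent with reduction/bulk_width")


# ---------------------------------------------------------------------------
# density averaging
# ---------------------------------------------------------------------------

def average_density(
    traj: Trajectory,
    target_sel: str,
    align_sel: str | None = None,
    spacing: float | np.ndarray = 1.0,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> DensityGrid:
    """Time-averaged occupancy grid of the selected atoms.

    Parameters
    ----------
    align_sel : optional selection of ≥3 atoms; each frame is superposed
        onto frame 0 on these atoms (Kabsch) before binning.
    spacing : voxel edge length(s), Å.
    extent : optional (origin, lengths) pair fixing the grid; by default
        the grid covers the bounding box of the target atoms across all
        frames, padded so a static atom sits at a voxel centre.

    Atoms falling outside the grid are dropped and counted in the returned
    grid's ``spill`` attribute, so that
    ``values.sum() * n_frames + spill == n_frames * n_target`` exactly.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    target_idx = traj.select(target_sel)
    coords = traj.frames[:, target_idx, :].copy()

    if align_sel is not None:
        align_idx = traj.select(align_sel)
        if len(align_idx) < 3:
            raise ValueError("alignment selection must resolve to >= 3 atoms")
        ref = traj.frames[0, align_idx, :]
        for k in range(traj.n_frames):
            rot, trans, _ = superpose_kabsch(traj.frames[k, align_idx, :], ref)
            coords[k] = apply_transform(coords[k], rot, trans)

    if extent is None:
        lo = coords.reshape(-1, 3).min(axis=0) - spacing / 2
        hi = coords.reshape(-1, 3).max(axis=0) + spacing / 2
        dims = np.maximum(np.ceil((hi - lo) / spacing - 1e-9).astype(int), 1)
        origin = lo
    else:
        origin = np.asarray(extent[0], dtype=float).reshape(3)
        lengths = np.asarray(extent[1], dtype=float).reshape(3)
        dims = np.maximum(np.ceil(lengths / spacing - 1e-9).astype(int), 1)

    counts = np.zeros(tuple(dims), dtype=float)
    spill = 0
    for k in range(traj.n_frames):
        idx = np.floor((coords[k] - origin) / spacing).astype(int)
        inside = ((idx >= 0) & (idx < dims)).all(axis=1)
        spill += int((~inside).sum())
        ii = idx[inside]
        np.add.at(counts, (ii[:, 0], ii[:, 1], ii[:, 2]), 1.0)

    if counts.sum() == 0 and len(target_idx) > 0:
        warnings.warn("all target atoms fell outside the density grid", stacklevel=2)
    values = counts / traj.n_frames
    return DensityGrid(
        origin, spacing, tuple(int(d) for d in dims), values,
        n_frames=traj.n_frames, spill=spill,
    )


# ---------------------------------------------------------------------------
# leaflets and width maps
# ---------------------------------------------------------------------------

def assign_leaflets(frame_coords: np.ndarray, phosphate_indices: np.ndarray) -> np.ndarray:
    """Label phosphate beads "upper"/"lower" about the instantaneous midplane.

    The midplane is the mean phosphate z of the frame. Raises if the beads
    are essentially coplanar at the midplane (not a bilayer).
    """
    phosphate_indices = np.asarray(phosphate_indices, dtype=int)
    if len(phosphate_indices) < 2:
        raise ValueError("need at least 2 phosphate-like beads")
    z = np.asarray(frame_coords)[phosphate_indices, 2]
    mid = z.mean()
    dz = z - mid
    if (np.abs(dz) < 0.1).mean() > 0.9:
        raise ValueError(
            "over 90% of beads lie within 0.1 Å of the midplane; "
            "input does not look like a bilayer"
        )
    return np.where(dz >= 0, "upper", "lower")


def bilayer_width_map(
    traj: Trajectory,
    phosphate_sel: str,
    bin_size: float = 2.0,
    align_sel: str | None = None,
) -> BilayerMap:
    """Time-averaged leaflet-separation map on an xy grid.

    Per bin, width = (time-mean z of upper-leaflet beads) − (time-mean z of
    lower-leaflet beads); bins lacking either leaflet are NaN. When
    ``align_sel`` is given, each frame is translated so that selection's
    centroid sits at the origin in xy (anchoring the map on e.g. a protein)
    and beads are wrapped into the box by minimum image.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    pidx = traj.select(phosphate_sel)
    if len(pidx) == 0:
        raise ValueError(f"phosphate selection {phosphate_sel!r} is empty")

    anchor_idx = traj.select(align_sel) if align_sel is not None else None

    # collect per-frame bead xy(z) after optional re-centering
    all_xy = []
    all_z = []
    all_up = []
    for k in range(traj.n_frames):
        coords = traj.frames[k]
        beads = coords[pidx].copy()
        if anchor_idx is not None and len(anchor_idx) > 0:
            shift = coords[anchor_idx].mean(axis=0)
            beads[:, 0] -= shift[0]
            beads[:, 1] -= shift[1]
            if traj.boxes is not None:
                box_xy = traj.boxes[k][:2]
                beads[:, :2] -= box_xy * np.round(beads[:, :2] / box_xy)
        labels = assign_leaflets(coords, pidx)
        all_xy.append(beads[:, :2])
        all_z.append(coords[pidx, 2])
        all_up.append(labels == "upper")
    xy = np.concatenate(all_xy)
    z = np.concatenate(all_z)
    upper = np.concatenate(all_up)

    lo = xy.min(axis=0)
    origin_xy = lo - bin_size / 2
    dims = np.maximum(
        np.ceil((xy.max(axis=0) + bin_size / 2 - origin_xy) / bin_size - 1e-9).astype(int),
        1,
    )
    ix = np.clip(((xy - origin_xy) / bin_size).astype(int), 0, dims - 1)

    zsum_up = np.zeros(tuple(dims))
    n_up = np.zeros(tuple(dims))
    zsum_lo = np.zeros(tuple(dims))
    n_lo = np.zeros(tuple(dims))
    np.add.at(zsum_up, (ix[upper, 0], ix[upper, 1]), z[upper])
    np.add.at(n_up, (ix[upper, 0], ix[upper, 1]), 1.0)
    np.add.at(zsum_lo, (ix[~upper, 0], ix[~upper, 1]), z[~upper])
    np.add.at(n_lo, (ix[~upper, 0], ix[~upper, 1]), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        width = zsum_up / n_up - zsum_lo / n_lo
    width[(n_up == 0) | (n_lo == 0)] = np.nan
    counts = (n_up + n_lo).astype(int)
    return BilayerMap(bin_size, origin_xy, width, counts)


def deformation_summary(
    bmap: BilayerMap,
    center_xy: np.ndarray | None = None,
    bulk_min_radius: float = 30.0,
) -> DeformationSummary:
    """Contrast the thinnest bin near ``center_xy`` with the bulk width.

    bulk_width = mean width over defined bins at radial distance
    ≥ ``bulk_min_radius`` from the centre; min_width = smallest defined
    width within that radius. Reported in nm (min_location stays in Å).
    """
    cx, cy = bmap.bin_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    if center_xy is None:
        center_xy = np.array([cx.mean(), cy.mean()])
    center_xy = np.asarray(center_xy, dtype=float).reshape(2)
    r = np.hypot(gx - center_xy[0], gy - center_xy[1])
    defined = bmap.defined
    bulk_mask = defined & (r >= bulk_min_radius)
    near_mask = defined & (r < bulk_min_radius)
    if not bulk_mask.any():
        raise ValueError(
            "no defined bins beyond bulk_min_radius; use a larger box or a "
            "smaller radius"
        )
    if not near_mask.any():
        raise ValueError("no defined bins within bulk_min_radius of the centre")
    bulk_width_A = float(bmap.width[bulk_mask].mean())
    flat = np.where(near_mask, bmap.width, np.inf)
    min_idx = np.unravel_index(np.argmin(flat), flat.shape)
    min_width_A = float(bmap.width[min_idx])
    min_location = np.array([gx[min_idx], gy[min_idx]])
    bulk_nm = bulk_width_A / 10.0
    min_nm = min_width_A / 10.0
    reduction = bulk_nm - min_nm
    return DeformationSummary(
        bulk_width=bulk_nm,
        min_width=min_nm,
        reduction=reduction,
        reduction_pct=100.0 * reduction / bulk_nm,
        min_location=min_location,
    )


def radial_width_profile(
    bmap: BilayerMap,
    center_xy: np.ndarray | None = None,
    dr: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean width (Å) in annuli of thickness ``dr`` around the centre."""
    cx, cy = bmap.bin_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    if center_xy is None:
        center_xy = np.array([cx.mean(), cy.mean()])
    r = np.hypot(gx - center_xy[0], gy - center_xy[1])
    defined = bmap.defined
    rmax = r[defined].max()
    edges = np.arange(0.0, rmax + dr, dr)
    radii = []
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = defined & (r >= lo) & (r < hi)
        if mask.any():
            radii.append(0.5 * (lo + hi))
            means.append(float(bmap.width[mask].mean()))
    return np.array(radii), np.array(means)
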