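"""Seeded synthetic-data generators with exported ground truth.

Each generator emulates the statistical/geometric structure one of the
analyses assumes, at desk scale, and returns a machine-readable ``truth``
dict alongside the data so parameter-recovery tests can compare against
what was programmed:

* a two-state (open/closed) gating residue pair whose inter-atom distance
  is Gaussian about a state-dependent mean and whose probe sphere holds a
  Poisson number of waters with a state-dependent rate;
* a coarse-grained bilayer whose leaflets carry a radially symmetric
  Gaussian funnel deformation of programmable depth;
* a solid phantom slab pierced by a straight cylindrical bore of known
  accessible radius;
* an activity plate with linear signal growth, cofactor-free background
  wells, replicate-level biological scatter and per-point read noise.

All generators draw from a single ``numpy.random.default_rng(seed)``
stream and are bit-reproducible for a fixed seed and parameter set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .structio import AtomRecord, PlateTable, Structure, Trajectory

__all__ = [
    "GatingParams",
    "FunnelParams",
    "gen_gating_trajectory",
    "gen_funnel_bilayer",
    "gen_tunnel_phantom",
    "gen_plate",
    "save_truth",
]


def save_truth(truth: dict, path: str) -> None:
    """Write a generator's ground-truth sidecar as JSON."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_default)


# ---------------------------------------------------------------------------
# gating trajectory
# ---------------------------------------------------------------------------

@dataclass
class GatingParams:
    """Two-state gate: distances N(μ_state, σ), sphere waters Poisson(λ_state).

    The hidden state follows a symmetric 2-state Markov chain switching
    with probability ``p_switch`` per frame, starting open. Defaults place
    the open and closed distance means 12σ apart, far beyond the 6σ
    separation at which thresholding is expected to recover ≥99% of states.
    """

    mu_open: float = 11.0
    mu_closed: float = 5.0
    sigma: float = 0.5
    lambda_open: float = 8.0
    lambda_closed: float = 1.0
    p_switch: float = 0.01
    n_frames: int = 2000
    seed: int = 0
    sphere_radius: float = 4.0
    n_decoys: int = 200
    dt_ns: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.p_switch < 1):
            raise ValueError("p_switch must be in (0, 1)")
        if self.mu_open == self.mu_closed:
            raise ValueError("state means must differ")
        for name in ("mu_open", "mu_closed", "sigma", "lambda_open",
                     "lambda_closed", "sphere_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _marker_atoms() -> list[AtomRecord]:
    c = 1.70
    return [
        AtomRecord(1, "CA", "MET", 334, "A", "C", c),
        AtomRecord(2, "CA", "TRP", 335, "A", "C", c),
        AtomRecord(3, "CH2", "TRP", 335, "A", "C", c),
        AtomRecord(4, "CA", "ASP", 339, "A", "C", c),
        AtomRecord(5, "CG", "ASP", 339, "A", "C", c),
        AtomRecord(6, "CA", "LEU", 346, "A", "C", c),
        AtomRecord(7, "CA", "PHE", 372, "A", "C", c),
    ]


# static scaffold coordinates (plane triple is non-collinear by construction)
_STATIC = {
    0: (0.0, 8.0, 0.0),   # Met334 CA
    3: (0.0, 8.0, 2.0),   # Asp339 CA
    4: (0.0, 9.0, 3.0),   # Asp339 CG
    5: (2.0, 8.0, 0.0),   # Leu346 CA
}


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction * r[:, None]


def _uniform_shell(rng: np.random.Generator, n: int, r_lo: float, r_hi: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = (r_lo**3 + (r_hi**3 - r_lo**3) * rng.random(n)) ** (1.0 / 3.0)
    return direction * r[:, None]


def gen_gating_trajectory(p: GatingParams) -> tuple[Trajectory, dict]:
    """Two-state gating trajectory plus per-frame ground truth.

    The gate pair sits on the x axis, symmetric about the origin, so the
    centre of geometry of the two Cα marker atoms is exactly the origin in
    every frame; waters drawn for the frame are placed strictly inside the
    gate sphere and every other water (parked pool and decoys) strictly
    outside, so a sphere count reproduces the truth exactly.
    """
    rng = np.random.default_rng(p.seed)
    lam_max = max(p.lambda_open, p.lambda_closed)
    pool = int(np.ceil(lam_max + 10.0 * np.sqrt(lam_max) + 10))

    states = np.empty(p.n_frames, dtype=int)  # 1 = open, 0 = closed
    states[0] = 1
    switches = rng.random(p.n_frames - 1) < p.p_switch if p.n_frames > 1 else []
    for t in range(1, p.n_frames):
        states[t] = states[t - 1] ^ int(switches[t - 1])

    mu = np.where(states == 1, p.mu_open, p.mu_closed)
    lam = np.where(states == 1, p.lambda_open, p.lambda_closed)
    distances = rng.normal(mu, p.sigma)
    counts = np.minimum(rng.poisson(lam), pool)

    atoms = _marker_atoms()
    n_water = pool + p.n_decoys
    for i in range(n_water):
        atoms.append(
            AtomRecord(8 + i, "OW", "HOH", 1000 + i, "W", "O", 1.52)
        )
    n_atoms = len(atoms)

    frames = np.empty((p.n_frames, n_atoms, 3))
    for t in range(p.n_frames):
        d = distances[t]
        half = d / 2.0
        frames[t, 0] = _STATIC[0]
        frames[t, 1] = (-half, 0.0, 0.0)   # Trp335 CA
        frames[t, 2] = (-half, 0.0, 0.0)   # Trp335 CH2 (gate-distance atom)
        frames[t, 3] = _STATIC[3]
        frames[t, 4] = _STATIC[4]
        frames[t, 5] = _STATIC[5]
        frames[t, 6] = (half, 0.0, 0.0)    # Phe372 CA
        k = counts[t]
        inside = _uniform_ball(rng, k, p.sphere_radius * 0.999)
        parked = _uniform_shell(
            rng, pool - k, p.sphere_radius + 1.0, p.sphere_radius + 11.0
        )
        decoys = _uniform_shell(
            rng, p.n_decoys, p.sphere_radius + 1.0, p.sphere_radius + 11.0
        )
        frames[t, 7 : 7 + k] = inside
        frames[t, 7 + k : 7 + pool] = parked
        frames[t, 7 + pool :] = decoys

    times = np.arange(p.n_frames) * p.dt_ns
    top = Structure(atoms, frames[0])
    traj = Trajectory(top, frames, times=times)
    truth = {
        "kind": "gating",
        "params": asdict(p),
        "states": states.tolist(),
        "distances": distances.tolist(),
        "water_counts": counts.tolist(),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# funnel bilayer
# ---------------------------------------------------------------------------

@dataclass
class FunnelParams:
    """Bilayer with a radially symmetric Gaussian funnel in both leaflets.

    Leaflet surfaces sit at ±bulk_width/2 ∓ (depth/2)·exp(−r²/2σ_r²) plus
    per-frame Gaussian z noise, so the analytic local width is
    bulk_width − depth·exp(−r²/2σ_r²). Defaults reproduce a 3.8 nm bulk
    membrane thinning by 1.7 nm at the funnel centre inside a 14 nm box,
    with phosphate beads on an 8 Å lattice (≈0.64 nm² per lipid).
    """

    bulk_width: float = 38.0
    depth: float = 17.0
    sigma_r: float = 10.0
    box_xy: float = 140.0
    bead_spacing: float = 8.0
    z_noise: float = 2.0
    n_frames: int = 100
    seed: int = 0
    dt_ns: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.depth < self.bulk_width):
            raise ValueError("require 0 < depth < bulk_width")
        if self.bead_spacing <= 0 or self.box_xy <= 0 or self.sigma_r <= 0:
            raise ValueError("bead_spacing, box_xy and sigma_r must be positive")

    def analytic_width(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.bulk_width - self.depth * np.exp(-(r**2) / (2 * self.sigma_r**2))


def gen_funnel_bilayer(p: FunnelParams) -> tuple[Trajectory, dict]:
    """Funnel-deformed bilayer trajectory plus leaflet/width ground truth."""
    rng = np.random.default_rng(p.seed)
    n_side = int(p.box_xy // p.bead_spacing)
    offsets = (np.arange(n_side) - (n_side - 1) / 2.0) * p.bead_spacing
    gx, gy = np.meshgrid(offsets, offsets, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    m = xy.shape[0]
    r = np.hypot(xy[:, 0], xy[:, 1])
    bump = (p.depth / 2.0) * np.exp(-(r**2) / (2 * p.sigma_r**2))
    z_up = p.bulk_width / 2.0 - bump
    z_lo = -p.bulk_width / 2.0 + bump

    atoms = []
    for i in range(m):
        atoms.append(AtomRecord(i + 1, "PO4", "POPC", i + 1, "U", "P", 2.64))
    for i in range(m):
        atoms.append(AtomRecord(m + i + 1, "PO4", "POPC", m + i + 1, "L", "P", 2.64))

    frames = np.empty((p.n_frames, 2 * m, 3))
    for t in range(p.n_frames):
        frames[t, :m, :2] = xy
        frames[t, m:, :2] = xy
        frames[t, :m, 2] = z_up + rng.normal(0.0, p.z_noise, m) if p.z_noise else z_up
        frames[t, m:, 2] = z_lo + rng.normal(0.0, p.z_noise, m) if p.z_noise else z_lo

    boxes = np.tile([p.box_xy, p.box_xy, p.bulk_width + 60.0], (p.n_frames, 1))
    times = np.arange(p.n_frames) * p.dt_ns
    top = Structure(atoms, frames[0], boxes[0])
    traj = Trajectory(top, frames, boxes=boxes, times=times)
    truth = {
        "kind": "funnel_bilayer",
        "params": asdict(p),
        "leaflets": ["upper"] * m + ["lower"] * m,
        "bulk_width": p.bulk_width,
        "depth": p.depth,
        "sigma_r": p.sigma_r,
        "min_width": p.bulk_width - p.depth,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# tunnel phantom
# ---------------------------------------------------------------------------

def gen_tunnel_phantom(
    bore_radius: float,
    length: float = 12.0,
    wall_thickness: float = 5.0,
    atom_radius: float = 1.7,
) -> tuple[Structure, dict]:
    """Solid slab with a straight cylindrical bore along z.

    Atom centres are packed on a cubic lattice (spacing = atom_radius, so
    the wall has no probe-sized voids) and excluded from a cylinder of
    radius ``bore_radius + atom_radius`` around the z axis, leaving an
    accessible bore of radius ``bore_radius`` up to a packing protrusion
    of at most half the lattice spacing (reported in the truth sidecar).
    """
    if bore_radius <= 0:
        raise ValueError("bore_radius must be positive")
    spacing = atom_radius
    r_inner = bore_radius + atom_radius
    r_outer = r_inner + wall_thickness
    ax = np.arange(-r_outer, r_outer + spacing / 2, spacing)
    az = np.arange(-length / 2, length / 2 + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r_xy = np.hypot(pts[:, 0], pts[:, 1])
    keep = (r_xy >= r_inner) & (r_xy <= r_outer)
    pts = pts[keep]
    atoms = [
        AtomRecord(i + 1, "C", "PHN", i + 1, "X", "C", atom_radius)
        for i in range(len(pts))
    ]
    truth = {
        "kind": "tunnel_phantom",
        "bore_radius": bore_radius,
        "accessible_radius": bore_radius,
        "radius_tolerance": spacing / 2.0,
        "length": length,
        "wall_thickness": wall_thickness,
        "atom_radius": atom_radius,
    }
    return Structure(atoms, pts), truth


# ---------------------------------------------------------------------------
# activity plates
# ---------------------------------------------------------------------------

def gen_plate(
    activities: dict[str, float],
    slope_wt: float = 2.0,
    noise_sd: float = 2.0,
    n_replicates: int = 2,
    wells_per_replicate: int = 4,
    seed: int = 0,
    replicate_sd: float = 0.0,
    background_slope: float = 0.2,
    intercept: float = 60.0,
    reference: str = "WT",
) -> tuple[PlateTable, dict]:
    """Synthetic plate: linear wells, background wells, replicate scatter.

    Per condition and replicate, ``wells_per_replicate`` +cofactor wells
    grow at ``background_slope + activity·slope_wt`` and as many −cofactor
    wells at the background slope alone; signals get independent Gaussian
    read noise (``noise_sd``) at each of 31 time points over 0–60 min.
    ``replicate_sd`` adds a per-(condition, replicate) offset to the
    activity, modelling biological replicate-to-replicate variability.
    """
    if reference not in activities:
        raise ValueError(f"reference condition {reference!r} missing from activities")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, 61.0, 2.0)  # 31 points, 1 h at 2-min intervals
    nt = times.size
    well_ids, conds, cofs, reps, slopes = [], [], [], [], []
    for cond in activities:
        for rep in range(1, n_replicates + 1):
            act = activities[cond]
            if replicate_sd:
                act = act + rng.normal(0.0, replicate_sd)
            for cof, slope in (
                ("+PalmCoA", background_slope + act * slope_wt),
                ("-PalmCoA", background_slope),
            ):
                for w in range(1, wells_per_replicate + 1):
                    well_ids.append(f"{cond}_{cof[0]}_{rep}_{w}")
                    conds.append(cond)
                    cofs.append(cof)
                    reps.append(rep)
                    slopes.append(slope)
    n_wells = len(well_ids)
    signal = intercept + np.outer(slopes, times)
    if noise_sd:
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    data = pd.DataFrame(
        {
            "well": np.repeat(well_ids, nt),
            "condition": np.repeat(conds, nt),
            "cofactor": np.repeat(cofs, nt),
            "replicate": np.repeat(reps, nt),
            "time_min": np.tile(times, n_wells),
            "signal": signal.ravel(),
        }
    )
    truth = {
        "kind": "plate",
        "activities": dict(activities),
        "slope_wt": slope_wt,
        "noise_sd": noise_sd,
        "replicate_sd": replicate_sd,
        "n_replicates": n_replicates,
        "wells_per_replicate": wells_per_replicate,
    }
    return PlateTable(data), truth
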