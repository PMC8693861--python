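"""Per-frame geometric metrics for trajectories.

The metrics here quantify a gating side chain at the mouth of a substrate
tunnel: the atom-pair distance between the gate residues, the number of
waters inside a sphere that rides on the gate's centre of geometry, and the
signed angle of a side-chain vector against a reference plane. A Kabsch
superposition routine supports frame alignment prior to density averaging,
and a centred rolling mean smooths the raw traces.

Every metric returns a :class:`TimeSeries` (times in ns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import mass_for
from .structio import Trajectory

__all__ = [
    "TimeSeries",
    "SphereSpec",
    "PlaneAngleSpec",
    "pair_distance_series",
    "com_distance_series",
    "moving_sphere_count",
    "vector_plane_angle_series",
    "rolling_mean",
    "superpose_kabsch",
    "apply_transform",
    "WATER_OXYGEN_SELECTION",
]

# water oxygens under common naming schemes; override per call if needed
WATER_OXYGEN_SELECTION = "resname HOH SOL TIP3 WAT and name O OW OH2"


@dataclass
class TimeSeries:
    """Paired times (ns) and values with a label and units."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path: str) -> None:
        header = f"time_ns\t{self.label or 'value'}"
        if self.units:
            header += f"_{self.units}"
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter="\t",
            header=header,
            comments="",
        )


@dataclass
class SphereSpec:
    """A probe sphere riding on the centre of geometry of ``center_atoms``."""

    center_atoms: str
    radius: float = 4.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class PlaneAngleSpec:
    """A (tail, head) vector measured against a 3-atom reference plane.

    Each selection must resolve to exactly one atom. The plane normal is
    the right-handed cross product (p2-p1)×(p3-p1), so reordering the plane
    atoms flips the angle's sign.
    """

    vector_atoms: tuple[str, str]
    plane_atoms: tuple[str, str, str]


def _single_index(traj: Trajectory, expr: str, what: str) -> int:
    idx = traj.select(expr)
    if len(idx) != 1:
        hint = (
            "; use com_distance_series for groups"
            if len(idx) > 1 and what.startswith("sel")
            else ""
        )
        raise ValueError(
            f"{what} {expr!r} resolved to {len(idx)} atoms, need exactly 1{hint}"
        )
    return int(idx[0])


def _minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def pair_distance_series(
    traj: Trajectory,
    selA: str,
    selB: str,
    use_minimum_image: bool = False,
) -> TimeSeries:
    """Per-frame Euclidean distance (Å) between two single atoms.

    With ``use_minimum_image`` and an orthorhombic box present, the shortest
    periodic image of the separation vector is used.
    """
    ia = _single_index(traj, selA, "selA")
    ib = _single_index(traj, selB, "selB")
    delta = traj.frames[:, ib, :] - traj.frames[:, ia, :]
    if use_minimum_image and traj.boxes is not None:
        delta = _minimum_image(delta, traj.boxes)
    dist = np.linalg.norm(delta, axis=1)
    return TimeSeries(traj.times, dist, label="pair_distance", units="A")


def com_distance_series(
    traj: Trajectory,
    groupA: str,
    groupB: str,
    weights: str = "geometry",
) -> TimeSeries:
    """Per-frame distance (Å) between two group centres.

    ``weights`` is "geometry" (centre of geometry) or "mass" (centre of
    mass, element masses from the bundled table).
    """
    ia = traj.select(groupA)
    ib = traj.select(groupB)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    if weights == "geometry":
        wa = np.ones(len(ia))
        wb = np.ones(len(ib))
    elif weights == "mass":
        atoms = traj.topology.atoms
        wa = np.array([mass_for(atoms[i].element) for i in ia])
        wb = np.array([mass_for(atoms[i].element) for i in ib])
    else:
        raise ValueError("weights must be 'geometry' or 'mass'")
    ca = np.einsum("tnc,n->tc", traj.frames[:, ia, :], wa) / wa.sum()
    cb = np.einsum("tnc,n->tc", traj.frames[:, ib, :], wb) / wb.sum()
    dist = np.linalg.norm(cb - ca, axis=1)
    return TimeSeries(traj.times, dist, label="com_distance", units="A")


def moving_sphere_count(
    traj: Trajectory,
    sphere: SphereSpec,
    target_sel: str = WATER_OXYGEN_SELECTION,
) -> TimeSeries:
    """Count target atoms within the moving sphere, per frame.

    The sphere centre is recomputed each frame as the centre of geometry of
    ``sphere.center_atoms``; the boundary is closed (distance ≤ radius).
    """
    center_idx = traj.select(sphere.center_atoms)
    if len(center_idx) == 0:
        raise ValueError(f"empty sphere-centre selection {sphere.center_atoms!r}")
    target_idx = traj.select(target_sel)
    if len(target_idx) == 0:
        return TimeSeries(
            traj.times, np.zeros(traj.n_frames, dtype=int), label="sphere_count",
            units="count",
        )
    centers = traj.frames[:, center_idx, :].mean(axis=1)  # T×3
    delta = traj.frames[:, target_idx, :] - centers[:, None, :]
    dist = np.linalg.norm(delta, axis=2)
    counts = (dist <= sphere.radius).sum(axis=1)
    return TimeSeries(traj.times, counts, label="sphere_count", units="count")


def vector_plane_angle_series(traj: Trajectory, spec: PlaneAngleSpec) -> TimeSeries:
    """Signed angle (degrees, [-90, +90]) of a vector against a plane.

    The angle is arcsin of the normalised dot product of the vector with the
    plane's unit normal; it is positive when the vector points to the side
    the normal points to.
    """
    tail = _single_index(traj, spec.vector_atoms[0], "vector tail")
    head = _single_index(traj, spec.vector_atoms[1], "vector head")
    p1, p2, p3 = (
        _single_index(traj, s, "plane atom") for s in spec.plane_atoms
    )
    vec = traj.frames[:, head, :] - traj.frames[:, tail, :]
    e1 = traj.frames[:, p2, :] - traj.frames[:, p1, :]
    e2 = traj.frames[:, p3, :] - traj.frames[:, p1, :]
    normal = np.cross(e1, e2)
    norm_n = np.linalg.norm(normal, axis=1)
    bad = np.flatnonzero(norm_n < 1e-8)
    if bad.size:
        raise ValueError(f"plane atoms collinear at frame {bad[0]}")
    norm_v = np.linalg.norm(vec, axis=1)
    zero_v = np.flatnonzero(norm_v < 1e-12)
    if zero_v.size:
        raise ValueError(f"zero-length vector at frame {zero_v[0]}")
    sin_theta = np.einsum("tc,tc->t", vec, normal) / (norm_v * norm_n)
    angles = np.degrees(np.arcsin(np.clip(sin_theta, -1.0, 1.0)))
    return TimeSeries(traj.times, angles, label="plane_angle", units="deg")


def rolling_mean(ts: TimeSeries, window: int = 50) -> TimeSeries:
    """Centred moving average; edges use the truncated available window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(ts):
        raise ValueError(f"window {window} exceeds series length {len(ts)}")
    smoothed = (
        pd.Series(np.asarray(ts.values, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return TimeSeries(ts.times, smoothed, label=f"{ts.label}_rollmean", units=ts.units)


def superpose_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1; reflections corrected). Apply as ``mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be N×3")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    mc = mobile - mu_m
    rc = reference - mu_r
    h = (mc * w[:, None]).T @ rc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    moved = mc @ rotation.T
    rmsd = float(np.sqrt((w * ((moved - rc) ** 2).sum(axis=1)).sum()))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation
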