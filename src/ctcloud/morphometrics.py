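"""Dimensional, volumetric and deformation analyses of point-cloud models.

Covers: percent-change / index-100 tables between scan-year models,
principal-axis bounding dimensions, voxel-count volume estimation,
cloud-to-cloud nearest-neighbour distance fields (the desk-scale stand-in
for cloud-to-mesh comparison) and point-to-point ICP rigid registration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .reconstruct import INTERIOR, LabeledPointCloud
from .stack_io import VoxelSpacing

__all__ = [
    "MorphReport",
    "ChangeTable",
    "RigidTransform",
    "DistanceField",
    "ICPResult",
    "percent_change",
    "change_table",
    "bounding_dimensions",
    "voxel_volume",
    "cloud_report",
    "nearest_distances",
    "icp_align",
]

QUANTITIES = ("length", "width", "thickness", "volume")


@dataclasses.dataclass(frozen=True)
class MorphReport:
    """Bounding dimensions (µm) and volume (µm³) of one model."""

    length: float
    width: float
    thickness: float
    volume: float
    label: str

    def __post_init__(self) -> None:
        if not (self.length >= self.width >= self.thickness > 0):
            raise ValueError("need length >= width >= thickness > 0")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclasses.dataclass
class ChangeTable:
    """Per-quantity value / index / percent rows against a base model."""

    rows: pd.DataFrame
    base_label: str


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """p -> rotation @ p + translation, in micrometres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(3))
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        """Magnitude of the rotation angle in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclasses.dataclass
class DistanceField:
    """Per-point nearest-neighbour distances (µm) with summary statistics."""

    distances: np.ndarray
    mean: float
    max: float
    percentiles: dict[int, float]

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceField":
        d = np.asarray(d, dtype=np.float64)
        pct = {q: float(np.percentile(d, q)) for q in (50, 90, 95, 99)}
        return cls(distances=d, mean=float(d.mean()), max=float(d.max()), percentiles=pct)


@dataclasses.dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int
    converged: bool
    rms_history: list[float] = dataclasses.field(default_factory=list)


def percent_change(reference: float, current: float) -> float:
    """100 * (current - reference) / reference, rounded to 2 decimals.

    The companion index is ``100 + percent`` (the base model is index 100).
    """
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (current - reference) / reference, 2)


def change_table(reports: list[MorphReport], base: str) -> ChangeTable:
    """Index/percent table of every model's dimensions against a base model."""
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    labels = [r.label for r in reports]
    if base not in labels:
        raise ValueError(f"unknown base label {base!r}")
    ref = reports[labels.index(base)]
    rows = []
    for quantity in QUANTITIES:
        base_value = getattr(ref, quantity)
        for rep in reports:
            pct = percent_change(base_value, getattr(rep, quantity))
            rows.append(
                {
                    "quantity": quantity,
                    "label": rep.label,
                    "value": getattr(rep, quantity),
                    "index": round(100.0 + pct, 2),
                    "percent": pct,
                }
            )
    return ChangeTable(rows=pd.DataFrame(rows), base_label=base)


def _extents(points: np.ndarray, axes: np.ndarray) -> np.ndarray:
    proj = points @ axes
    return proj.max(axis=0) - proj.min(axis=0)


def _min_area_rect(xy: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers minimal-area rectangle of 2D points (hull-edge sweep)."""
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(xy)
        pts = xy[hull.vertices]
    except QhullError:
        pts = xy
    best: tuple[float, float, float] | None = None
    m = len(pts)
    for k in range(m):
        edge = pts[(k + 1) % m] - pts[k]
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        w = pts @ u
        h = pts @ v
        width, height = w.max() - w.min(), h.max() - h.min()
        if best is None or width * height < best[0]:
            best = (width * height, width, height)
    if best is None:
        ext = xy.max(axis=0) - xy.min(axis=0)
        return float(ext[0]), float(ext[1])
    return best[1], best[2]


def _hull_face_extents(points: np.ndarray) -> tuple[float, float, float] | None:
    """Minimal-volume oriented box over hull-face orientations.

    Used when the covariance spectrum is degenerate and principal axes are
    arbitrary (e.g. symmetric solids).  Exact whenever the minimal box has
    a face flush with a convex-hull face.
    """
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    verts = points[hull.vertices]
    normals = np.unique(np.round(hull.equations[:, :3], 9), axis=0)
    if len(normals) > 2000:  # pathological hull; stay with pca extents
        return None
    best: tuple[float, tuple[float, float, float]] | None = None
    for n in normals:
        n = n / np.linalg.norm(n)
        seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, seed)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        depth_proj = verts @ n
        depth = depth_proj.max() - depth_proj.min()
        width, height = _min_area_rect(np.column_stack((verts @ u, verts @ v)))
        volume = depth * width * height
        if best is None or volume < best[0]:
            dims = tuple(sorted((depth, width, height), reverse=True))
            best = (volume, dims)
    return None if best is None else best[1]


def bounding_dimensions(
    cloud: LabeledPointCloud | np.ndarray, method: str = "pca"
) -> tuple[float, float, float]:
    """(length, width, thickness): sorted extents of the cloud.

    ``pca`` measures along the three principal axes (orientation
    independent); ``axis`` measures along x/y/z.  Degenerate clouds fall
    back from pca to axis with a warning.
    """
    points = cloud.points if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud, dtype=np.float64)
    if points.shape[0] == 0:
        raise ValueError("empty cloud")
    if method not in ("pca", "axis"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pca":
        centred = points - points.mean(axis=0)
        if points.shape[0] < 4 or np.linalg.matrix_rank(centred) < 3:
            warnings.warn("degenerate cloud for pca dimensions; falling back to axis extents", stacklevel=2)
            method = "axis"
        else:
            cov = centred.T @ centred / points.shape[0]
            vals, vecs = np.linalg.eigh(cov)
            # a (near-)degenerate spectrum leaves the principal axes
            # arbitrary within the degenerate subspace; fall back to a
            # hull-face minimal-box search there
            scale = max(vals.max(), 1e-30)
            if np.min(np.diff(np.sort(vals))) / scale < 1e-6:
                dims = _hull_face_extents(points)
                if dims is not None:
                    return dims
            ext = np.sort(_extents(points, vecs))[::-1]
            return float(ext[0]), float(ext[1]), float(ext[2])
    ext = np.sort(_extents(points, np.eye(3)))[::-1]
    return float(ext[0]), float(ext[1]), float(ext[2])


def voxel_volume(foreground_count: int, spacing: VoxelSpacing) -> float:
    """Volume (µm³) of ``foreground_count`` voxels: count * dx * dy * dz."""
    if foreground_count < 0:
        raise ValueError("voxel count must be >= 0")
    return foreground_count * spacing.voxel_volume


def cloud_report(
    cloud: LabeledPointCloud,
    label: str,
    spacing: VoxelSpacing | None = None,
    method: str = "pca",
) -> MorphReport:
    """MorphReport of a cloud: pca dimensions plus (if spacing is given and
    the cloud holds solid interior voxels) the voxel-count volume."""
    length, width, thickness = bounding_dimensions(cloud, method=method)
    volume = float("nan")
    if spacing is not None:
        n_solid = int((cloud.labels == INTERIOR).sum())
        if n_solid:
            volume = voxel_volume(n_solid, spacing)
    if not np.isfinite(volume):
        volume = length * width * thickness  # bounding-box proxy, flagged by caller
    return MorphReport(length=length, width=width, thickness=thickness, volume=volume, label=label)


def nearest_distances(compared: LabeledPointCloud, reference: LabeledPointCloud) -> DistanceField:
    """Exact nearest-neighbour distance from each compared point to the
    reference cloud (KD-tree accelerated)."""
    if len(reference) == 0:
        raise ValueError("empty reference cloud")
    if len(compared) == 0:
        raise ValueError("empty compared cloud")
    tree = cKDTree(reference.points)
    d, _ = tree.query(compared.points, k=1)
    return DistanceField.from_distances(d)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (closed form)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=cd - rot @ cs)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / points.shape[0]
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, ::-1]  # descending variance


def _init_candidates(moving: np.ndarray, fixed: np.ndarray) -> list[RigidTransform]:
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    cands = [RigidTransform(np.eye(3), cf - cm)]
    if moving.shape[0] >= 4 and fixed.shape[0] >= 4:
        vm, vf = _principal_axes(moving), _principal_axes(fixed)
        for s0 in (1.0, -1.0):
            for s1 in (1.0, -1.0):
                basis = vf * np.array([s0, s1, 1.0])
                rot = basis @ vm.T
                if np.linalg.det(rot) < 0:
                    basis = vf * np.array([s0, s1, -1.0])
                    rot = basis @ vm.T
                cands.append(RigidTransform(rot, cf - rot @ cm))
    return cands


def icp_align(
    moving: LabeledPointCloud,
    fixed: LabeledPointCloud,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> ICPResult:
    """Point-to-point ICP: nearest-neighbour correspondence plus closed-form
    least-squares rigid update per iteration.

    Initialisation is centroid alignment with a principal-axes pre-rotation
    (the candidate with lowest starting rms wins).  Iteration stops when the
    rms improvement drops below ``tol`` or ``max_iter`` is hit; the result
    carries a ``converged`` flag.
    """
    if len(moving) < 3 or len(fixed) < 3:
        raise ValueError("both clouds need at least 3 points")
    src = moving.points
    tree = cKDTree(fixed.points)

    def rms_of(transform: RigidTransform) -> float:
        d, _ = tree.query(transform.apply(src), k=1)
        return float(np.sqrt(np.mean(d**2)))

    current = min(_init_candidates(src, fixed.points), key=rms_of)
    rms = rms_of(current)
    history = [rms]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = current.apply(src)
        d, idx = tree.query(moved, k=1)
        update = _kabsch(moved, fixed.points[idx])
        candidate = RigidTransform(
            rotation=update.rotation @ current.rotation,
            translation=update.rotation @ current.translation + update.translation,
        )
        new_rms = rms_of(candidate)
        if new_rms > rms:  # NN reassignment can only improve; keep the best
            break
        improved = rms - new_rms
        current, rms = candidate, new_rms
        history.append(rms)
        if improved < tol:
            converged = True
            break
    return ICPResult(transform=current, rms=rms, n_iter=it, converged=converged, rms_history=history)
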