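"""Synthetic micro-CT slice stacks of a leaf-shaped solid with planted defects.

The body is a tapered ellipsoid of "wood" grey against an air background.
Internal defects — crack slabs and spherical pores — are carved at a darker
"feature" grey (low-attenuation voids).  Additive Gaussian noise is applied
after the ground-truth masks are frozen, so every pipeline stage can be
validated against exact voxel sets and closed-form volumes.

Geometry is defined in a straight body frame; an optional circular-arc bend
of the long axis is applied via the inverse bend map when voxelizing, so
planted features bend with the body.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .stack_io import SliceImage, SliceStack, VoxelSpacing

__all__ = [
    "Crack",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "deform_phantom",
    "internal_feature_boundary",
    "default_spec",
    "analytic_body_volume",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass(frozen=True)
class Crack:
    """Planar slab defect: |normal . p - offset| <= width/2, cut to the body
    core (quadric value <= depth_fraction keeps the crack off the surface)."""

    normal: tuple[float, float, float]
    offset: float
    width: float
    depth_fraction: float = 0.85

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.linalg.norm(n) > 0:
            raise ValueError("crack normal must be non-zero")
        if self.width <= 0 or not (0 < self.depth_fraction <= 1):
            raise ValueError("crack width must be > 0 and depth_fraction in (0, 1]")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic artefact with derivable truth."""

    grid: tuple[int, int, int] = (160, 96, 72)  # (nx, ny, n_slices)
    spacing: VoxelSpacing = VoxelSpacing(50.0, 50.0, 50.0)
    axes: tuple[float, float, float] = (3600.0, 1700.0, 1500.0)  # half-axes µm
    taper: float = 0.3
    bend_deg: float = 0.0
    cracks: tuple[Crack, ...] = ()
    n_pores: int = 0
    pore_radius: tuple[float, float] = (250.0, 350.0)
    grey_air: int = 30
    grey_wood: int = 180
    grey_feature: int = 120
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 16:
            raise ValueError("grid dimensions must all be >= 16")
        if not (0 <= self.grey_air < self.grey_feature < self.grey_wood <= 255):
            raise ValueError("need grey_air < grey_feature < grey_wood on [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must lie in [0, 1)")
        if any(a <= 0 for a in self.axes):
            raise ValueError("body half-axes must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spacing"] = [self.spacing.dx, self.spacing.dy, self.spacing.dz]
        d["cracks"] = [dataclasses.asdict(c) for c in self.cracks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "spacing" in d:
            d["spacing"] = VoxelSpacing(*d["spacing"])
        if "cracks" in d:
            d["cracks"] = tuple(
                Crack(normal=tuple(c["normal"]), offset=c["offset"],
                      width=c["width"], depth_fraction=c.get("depth_fraction", 0.85))
                for c in d["cracks"]
            )
        for key in ("grid", "axes", "pore_radius"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclasses.dataclass
class GroundTruth:
    """Pre-noise voxel truth: (n_slices, rows, cols) boolean masks.

    ``analytic_volume`` is the closed-form body volume minus the planted
    pore spheres; crack slabs are not subtracted analytically (volume tests
    should use crack-free specs).
    """

    wood_mask: np.ndarray
    feature_mask: np.ndarray
    analytic_volume: float
    major_axis_length: float

    @property
    def body_mask(self) -> np.ndarray:
        return self.wood_mask | self.feature_mask


def analytic_body_volume(axes: tuple[float, float, float], taper: float) -> float:
    """Closed-form volume of the tapered ellipsoid.

    Cross-sections at relative position u = x/a are ellipses with half-axes
    b*g(u), c*g(u), g(u) = 1 - taper*(u+1)/2, inscribed in the ellipsoid
    envelope 1 - u^2; integrating pi*b*c*g(u)^2*(1-u^2) over u in [-1, 1]
    gives pi*a*b*c*(4/3 - 4*taper/3 + 2*taper^2/5).
    """
    a, b, c = axes
    t = taper
    return float(np.pi * a * b * c * (4.0 / 3.0 - 4.0 * t / 3.0 + 2.0 * t * t / 5.0))


def _body_frame(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Straight body-frame coordinates for every voxel centre, shape (nz, ny, nx)."""
    nx, ny, nz = spec.grid
    sp = spec.spacing
    x = np.arange(nx) * sp.dx
    y = np.arange(ny) * sp.dy
    z = np.arange(1, nz + 1) * sp.dz
    centre = np.array([x.mean(), y.mean(), z.mean()])
    Z, Y, X = np.meshgrid(z - centre[2], y - centre[1], x - centre[0], indexing="ij")
    if spec.bend_deg:
        a = spec.axes[0]
        theta = np.deg2rad(spec.bend_deg)
        radius = 2.0 * a / theta
        phi = np.arctan2(X, radius - Y)
        r = np.hypot(X, radius - Y)
        X = radius * phi
        Y = radius - r
    return X, Y, Z


def _quadric(spec: PhantomSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    a, b, c = spec.axes
    u = np.clip(X / a, -1.0, 1.0)
    g = 1.0 - spec.taper * (u + 1.0) / 2.0
    g = np.maximum(g, 1e-9)
    return (X / a) ** 2 + (Y / (b * g)) ** 2 + (Z / (c * g)) ** 2


def _place_pores(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Rejection-sample non-overlapping pore spheres well inside the body."""
    a, b, c = spec.axes
    rmin, rmax = spec.pore_radius
    placed: list[tuple[np.ndarray, float]] = []
    attempts = 0
    while len(placed) < spec.n_pores and attempts < 10000:
        attempts += 1
        centre = rng.uniform(-1.0, 1.0, size=3) * np.array([a, b, c]) * 0.7
        radius = float(rng.uniform(rmin, rmax))
        spec0 = dataclasses.replace(spec, bend_deg=0.0)
        q = _quadric(spec0, *[np.asarray(v) for v in centre])
        if q > 0.5:
            continue
        if any(np.linalg.norm(centre - c0) <= r0 + radius + 2 * spec.spacing.dx
               for c0, r0 in placed):
            continue
        placed.append((centre, radius))
    if len(placed) < spec.n_pores:
        warnings.warn("could not place all requested pores inside the body")
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[SliceStack, GroundTruth]:
    """Voxelize the phantom and return the noisy stack plus exact ground truth.

    Deterministic for a given seed: pore placement and noise come from one
    seeded generator.  Ground-truth masks are frozen before noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = _body_frame(spec)
    q = _quadric(spec, X, Y, Z)
    body = q <= 1.0

    feature = np.zeros_like(body)
    for crack in spec.cracks:
        n = np.asarray(crack.normal, dtype=float)
        n /= np.linalg.norm(n)
        dist = n[0] * X + n[1] * Y + n[2] * Z - crack.offset
        feature |= (np.abs(dist) <= crack.width / 2.0) & (q <= crack.depth_fraction)
    pores = _place_pores(spec, rng)
    for centre, radius in pores:
        d2 = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2
        feature |= d2 <= radius**2

    if (feature & ~body).any():
        warnings.warn("planted features exceed the body; clipping to the body support")
    feature &= body
    wood = body & ~feature

    pore_volume = sum(4.0 / 3.0 * np.pi * r**3 for _, r in pores)
    volume = analytic_body_volume(spec.axes, spec.taper) - pore_volume

    grey = np.full(body.shape, float(spec.grey_air))
    grey[wood] = spec.grey_wood
    grey[feature] = spec.grey_feature
    if spec.noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)
    grey = np.clip(np.rint(grey), 0, 255).astype(np.uint8)

    slices = [
        SliceImage(pixels=grey[k], bit_depth=8, index=k + 1)
        for k in range(grey.shape[0])
    ]
    stack = SliceStack(slices=slices, spacing=spec.spacing, name="phantom")
    truth = GroundTruth(
        wood_mask=wood,
        feature_mask=feature,
        analytic_volume=volume,
        major_axis_length=2.0 * spec.axes[0],
    )
    return stack, truth


def deform_phantom(spec: PhantomSpec, shrink: float = 0.0, bend_deg: float = 0.0) -> PhantomSpec:
    """Spec of a conserved/deformed artefact: axes scaled by (1 - shrink)
    and the long axis bent by an additional circular arc of ``bend_deg``."""
    if not (0 <= shrink < 0.5):
        raise ValueError("shrink must lie in [0, 0.5)")
    factor = 1.0 - shrink
    return dataclasses.replace(
        spec,
        axes=tuple(a * factor for a in spec.axes),
        bend_deg=spec.bend_deg + bend_deg,
    )


def _inner_boundary_2d(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask, structure=_EIGHT, border_value=0)


def internal_feature_boundary(truth: GroundTruth) -> np.ndarray:
    """Per-slice boundary voxels of the planted features, inside the body.

    For each slice: feature pixels with an 8-connected non-feature
    neighbour, restricted to the body interior (off the body's own per-slice
    boundary) — the voxel set a segmented reconstruction should label as
    internal features.
    """
    body = truth.body_mask
    out = np.zeros_like(truth.feature_mask)
    for k in range(body.shape[0]):
        b = body[k]
        if not b.any():
            continue
        interior = b & ~_inner_boundary_2d(b)
        f = truth.feature_mask[k] & interior
        out[k] = _inner_boundary_2d(f) & interior
    return out


def default_spec(**overrides) -> PhantomSpec:
    """A modest phantom with two pores and one crack, handy for tests/demos."""
    base = dict(
        grid=(160, 96, 72),
        spacing=VoxelSpacing(50.0, 50.0, 50.0),
        axes=(3600.0, 1700.0, 1500.0),
        taper=0.3,
        cracks=(Crack(normal=(0.0, 1.0, 0.0), offset=200.0, width=160.0, depth_fraction=0.8),),
        n_pores=2,
        pore_radius=(250.0, 350.0),
        seed=7,
    )
    base.update(overrides)
    return PhantomSpec(**base)
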