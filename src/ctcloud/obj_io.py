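"""Wavefront OBJ input/output for labeled point clouds.

Only the vertex-dialect is used: one ``v x y z [r g b]`` line per point,
no faces.  Coordinates are written in micrometres, unscaled, so volumetric
analyses survive the round trip.  Labels are carried by a fixed per-vertex
colour scheme:

==================  =====================
label               colour (r, g, b)
==================  =====================
outer_surface       0.000 0.000 1.000  (blue)
internal_feature    0.400 0.800 1.000  (light blue)
wood_boundary       0.000 0.800 0.000  (green)
interior            0.600 0.600 0.600  (grey)
==================  =====================
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np

from .reconstruct import LABELS, INTERIOR, LabeledPointCloud

__all__ = ["ObjDialect", "LABEL_COLORS", "write_obj", "read_obj"]

LABEL_COLORS: dict[str, tuple[float, float, float]] = {
    "outer_surface": (0.0, 0.0, 1.0),
    "internal_feature": (0.4, 0.8, 1.0),
    "wood_boundary": (0.0, 0.8, 0.0),
    "interior": (0.6, 0.6, 0.6),
}


@dataclasses.dataclass(frozen=True)
class ObjDialect:
    precision: int = 4
    with_color: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.precision <= 12):
            raise ValueError("precision must lie in [1, 12]")


def write_obj(
    cloud: LabeledPointCloud,
    path: str | Path,
    dialect: ObjDialect = ObjDialect(),
    header: Iterable[str] = (),
) -> None:
    """Write the cloud as a vertex-only OBJ file (UTF-8, LF line endings)."""
    path = Path(path)
    p = dialect.precision
    names = cloud.label_names()
    lines = ["# ctcloud point cloud"]
    for extra in header:
        lines.append(f"# {extra}")
    lines.append(f"# points: {len(cloud)}")
    lines.append(f"# precision: {p}")
    lines.append(f"# colors: {'on' if dialect.with_color else 'off'}")
    for idx in range(len(cloud)):
        x, y, z = cloud.points[idx]
        line = f"v {x:.{p}f} {y:.{p}f} {z:.{p}f}"
        if dialect.with_color:
            r, g, b = LABEL_COLORS[names[idx]]
            line += f" {r:.3f} {g:.3f} {b:.3f}"
        lines.append(line)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _label_from_color(rgb: tuple[float, float, float]) -> int:
    best, best_d = INTERIOR, float("inf")
    for name, ref in LABEL_COLORS.items():
        d = sum((a - b) ** 2 for a, b in zip(rgb, ref))
        if d < best_d:
            best, best_d = LABELS.index(name), d
    return best


def read_obj(path: str | Path) -> LabeledPointCloud:
    """Read vertex lines from an OBJ file; faces/normals/comments are ignored.

    Vertices with a recognised colour triple get the matching label, others
    default to ``interior``.
    """
    path = Path(path)
    points: list[tuple[float, float, float]] = []
    labels: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line.startswith("v ") and line != "v":
                continue
            fields = line.split()
            if len(fields) not in (4, 7):
                raise ValueError(f"malformed vertex line {lineno} in {path.name}: {line!r}")
            try:
                vals = [float(f) for f in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"malformed vertex line {lineno} in {path.name}: {line!r}") from exc
            points.append((vals[0], vals[1], vals[2]))
            labels.append(_label_from_color(tuple(vals[3:6])) if len(vals) == 6 else INTERIOR)
    pts = np.array(points, dtype=np.float64).reshape(-1, 3)
    return LabeledPointCloud(points=pts, labels=np.array(labels, dtype=np.int8))
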