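"""Reading skeleton point clouds and helix annotations, writing reports.

Supported inputs:

* MRC/CCP4 density or skeleton volumes (via :mod:`gemmi`); every voxel above a
  threshold becomes a skeleton point at ``origin + voxel_size * (i, j, k)`` Å.
* Plain-text XYZ skeletons — one ``x y z`` triple per line in Å, ``#`` comments,
  and an optional ``#voxel_size <float>`` directive.
* Helix annotations as either a JSON list ``[{"id":…, "p":[x,y,z], "q":[x,y,z]}]``
  or an equivalent 7-column text format ``id x1 y1 z1 x2 y2 z2``.

Reports mirror the per-endpoint-pair measurement table: columns
``pair, feasible, expected, measured, diff, rel_err, epsilon, lcg_id``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .geometry import euclidean

__all__ = [
    "SkeletonCloud",
    "HelixAxis",
    "LengthReport",
    "read_skeleton_mrc",
    "read_skeleton_text",
    "write_skeleton_mrc",
    "write_skeleton_text",
    "read_helices",
    "write_helices",
    "write_report",
    "read_report_json",
]


@dataclass
class SkeletonCloud:
    """A set of skeleton points in Å with lattice metadata.

    ``points`` is an ``(n, 3)`` float array.  For map-derived clouds every
    point is ``origin + voxel_size * integer triple``.
    """

    points: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source: str = "text"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.points.size == 0:
            raise ValueError("empty skeleton")
        if self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class HelixAxis:
    """Central axis of a detected α-helix: a segment from ``p`` to ``q`` in Å."""

    id: str
    p: np.ndarray
    q: np.ndarray

    def __init__(self, id: str, p, q):
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        if p.shape != (3,) or q.shape != (3,):
            raise ValueError("helix endpoints must be 3D points")
        if np.array_equal(p, q):
            raise ValueError(f"degenerate axis for helix {id!r}: p == q")
        object.__setattr__(self, "id", str(id))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)

    @property
    def length(self) -> float:
        return euclidean(self.p, self.q)


@dataclass
class LengthReport:
    """One row of the measurement table for a single helix-endpoint pair."""

    pair_label: str
    feasible: bool
    measured_length: Optional[float] = None
    expected_length: Optional[float] = None
    diff: Optional[float] = None
    rel_err: Optional[float] = None
    epsilon: Optional[float] = None
    lcg_id: Optional[str] = None
    n_vertices_before: Optional[int] = None
    n_vertices_after: Optional[int] = None

    def __post_init__(self):
        if not self.feasible and self.measured_length is not None:
            raise ValueError("infeasible pair cannot carry a measured length")


# ---------------------------------------------------------------------------
# skeleton readers / writers

def read_skeleton_mrc(path, threshold: float = 0.0, permissive: bool = False) -> SkeletonCloud:
    """Load every voxel with density > ``threshold`` as a skeleton point.

    The voxel size and origin come from the map header.  Maps with permuted
    axis order are rejected unless ``permissive=True`` (then normalized), and
    anisotropic voxels are always rejected.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad files
        raise IOError(f"cannot read MRC map {path}: {exc}") from exc
    axis_order = [m.header_i32(i) for i in (17, 18, 19)]
    if axis_order != [1, 2, 3]:
        if not permissive:
            raise ValueError(
                f"map {path} has permuted axis order {axis_order}; "
                "pass permissive=True to normalize"
            )
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = m.grid
    nx, ny, nz = grid.shape
    cell = grid.unit_cell
    spacings = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if not np.allclose(spacings, spacings[0], rtol=1e-4):
        raise ValueError(
            f"map {path} has anisotropic voxels {tuple(spacings)}; not supported"
        )
    voxel_size = float(spacings[0])
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    arr = np.array(grid, copy=False)
    idx = np.argwhere(arr > threshold)
    if idx.size == 0:
        raise ValueError(f"empty skeleton: no voxel above threshold {threshold}")
    points = origin + voxel_size * idx.astype(float)
    return SkeletonCloud(points=points, voxel_size=voxel_size, origin=origin, source="map")


def write_skeleton_mrc(cloud: SkeletonCloud, path, value: float = 1.0) -> None:
    """Rasterize a lattice-aligned cloud back to an MRC map (fixture writer)."""
    idx = np.rint((cloud.points - cloud.origin) / cloud.voxel_size).astype(int)
    if np.any(idx < 0):
        raise ValueError("cloud contains points below the origin; cannot rasterize")
    shape = idx.max(axis=0) + 2  # one voxel of padding
    arr = np.zeros(tuple(shape), dtype=np.float32)
    arr[idx[:, 0], idx[:, 1], idx[:, 2]] = value
    grid = gemmi.FloatGrid(*map(int, shape))
    grid.set_unit_cell(
        gemmi.UnitCell(
            shape[0] * cloud.voxel_size,
            shape[1] * cloud.voxel_size,
            shape[2] * cloud.voxel_size,
            90, 90, 90,
        )
    )
    np.array(grid, copy=False)[:] = arr
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), cloud.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def read_skeleton_text(path) -> SkeletonCloud:
    """Read a plain-text XYZ skeleton (Å); see module docstring for the format."""
    voxel_size = 1.0
    pts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line[1:].split()
                if tok and tok[0] == "voxel_size":
                    voxel_size = float(tok[1])
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {len(fields)}")
            try:
                pts.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinate: {exc}") from exc
    if not pts:
        raise ValueError(f"empty skeleton file {path}")
    return SkeletonCloud(points=np.array(pts), voxel_size=voxel_size, source="text")


def write_skeleton_text(cloud: SkeletonCloud, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#voxel_size {cloud.voxel_size:.6g}\n")
        for x, y, z in cloud.points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# helix annotations

def read_helices(path) -> list[HelixAxis]:
    """Read helix axis annotations from JSON or 7-column text."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        entries = json.loads(text)
        if isinstance(entries, dict):
            entries = entries.get("helices", [entries])
        helices = [HelixAxis(e["id"], e["p"], e["q"]) for e in entries]
    else:
        helices = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 'id x1 y1 z1 x2 y2 z2'")
            helices.append(
                HelixAxis(fields[0], [float(v) for v in fields[1:4]], [float(v) for v in fields[4:7]])
            )
    if not helices:
        raise ValueError(f"no helices found in {path}")
    return helices


def write_helices(helices: list[HelixAxis], path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        payload = [
            {"id": h.id, "p": list(map(float, h.p)), "q": list(map(float, h.q))}
            for h in helices
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "text":
        lines = ["# id x1 y1 z1 x2 y2 z2"]
        for h in helices:
            coords = " ".join(f"{v:.6f}" for v in (*h.p, *h.q))
            lines.append(f"{h.id} {coords}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown helix format {fmt!r}")


# ---------------------------------------------------------------------------
# reports

_REPORT_COLUMNS = ("pair", "feasible", "expected", "measured", "diff", "rel_err", "epsilon", "lcg_id")


def _fmt(value, spec):
    return "" if value is None else format(value, spec)


def write_report(reports: list[LengthReport], path, fmt: str = "tsv") -> None:
    """Write measurement rows as TSV (table-style formatting) or JSON."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(_REPORT_COLUMNS)]
        for r in reports:
            lines.append(
                "\t".join(
                    [
                        r.pair_label,
                        "yes" if r.feasible else "no",
                        _fmt(r.expected_length, ".1f"),
                        _fmt(r.measured_length, ".4f"),
                        _fmt(r.diff, ".4f"),
                        _fmt(r.rel_err, ".1f"),
                        _fmt(r.epsilon, ".2f"),
                        r.lcg_id or "",
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = [
            {
                "pair": r.pair_label,
                "feasible": r.feasible,
                "expected": r.expected_length,
                "measured": r.measured_length,
                "diff": r.diff,
                "rel_err": r.rel_err,
                "epsilon": r.epsilon,
                "lcg_id": r.lcg_id,
                "n_vertices_before": r.n_vertices_before,
                "n_vertices_after": r.n_vertices_after,
            }
            for r in reports
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report_json(path) -> list[LengthReport]:
    entries = json.loads(Path(path).read_text())
    return [
        LengthReport(
            pair_label=e["pair"],
            feasible=e["feasible"],
            measured_length=e["measured"],
            expected_length=e["expected"],
            diff=e["diff"],
            rel_err=e["rel_err"],
            epsilon=e["epsilon"],
            lcg_id=e["lcg_id"],
            n_vertices_before=e.get("n_vertices_before"),
            n_vertices_after=e.get("n_vertices_after"),
        )
        for e in entries
    ]
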