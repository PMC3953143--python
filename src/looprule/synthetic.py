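"""Synthetic helix-loop-helix skeleton fixtures with known ground truth.

A fixture consists of two straight helix axes joined by a smooth cubic Bézier
loop whose analytic arc length equals the expected length of an ``n``-residue
loop, 3.8 × (n + 1) Å.  The loop curve is sampled densely, optionally
perturbed by smooth jitter and snapped to the cubic voxel lattice, and points
inside the 2.3 Å helix mask are removed — so fixtures look like the
*post-masking* skeleton a measurement run starts from.  Optional decoy
clusters and isolated noise points exercise LCG selection.

The generator emulates the skeleton of a helix-loop-helix motif directly
rather than simulating a density map and re-skeletonizing it; jitter and
lattice snap stand in for skeletonization imperfection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from .geometry import Segment3, points_to_segment_distances
from .io_formats import (
    HelixAxis,
    SkeletonCloud,
    write_helices,
    write_skeleton_mrc,
    write_skeleton_text,
)
from .preprocess import HELIX_MASK_RADIUS
from .simplify import expected_length

__all__ = ["SyntheticHLH", "generate_hlh", "arc_length", "write_fixture"]


@dataclass
class SyntheticHLH:
    """A generated fixture: two helices, a skeleton cloud, and ground truth."""

    helices: list[HelixAxis]
    cloud: SkeletonCloud
    true_pair_label: str
    true_loop_length: float
    true_lcg_points: np.ndarray
    seed: int
    params: dict


def _bezier(control: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic Bézier curve evaluated at parameter values ``t``."""
    t = np.asarray(t, dtype=float)[:, None]
    p0, p1, p2, p3 = control
    u = 1.0 - t
    return u**3 * p0 + 3 * u**2 * t * p1 + 3 * u * t**2 * p2 + t**3 * p3


def _bezier_speed(control: np.ndarray, t: float) -> float:
    p0, p1, p2, p3 = control
    u = 1.0 - t
    d = 3 * (u**2 * (p1 - p0) + 2 * u * t * (p2 - p1) + t**2 * (p3 - p2))
    return float(np.linalg.norm(d))


def arc_length(control: np.ndarray, t_range: tuple[float, float] = (0.0, 1.0)) -> float:
    """Arc length of a cubic Bézier by adaptive quadrature (rel. error ≤ 1e-6)."""
    control = np.asarray(control, dtype=float)
    val, _ = quad(lambda t: _bezier_speed(control, t), *t_range, epsabs=1e-10, epsrel=1e-9, limit=200)
    return float(val)


def _smooth_jitter(n: int, sd: float, rng: np.random.Generator, knots: int = 8) -> np.ndarray:
    """Spatially correlated Gaussian displacement field along the curve.

    Independent per-sample jitter would shatter the snapped skeleton into
    fragments, which is not how skeletonization errs — its bias is smooth
    along the curve.  Gaussian displacements are drawn at a few knots and
    interpolated, so the pointwise sd is ``sd`` but neighbouring samples move
    together and lattice connectivity survives.
    """
    if sd <= 0:
        return np.zeros((n, 3))
    knot_t = np.linspace(0.0, 1.0, knots)
    knot_d = rng.normal(0.0, sd, size=(knots, 3))
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(t, knot_t, knot_d[:, k]) for k in range(3)])


def generate_hlh(
    n_loop_residues: int,
    voxel_size: float = 1.0,
    lattice_snap: bool = True,
    decoy_clusters: int = 0,
    noise_points: int = 0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticHLH:
    """Generate a seeded helix-loop-helix skeleton fixture.

    The loop joins helix 1's ``q`` endpoint to helix 2's ``r`` endpoint, so
    the ground-truth pair label is always ``q-r``.  Raises ``ValueError``
    when the geometry is infeasible (loop too short to clear the helix mask).
    """
    if n_loop_residues < 1:
        raise ValueError("n_loop_residues must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    rng = np.random.default_rng(seed)
    target = expected_length(n_loop_residues)

    # unit-chord control polygon with a gentle bulge; scaled to the target arc
    bulge = rng.uniform(0.10, 0.20)
    twist = rng.uniform(-0.06, 0.06)
    control = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0 / 3.0, bulge, 0.0],
            [2.0 / 3.0, bulge, twist],
            [1.0, 0.0, 0.0],
        ]
    )
    control *= target / arc_length(control)
    rot = Rotation.random(rng=rng).as_matrix()
    control = control @ rot.T
    true_length = arc_length(control)  # scale/rotation invariant; == target

    # helices continue the loop tangents beyond its ends
    a, b = control[0], control[3]
    tan_a = control[0] - control[1]
    tan_a /= np.linalg.norm(tan_a)
    tan_b = control[3] - control[2]
    tan_b /= np.linalg.norm(tan_b)
    len1, len2 = rng.uniform(8.0, 12.0, size=2)
    h1 = HelixAxis("H1", p=a + len1 * tan_a, q=a)
    h2 = HelixAxis("H2", p=b, q=b + len2 * tan_b)

    # dense sampling of the loop curve
    n_samples = max(int(np.ceil(true_length / (0.3 * voxel_size))), 8)
    t = np.linspace(0.0, 1.0, n_samples)
    loop_pts = _bezier(control, t)
    loop_pts = loop_pts + _smooth_jitter(n_samples, jitter_sd, rng)

    # decoy clusters: compact blobs far from the true pair's endpoints
    decoys = []
    centre = 0.5 * (a + b)
    for _ in range(decoy_clusters):
        for _attempt in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c = centre + rng.uniform(12.0, 22.0) * direction
            if min(np.linalg.norm(c - a), np.linalg.norm(c - b)) >= 8.0 + 3.0:
                break
        else:
            raise ValueError("could not place decoy cluster")
        blob = c + rng.normal(0.0, 1.2, size=(rng.integers(12, 25), 3))
        decoys.append(blob)

    parts = [loop_pts] + decoys
    all_pts = np.vstack(parts)

    # isolated noise points >= 5 Å from everything already placed
    noise = []
    if noise_points:
        lo = all_pts.min(axis=0) - 10.0
        hi = all_pts.max(axis=0) + 10.0
        placed = all_pts
        for _ in range(noise_points):
            for _attempt in range(100):
                cand = rng.uniform(lo, hi)
                if np.linalg.norm(placed - cand, axis=1).min() >= 5.0:
                    noise.append(cand)
                    placed = np.vstack([placed, cand])
                    break
    if noise:
        all_pts = np.vstack([all_pts] + [np.asarray(noise)])
    n_loop = loop_pts.shape[0]

    # shift the scene into the positive octant so lattice indices are valid
    shift = 2.0 * voxel_size - np.floor(
        np.minimum(all_pts.min(axis=0), np.vstack([h1.p, h1.q, h2.p, h2.q]).min(axis=0))
    )
    all_pts = all_pts + shift
    h1 = HelixAxis(h1.id, h1.p + shift, h1.q + shift)
    h2 = HelixAxis(h2.id, h2.p + shift, h2.q + shift)

    if lattice_snap:
        all_pts = np.rint(all_pts / voxel_size) * voxel_size

    # remove points inside the helix mask (fixtures are post-mask realistic)
    keep = np.ones(all_pts.shape[0], dtype=bool)
    for h in (h1, h2):
        keep &= points_to_segment_distances(all_pts, Segment3(h.p, h.q)) > HELIX_MASK_RADIUS
    is_loop = np.zeros(all_pts.shape[0], dtype=bool)
    is_loop[:n_loop] = True

    loop_kept = all_pts[keep & is_loop]
    if loop_kept.shape[0] == 0:
        raise ValueError(
            "infeasible geometry: the loop is too short to clear the helix mask; "
            "increase n_loop_residues"
        )
    # deduplicate after snapping, preserving the loop/decoy split
    kept = all_pts[keep]
    kept_is_loop = is_loop[keep]
    _, unique_idx = np.unique(np.round(kept / (0.25 * voxel_size)).astype(np.int64), axis=0, return_index=True)
    unique_idx.sort()
    kept = kept[unique_idx]
    kept_is_loop = kept_is_loop[unique_idx]
    loop_kept = kept[kept_is_loop]

    for endpoint in (h1.q, h2.p):
        if np.linalg.norm(loop_kept - endpoint, axis=1).min() > 5.0:
            raise ValueError(
                "infeasible geometry: helix mask leaves the loop out of attachment range"
            )

    cloud = SkeletonCloud(
        points=kept,
        voxel_size=voxel_size,
        origin=np.zeros(3),
        source="map" if lattice_snap else "text",
    )
    return SyntheticHLH(
        helices=[h1, h2],
        cloud=cloud,
        true_pair_label="q-r",
        true_loop_length=float(true_length),
        true_lcg_points=loop_kept,
        seed=seed,
        params=dict(
            n_loop_residues=n_loop_residues,
            voxel_size=voxel_size,
            lattice_snap=lattice_snap,
            decoy_clusters=decoy_clusters,
            noise_points=noise_points,
            jitter_sd=jitter_sd,
        ),
    )


def write_fixture(hlh: SyntheticHLH, out_dir) -> dict[str, Path]:
    """Write skeleton (text, and MRC when lattice-aligned), helices and truth.

    Returns the paths written, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    text_path = out_dir / "skeleton.xyz"
    write_skeleton_text(hlh.cloud, text_path)
    paths["skeleton_text"] = text_path

    if hlh.params.get("lattice_snap"):
        mrc_path = out_dir / "skeleton.mrc"
        write_skeleton_mrc(hlh.cloud, mrc_path)
        paths["skeleton_mrc"] = mrc_path

    helices_path = out_dir / "helices.json"
    write_helices(hlh.helices, helices_path, fmt="json")
    paths["helices"] = helices_path

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "true_pair": hlh.true_pair_label,
                "true_loop_length": hlh.true_loop_length,
                "expected_length": expected_length(hlh.params["n_loop_residues"]),
                "seed": hlh.seed,
                "params": hlh.params,
            },
            indent=1,
        )
        + "\n"
    )
    paths["ground_truth"] = truth_path
    return paths
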