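"""Helix masking and clustering of skeleton voxels into local connectivity graphs.

Helix detection and skeletonization are independent upstream steps, so the
skeleton still contains voxels that belong to the helices themselves.  Those
are removed by deleting every point within ``radius`` (default 2.3 Å — an
α-helix is 2.3–2.5 Å in radius) of any helix central-axis segment.  The
surviving points are clustered into *local connectivity graphs* (LCGs):
connected components of the graph whose edges join point pairs closer than
``max_edge`` voxel units (default 2, i.e. 26-connectivity on a unit lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import Segment3, points_to_segment_distances
from .io_formats import HelixAxis, SkeletonCloud

__all__ = ["LCG", "mask_helix_voxels", "build_lcgs"]

HELIX_MASK_RADIUS = 2.3  # Å; α-helix radius
MAX_EDGE = 2.0  # voxel units; "< 2" keeps all 26-neighbours on a unit lattice


@dataclass
class LCG:
    """A connected cluster of skeleton points with bounded edge length.

    ``nodes`` is an ``(n, 3)`` array in Å, sorted lexicographically so node
    indices are deterministic; ``edges`` are index pairs into ``nodes``.
    """

    id: str
    nodes: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.nodes.shape[0]


def mask_helix_voxels(
    cloud: SkeletonCloud,
    helices: list[HelixAxis],
    radius: float = HELIX_MASK_RADIUS,
) -> SkeletonCloud:
    """Remove every point within ``radius`` of any helix axis segment.

    The boundary is inclusive: a point at exactly ``radius`` is removed.
    Raises ``ValueError`` if no loop skeleton remains.
    """
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    keep = np.ones(len(cloud), dtype=bool)
    for h in helices:
        d = points_to_segment_distances(cloud.points, Segment3(h.p, h.q))
        keep &= d > radius
    if not keep.any():
        raise ValueError("no loop skeleton remains after helix masking")
    return SkeletonCloud(
        points=cloud.points[keep],
        voxel_size=cloud.voxel_size,
        origin=cloud.origin,
        source=cloud.source,
    )


def build_lcgs(
    cloud: SkeletonCloud,
    max_edge: float = MAX_EDGE,
    strict: bool = True,
) -> list[LCG]:
    """Cluster skeleton points into LCGs.

    An edge joins two points when their distance in voxel units (Å distance
    divided by ``cloud.voxel_size``) is ``< max_edge`` (``<=`` with
    ``strict=False``).  Components are returned sorted by size (descending),
    ties broken by the lexicographically smallest node, and labelled
    ``lcg0, lcg1, …``.
    """
    if max_edge <= 0:
        raise ValueError("max_edge must be positive")
    pts = cloud.points
    n = pts.shape[0]
    r_ang = max_edge * cloud.voxel_size
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=r_ang, output_type="ndarray")  # distance <= r
    if pairs.size and strict:
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d / cloud.voxel_size < max_edge]
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    comps = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        node_pts = pts[members]
        order = np.lexsort((node_pts[:, 2], node_pts[:, 1], node_pts[:, 0]))
        comps.append((members[order], node_pts[order]))

    # size desc, then lexicographically smallest node
    comps.sort(key=lambda item: (-item[1].shape[0], tuple(item[1][0])))

    # map each global point index to (component rank, local node index)
    rank_of = np.empty(n, dtype=int)
    local_of = np.empty(n, dtype=int)
    for rank, (members, _) in enumerate(comps):
        rank_of[members] = rank
        local_of[members] = np.arange(members.shape[0])

    edge_lists: list[list[tuple[int, int]]] = [[] for _ in comps]
    for a, b in pairs:
        edge_lists[rank_of[a]].append((int(local_of[a]), int(local_of[b])))

    return [
        LCG(id=f"lcg{rank}", nodes=node_pts, edges=edge_lists[rank])
        for rank, (_, node_pts) in enumerate(comps)
    ]
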