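"""LCG selection by directed Hausdorff distance, endpoint attachment and BFS.

The loop between two helices could run between any of the four combinations of
their axis endpoints.  For helices with endpoints (p, q) and (r, s) the
candidate pairs are {p,r}, {p,s}, {q,r}, {q,s}.  For each pair the cluster of
skeleton points (LCG) closest in *directed* Hausdorff distance is selected,
both endpoints are attached to their nearest cluster node (infeasible if
either attachment edge exceeds the cutoff, default 5 Å), and a minimum-hop BFS
path between the endpoints is extracted through the cluster.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import HelixAxis
from .preprocess import LCG

__all__ = [
    "EndpointPair",
    "LoopPath",
    "enumerate_endpoint_pairs",
    "directed_hausdorff",
    "select_lcg",
    "attach_endpoints",
    "bfs_path",
    "find_loop_paths",
]

ATTACH_CUTOFF = 5.0  # Å; longer attachment edges mark the pair infeasible

PAIR_LABELS = ("p-r", "p-s", "q-r", "q-s")


@dataclass(frozen=True)
class EndpointPair:
    """One of the four helix-endpoint combinations."""

    label: str
    e1: np.ndarray  # endpoint on helix 1
    e2: np.ndarray  # endpoint on helix 2

    def as_array(self) -> np.ndarray:
        return np.vstack([self.e1, self.e2])


@dataclass
class LoopPath:
    """A candidate loop polyline from ``pair.e1`` to ``pair.e2`` through an LCG."""

    pair: EndpointPair
    lcg_id: Optional[str]
    vertices: Optional[np.ndarray]  # (n, 3), first row e1, last row e2
    attach_lengths: Optional[tuple[float, float]]
    feasible: bool


def enumerate_endpoint_pairs(h1: HelixAxis, h2: HelixAxis) -> list[EndpointPair]:
    """The four endpoint pairs {p,r}, {p,s}, {q,r}, {q,s}, in canonical order."""
    ends1 = {"p": h1.p, "q": h1.q}
    ends2 = {"r": h2.p, "s": h2.q}
    return [
        EndpointPair(label=f"{a}-{b}", e1=ends1[a], e2=ends2[b])
        for a, b in (("p", "r"), ("p", "s"), ("q", "r"), ("q", "s"))
    ]


def directed_hausdorff(z: np.ndarray, lcg: LCG) -> float:
    """h(z, b) = max over z_i of the min Euclidean distance to the LCG nodes.

    Directed (non-symmetric): the first argument is always the endpoint set,
    the second the candidate cluster.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if len(lcg) == 0:
        raise ValueError("cannot measure distance to an empty LCG")
    d = np.sqrt(((z[:, None, :] - lcg.nodes[None, :, :]) ** 2).sum(-1))
    return float(d.min(axis=1).max())


def select_lcg(pair: EndpointPair, lcgs: list[LCG]) -> LCG:
    """The LCG minimizing the directed Hausdorff distance from the pair.

    Ties are broken by larger node count, then smaller id — deterministic.
    """
    if not lcgs:
        raise ValueError("no LCGs to select from")
    z = pair.as_array()
    scored = [(directed_hausdorff(z, b), -len(b), b.id, b) for b in lcgs]
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def attach_endpoints(
    pair: EndpointPair, lcg: LCG, cutoff: float = ATTACH_CUTOFF
) -> Optional[tuple[dict[int, list[int]], np.ndarray, tuple[float, float]]]:
    """Attach both endpoints to their nearest LCG node.

    Returns ``(adjacency, coords, attach_lengths)`` where ``coords`` stacks the
    LCG nodes followed by e1 and e2 (indices ``n`` and ``n+1``), or ``None``
    if either attachment edge is longer than ``cutoff`` (exactly ``cutoff``
    is still feasible).  Nearest-node ties go to the lexicographically
    smallest node, which is the lowest index since LCG nodes are sorted.
    """
    n = len(lcg)
    za = pair.as_array()
    dists = np.linalg.norm(za[:, None, :] - lcg.nodes[None, :, :], axis=-1)
    nearest = dists.argmin(axis=1)  # argmin returns the first (smallest) index
    lengths = (float(dists[0, nearest[0]]), float(dists[1, nearest[1]]))
    if lengths[0] > cutoff or lengths[1] > cutoff:
        return None

    adjacency: dict[int, list[int]] = {i: [] for i in range(n + 2)}
    for a, b in lcg.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    for endpoint_idx, node in zip((n, n + 1), nearest):
        adjacency[endpoint_idx].append(int(node))
        adjacency[int(node)].append(endpoint_idx)
    for neighbors in adjacency.values():
        neighbors.sort()
    coords = np.vstack([lcg.nodes, pair.e1, pair.e2])
    return adjacency, coords, lengths


def bfs_path(
    adjacency: dict[int, list[int]], coords: np.ndarray, source: int, target: int
) -> Optional[list[int]]:
    """Minimum-hop path from ``source`` to ``target`` by breadth-first search.

    Neighbor expansion follows ascending node index, which for sorted LCG
    nodes is ascending lexicographic coordinate order — the search is fully
    deterministic.  Returns ``None`` when no path exists.
    """
    if source not in adjacency or target not in adjacency:
        raise KeyError("source/target not present in graph")
    parent: dict[int, int] = {source: source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if u == target:
            path = [u]
            while path[-1] != source:
                path.append(parent[path[-1]])
            return path[::-1]
        for v in adjacency[u]:
            if v not in parent:
                parent[v] = u
                queue.append(v)
    return None


def find_loop_paths(
    h1: HelixAxis,
    h2: HelixAxis,
    lcgs: list[LCG],
    cutoff: float = ATTACH_CUTOFF,
) -> list[LoopPath]:
    """One candidate LoopPath per endpoint pair (possibly infeasible).

    Each pair independently selects its best LCG, attaches, and runs BFS.
    """
    if not lcgs:
        raise ValueError("no LCGs available")
    out = []
    for pair in enumerate_endpoint_pairs(h1, h2):
        best = select_lcg(pair, lcgs)
        attached = attach_endpoints(pair, best, cutoff=cutoff)
        if attached is None:
            out.append(
                LoopPath(pair=pair, lcg_id=best.id, vertices=None, attach_lengths=None, feasible=False)
            )
            continue
        adjacency, coords, lengths = attached
        n = len(best)
        node_path = bfs_path(adjacency, coords, n, n + 1)
        if node_path is None:  # cannot happen for a connected LCG; guard anyway
            out.append(
                LoopPath(pair=pair, lcg_id=best.id, vertices=None, attach_lengths=lengths, feasible=False)
            )
            continue
        out.append(
            LoopPath(
                pair=pair,
                lcg_id=best.id,
                vertices=coords[node_path],
                attach_lengths=lengths,
                feasible=True,
            )
        )
    return out
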