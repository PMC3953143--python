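"""Douglas-Peucker simplification, loop-length measurement and the ε sweep.

Measuring raw voxel paths overestimates loop length: a path along cubic-lattice
edges zigzags around the smooth curve it traces.  Douglas-Peucker
simplification removes vertices that stay within a band of half-width ε around
the test line of each segment, straightening the path; the measured length is
the total length of the simplified polyline (attachment segments to the helix
endpoints included).  The expected length of an n-residue loop is
3.8 Å × (n + 1), 3.8 Å being the mean Cα–Cα distance between sequence-adjacent
residues.  Because no blind rule fixes ε, the measured length is evaluated over
a sweep (default 0–6 Å in 0.05 steps), which is a non-increasing step function
of ε.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Segment3, point_to_line_distance, polyline_length
from .loop_finder import LoopPath

__all__ = [
    "SimplificationParams",
    "SweepResult",
    "douglas_peucker",
    "measure_loop",
    "expected_length",
    "error_metrics",
    "epsilon_sweep",
]

CA_CA_DISTANCE = 3.8  # Å; mean distance between sequence-adjacent residues

DEFAULT_SWEEP = (0.0, 6.0, 0.05)


@dataclass(frozen=True)
class SimplificationParams:
    """ε (the vertex-removal band half-width, Å) or a sweep (min, max, step)."""

    epsilon: float = 0.0
    sweep: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sweep is not None:
            lo, hi, step = self.sweep
            if lo > hi or step <= 0:
                raise ValueError("sweep must satisfy min <= max and step > 0")


@dataclass
class SweepResult:
    """Measured length at each sampled ε, plus the best ε when an expected
    length is available (smallest sampled ε minimizing |measured − expected|)."""

    epsilons: np.ndarray
    lengths: np.ndarray
    best_epsilon: Optional[float] = None
    best_length: Optional[float] = None


def _max_deviation(vertices: np.ndarray, lo: int, hi: int) -> tuple[float, int]:
    """Largest perpendicular distance of interior vertices to the test line
    through vertices lo and hi; ties go to the earliest index."""
    line = Segment3(vertices[lo], vertices[hi])
    best_d, best_i = -1.0, -1
    for i in range(lo + 1, hi):
        d = point_to_line_distance(vertices[i], line)
        if d > best_d:
            best_d, best_i = d, i
    return best_d, best_i


def douglas_peucker(path: np.ndarray, epsilon: float) -> np.ndarray:
    """Simplify a polyline: vertices within the ε band of the current test
    line are dropped; the segment splits at the most distant vertex otherwise.

    The distance test uses the infinite line through the segment endpoints
    (falling back to point distance when they coincide).  The split condition
    is strict (d_max > ε), so ε = 0 removes only exactly-collinear vertices,
    which leaves the measured length unchanged.  Output vertices are a
    subsequence of the input including both endpoints.
    """
    v = np.atleast_2d(np.asarray(path, dtype=float))
    if v.shape[0] < 2:
        raise ValueError("douglas_peucker needs at least 2 vertices")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    keep = np.zeros(v.shape[0], dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, v.shape[0] - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        d_max, i_max = _max_deviation(v, lo, hi)
        if d_max > epsilon:
            keep[i_max] = True
            stack.append((lo, i_max))
            stack.append((i_max, hi))
    return v[keep]


def measure_loop(path: LoopPath, epsilon: float) -> float:
    """Length of the simplified loop polyline in Å.

    The polyline runs from one helix endpoint to the other, so the two
    endpoint-attachment segments take part in the simplification and count
    toward the measured length.
    """
    if not path.feasible or path.vertices is None:
        raise ValueError(f"pair {path.pair.label} is infeasible; nothing to measure")
    return polyline_length(douglas_peucker(path.vertices, epsilon))


def expected_length(n: int) -> float:
    """Expected length in Å of a loop of ``n`` amino acids: 3.8 × (n + 1)."""
    if n < 0 or int(n) != n:
        raise ValueError("residue count must be a non-negative integer")
    return CA_CA_DISTANCE * (n + 1)


def error_metrics(measured: float, expected: float) -> tuple[float, float]:
    """Absolute difference (Å) and relative error (percent of expected)."""
    if expected <= 0:
        raise ValueError("expected length must be positive")
    diff = abs(measured - expected)
    return diff, 100.0 * diff / expected


def sweep_epsilons(sweep: tuple[float, float, float] = DEFAULT_SWEEP) -> np.ndarray:
    lo, hi, step = sweep
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def epsilon_sweep(
    path: LoopPath,
    params: SimplificationParams = SimplificationParams(sweep=DEFAULT_SWEEP),
    expected: Optional[float] = None,
) -> SweepResult:
    """Measure the loop at every sampled ε.

    When ``expected`` is given, ``best_epsilon`` is the smallest sampled ε
    whose measured length is closest to it.
    """
    eps = sweep_epsilons(params.sweep if params.sweep is not None else DEFAULT_SWEEP)
    lengths = np.array([measure_loop(path, float(e)) for e in eps])
    result = SweepResult(epsilons=eps, lengths=lengths)
    if expected is not None:
        errors = np.abs(lengths - expected)
        i = int(np.argmin(errors))  # argmin takes the first, i.e. smallest ε
        result.best_epsilon = float(eps[i])
        result.best_length = float(lengths[i])
    return result
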