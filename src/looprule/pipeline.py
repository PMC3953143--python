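"""End-to-end measurement pipeline: files in, per-pair length reports out.

Stages: load skeleton and helices → mask helix voxels → cluster into LCGs →
for each of the four endpoint pairs: select LCG, attach endpoints, BFS path →
Douglas-Peucker simplify → measure (single ε or sweep) → report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats, loop_finder, preprocess, simplify

logger = logging.getLogger("looprule")

__all__ = ["RunConfig", "PipelineError", "run_measurement"]

# distinct exit codes surfaced by the CLI
EXIT_INPUT_ERROR = 2
EXIT_EMPTY_SKELETON = 3
EXIT_ALL_INFEASIBLE = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """All parameters of one measurement run."""

    skeleton_path: str
    helices_path: str
    skeleton_format: str = "auto"  # auto | mrc | text
    threshold: float = 0.0
    permissive: bool = False
    helix_mask_radius: float = preprocess.HELIX_MASK_RADIUS
    max_edge: float = preprocess.MAX_EDGE
    edge_strict: bool = True
    attach_cutoff: float = loop_finder.ATTACH_CUTOFF
    epsilon: Optional[float] = None
    sweep: tuple[float, float, float] = simplify.DEFAULT_SWEEP
    loop_residues: Optional[int] = None
    pair: str = "all"
    report_path: Optional[str] = None
    report_format: str = "tsv"
    helix_ids: Optional[tuple[str, str]] = None
    debug_polyline: Optional[str] = field(default=None)

    def __post_init__(self):
        for name in ("helix_mask_radius", "max_edge", "attach_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi, step = self.sweep
        if lo > hi or step <= 0:
            raise ValueError("sweep must satisfy min <= max and step > 0")

    def save(self, path) -> None:
        """Serialize to JSON; :meth:`load` reproduces an identical config."""
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for key in ("sweep", "helix_ids"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _load_skeleton(config: RunConfig) -> io_formats.SkeletonCloud:
    fmt = config.skeleton_format
    if fmt == "auto":
        fmt = "mrc" if str(config.skeleton_path).endswith((".mrc", ".map", ".ccp4")) else "text"
    if fmt == "mrc":
        return io_formats.read_skeleton_mrc(
            config.skeleton_path, threshold=config.threshold, permissive=config.permissive
        )
    return io_formats.read_skeleton_text(config.skeleton_path)


def run_measurement(config: RunConfig) -> list[io_formats.LengthReport]:
    """Run the full pipeline and return one report per endpoint pair.

    Raises :class:`PipelineError` with a distinct exit code for input errors,
    an empty post-mask skeleton, or four infeasible pairs.
    """
    try:
        cloud = _load_skeleton(config)
        helices = io_formats.read_helices(config.helices_path)
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError(f"input error: {exc}", EXIT_INPUT_ERROR) from exc
    if config.helix_ids is not None:
        by_id = {h.id: h for h in helices}
        try:
            helices = [by_id[config.helix_ids[0]], by_id[config.helix_ids[1]]]
        except KeyError as exc:
            raise PipelineError(f"input error: unknown helix id {exc}", EXIT_INPUT_ERROR) from exc
    if len(helices) < 2:
        raise PipelineError("input error: need at least two helices", EXIT_INPUT_ERROR)
    h1, h2 = helices[0], helices[1]
    logger.info("loaded %d skeleton points, helices %s and %s", len(cloud), h1.id, h2.id)

    try:
        masked = preprocess.mask_helix_voxels(cloud, [h1, h2], radius=config.helix_mask_radius)
    except ValueError as exc:
        raise PipelineError(str(exc), EXIT_EMPTY_SKELETON) from exc
    lcgs = preprocess.build_lcgs(masked, max_edge=config.max_edge, strict=config.edge_strict)
    logger.info("%d points after helix mask, %d LCGs", len(masked), len(lcgs))

    expected = (
        simplify.expected_length(config.loop_residues)
        if config.loop_residues is not None
        else None
    )

    paths = loop_finder.find_loop_paths(h1, h2, lcgs, cutoff=config.attach_cutoff)
    if config.pair != "all":
        paths = [p for p in paths if p.pair.label == config.pair]
        if not paths:
            raise PipelineError(f"input error: unknown pair {config.pair!r}", EXIT_INPUT_ERROR)

    reports = []
    for path in paths:
        if not path.feasible:
            logger.info("pair %s: infeasible (lcg=%s)", path.pair.label, path.lcg_id)
            reports.append(
                io_formats.LengthReport(
                    pair_label=path.pair.label,
                    feasible=False,
                    expected_length=expected,
                    lcg_id=path.lcg_id,
                )
            )
            continue
        if config.epsilon is not None:
            eps = config.epsilon
            measured = simplify.measure_loop(path, eps)
        else:
            sweep = simplify.epsilon_sweep(
                path, simplify.SimplificationParams(sweep=config.sweep), expected=expected
            )
            if expected is not None:
                eps, measured = sweep.best_epsilon, sweep.best_length
            else:  # without an expected length, report the unsimplified path
                eps, measured = float(sweep.epsilons[0]), float(sweep.lengths[0])
        simplified = simplify.douglas_peucker(path.vertices, eps)
        diff = rel_err = None
        if expected is not None:
            diff, rel_err = simplify.error_metrics(measured, expected)
        logger.info(
            "pair %s: lcg=%s hops=%d measured=%.4f eps=%.2f",
            path.pair.label, path.lcg_id, path.vertices.shape[0] - 1, measured, eps,
        )
        reports.append(
            io_formats.LengthReport(
                pair_label=path.pair.label,
                feasible=True,
                measured_length=float(measured),
                expected_length=expected,
                diff=diff,
                rel_err=rel_err,
                epsilon=float(eps),
                lcg_id=path.lcg_id,
                n_vertices_before=int(path.vertices.shape[0]),
                n_vertices_after=int(simplified.shape[0]),
            )
        )
        if config.debug_polyline:
            with open(config.debug_polyline, "a") as fh:
                fh.write(f"# pair {path.pair.label} epsilon {eps}\n")
                for x, y, z in simplified:
                    fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")

    if not any(r.feasible for r in reports):
        raise PipelineError("all endpoint pairs are infeasible", EXIT_ALL_INFEASIBLE)

    if config.report_path:
        io_formats.write_report(reports, config.report_path, fmt=config.report_format)
    return reports
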