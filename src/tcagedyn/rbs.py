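"""Rigid-body segmentation (RBS) of molecular-dynamics trajectories.

A protein (or receptor-ligand complex) moving as a set of quasi-rigid parts
leaves a characteristic signature in the fluctuations of its internal
distances: Cα pairs inside one rigid part keep a near-constant separation,
while pairs spanning a hinge fluctuate strongly.  RBS therefore clusters
residues with DBSCAN, using the Cα–Cα distance standard-deviation matrix as
a precomputed pairwise metric: two residues are "close" when their mutual
distance fluctuates by less than the cluster radius ``clr`` (2.5 Å default),
and a residue is a core point when at least ``cln`` (5) neighbors fall
within that radius.  Residues reachable from no core point move freely and
stay UNASSIGNED.

The DBSCAN here is written for determinism on a precomputed symmetric
matrix: border points attach to the lowest-indexed core residue within
``clr``, and segment ids are contiguous from 0 in order of each segment's
first residue, so identical inputs always give identical labelings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import Trajectory

logger = logging.getLogger(__name__)

#: Label of residues not assigned to any rigid segment.
UNASSIGNED = -1


@dataclass
class DistanceStdDevMatrix:
    """Per-residue-pair fluctuation matrix: entry (i, j) is the population
    standard deviation over frames of the Cα_i–Cα_j distance, Å."""

    values: np.ndarray
    residue_index: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_index)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix entries must be finite")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("matrix diagonal must be zero")

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)


@dataclass(frozen=True)
class SegmentationParams:
    """DBSCAN parameters of the segmentation.

    clr: cluster radius, Å — fluctuation threshold under which two residues
    count as neighbors.
    cln: neighbor count required for a core residue.
    stride: trajectory sampling interval, ps.
    neighbor_counting: "exclude_self" (default: a residue needs cln OTHER
    residues within clr) or "include_self" (the residue itself counts, as in
    some library conventions).
    """

    clr: float = 2.5
    cln: int = 5
    stride: float = 100.0
    neighbor_counting: str = "exclude_self"

    def __post_init__(self) -> None:
        if self.clr <= 0:
            raise ValueError("clr must be > 0")
        if self.cln < 1:
            raise ValueError("cln must be >= 1")
        if self.stride <= 0:
            raise ValueError("stride must be > 0")
        if self.neighbor_counting not in ("exclude_self", "include_self"):
            raise ValueError(f"unknown neighbor_counting {self.neighbor_counting!r}")


@dataclass
class SegmentationResult:
    """Per-residue segment labels: ids 0..K-1 contiguous in order of each
    segment's first residue; UNASSIGNED (-1) for freely moving residues."""

    labels: np.ndarray
    residue_index: list[tuple[str, int]]
    params: SegmentationParams
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.residue_index),):
            raise ValueError("labels length does not match residue index")

    @property
    def n_segments(self) -> int:
        return int(self.labels.max(initial=UNASSIGNED) + 1)

    def members(self, segment: int) -> list[tuple[str, int]]:
        return [r for r, lab in zip(self.residue_index, self.labels) if lab == segment]


def _strided_frame_indices(traj: Trajectory, stride: float) -> np.ndarray:
    """Frames at times t0, t0+stride, ...; when stride is not a multiple of
    the frame interval, the nearest earlier frame is taken (with a warning)."""
    ratio = stride / traj.frame_interval
    step_exact = round(ratio)
    if abs(ratio - step_exact) > 1e-9:
        logger.warning("stride %.6g ps is not a multiple of the frame interval "
                       "%.6g ps; taking nearest earlier frames", stride,
                       traj.frame_interval)
    times = np.arange(traj.n_frames) * traj.frame_interval
    wanted = np.arange(0.0, times[-1] + 1e-9, stride)
    idx = np.searchsorted(times, wanted + 1e-9) - 1
    return np.unique(np.clip(idx, 0, traj.n_frames - 1))


def compute_distance_stddev_matrix(traj: Trajectory,
                                   stride: float = 100.0) -> DistanceStdDevMatrix:
    """Population standard deviation of every Cα–Cα distance over the
    strided frames.

    Each residue must carry exactly one Cα; at least two frames must remain
    after striding.  The divide-by-N (population) convention keeps the result
    fully determined by the frame set.
    """
    residue_ids, ca_idx = traj.ca_indices()
    frames = _strided_frame_indices(traj, stride)
    if frames.size < 2:
        raise ValueError(f"only {frames.size} frame(s) remain after striding; need >= 2")
    xyz = traj.coords[np.ix_(frames, ca_idx)]  # (n_f, n_res, 3)
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (n_f, n_res, n_res)
    std = dist.std(axis=0, ddof=0)
    std = 0.5 * (std + std.T)  # exact symmetry against fp noise
    np.fill_diagonal(std, 0.0)
    return DistanceStdDevMatrix(values=std, residue_index=residue_ids)


def dbscan_segment(matrix: DistanceStdDevMatrix,
                   params: SegmentationParams | None = None) -> SegmentationResult:
    """DBSCAN on the fluctuation matrix as a precomputed metric.

    Residue i is a core point when at least ``cln`` residues lie within
    ``clr`` of it (the residue itself counted or not per
    ``neighbor_counting``).  Clusters are the connected components of the
    core-core adjacency at radius clr; border (non-core) residues within clr
    of a core attach to the lowest-indexed such core; everything else is
    UNASSIGNED.  Segment ids are renumbered 0..K-1 by first residue.
    """
    params = params or SegmentationParams()
    n = matrix.n_residues
    close = matrix.values <= params.clr
    neighbor_counts = close.sum(axis=1)  # includes self (diagonal is 0 <= clr)
    if params.neighbor_counting == "exclude_self":
        neighbor_counts = neighbor_counts - 1
    core = neighbor_counts >= params.cln

    labels = np.full(n, UNASSIGNED, dtype=int)
    if core.any():
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        core_idx = np.flatnonzero(core)
        adjacency = csr_matrix(close[np.ix_(core_idx, core_idx)])
        _, comp = connected_components(adjacency, directed=False)
        labels[core_idx] = comp
        for i in np.flatnonzero(~core):
            claiming = core_idx[close[i, core_idx]]
            if claiming.size:
                labels[i] = labels[claiming[0]]  # lowest-indexed claiming core

        # contiguous ids ordered by each segment's first residue
        order: dict[int, int] = {}
        for lab in labels:
            if lab != UNASSIGNED and lab not in order:
                order[lab] = len(order)
        labels = np.array([UNASSIGNED if lab == UNASSIGNED else order[lab]
                           for lab in labels])
    return SegmentationResult(labels=labels, residue_index=matrix.residue_index,
                              params=params)


def segment_trajectory(traj: Trajectory,
                       params: SegmentationParams | None = None) -> SegmentationResult:
    """Full RBS: fluctuation matrix at the configured stride, then DBSCAN."""
    params = params or SegmentationParams()
    matrix = compute_distance_stddev_matrix(traj, stride=params.stride)
    result = dbscan_segment(matrix, params)
    result.n_frames = _strided_frame_indices(traj, params.stride).size
    return result


def _ranges(residues: list[int]) -> str:
    """Compact 'a-b,c' rendering of sorted residue numbers."""
    if not residues:
        return ""
    parts = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r == prev + 1:
            prev = r
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = r
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ",".join(parts)


def segmentation_report(result: SegmentationResult) -> pd.DataFrame:
    """Tabular summary: one row per segment plus an UNASSIGNED row, with
    residue ranges, sizes, and the fraction of all residues."""
    n_total = len(result.residue_index)
    rows = []
    for seg in range(result.n_segments):
        members = result.members(seg)
        rows.append({"segment": seg,
                     "residues": _ranges(sorted(r for _, r in members)),
                     "size": len(members),
                     "fraction": len(members) / n_total})
    unassigned = result.members(UNASSIGNED)
    rows.append({"segment": "UNASSIGNED",
                 "residues": _ranges(sorted(r for _, r in unassigned)),
                 "size": len(unassigned),
                 "fraction": len(unassigned) / n_total})
    return pd.DataFrame(rows)
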