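"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (loops, BFS,
explicit SVD) rather than reusing the package's code paths, so agreement is
evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


def naive_dbscan(matrix: np.ndarray, clr: float, cln: int,
                 include_self: bool) -> np.ndarray:
    """Plain-loop DBSCAN on a precomputed symmetric distance matrix.

    Core point: >= cln points within clr (self counted iff include_self).
    Clusters grown by breadth-first search over core-core adjacency starting
    from the lowest-index unvisited core; border points attach to the
    lowest-index core within clr; labels renumbered 0..K-1 in order of each
    cluster's first member.  UNASSIGNED = -1.
    """
    n = matrix.shape[0]
    neighbors = [set(np.flatnonzero(matrix[i] <= clr)) for i in range(n)]
    core = np.zeros(n, dtype=bool)
    for i in range(n):
        count = len(neighbors[i]) if include_self else len(neighbors[i] - {i})
        core[i] = count >= cln
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            for k in sorted(neighbors[j]):
                if core[k] and labels[k] == -1:
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        claiming = [j for j in sorted(neighbors[i]) if core[j]]
        if claiming:
            labels[i] = labels[claiming[0]]
    # renumber by first appearance
    remap: dict[int, int] = {}
    out = np.full(n, -1, dtype=int)
    for i in range(n):
        if labels[i] == -1:
            continue
        if labels[i] not in remap:
            remap[labels[i]] = len(remap)
        out[i] = remap[labels[i]]
    return out


def brute_stddev_matrix(ca_coords: np.ndarray) -> np.ndarray:
    """Population std of pairwise distances, computed with explicit loops."""
    n_frames, n_res, _ = ca_coords.shape
    out = np.zeros((n_res, n_res))
    for i in range(n_res):
        for j in range(i + 1, n_res):
            d = [float(np.sqrt(((ca_coords[f, i] - ca_coords[f, j]) ** 2).sum()))
                 for f in range(n_frames)]
            mean = sum(d) / n_frames
            var = sum((x - mean) ** 2 for x in d) / n_frames
            out[i, j] = out[j, i] = np.sqrt(var)
    return out


def torsion_atan2(p0, p1, p2, p3) -> float:
    """Textbook torsion via atan2(|b2| b1·(b2×b3), (b1×b2)·(b2×b3)), degrees."""
    b1 = np.subtract(p1, p0)
    b2 = np.subtract(p2, p1)
    b3 = np.subtract(p3, p2)
    c23 = np.cross(b2, b3)
    c12 = np.cross(b1, b2)
    angle = np.degrees(np.arctan2(np.linalg.norm(b2) * np.dot(b1, c23),
                                  np.dot(c12, c23)))
    return angle + 360.0 if angle <= -180.0 else angle


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation of mobile onto target via explicit SVD.

    Returns a function applying the transform to arbitrary points.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    def apply(points: np.ndarray) -> np.ndarray:
        return (points - mc) @ rot.T + tc

    return apply


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def leader_cluster_sizes(rmsd_matrix: np.ndarray, cutoff: float) -> list[int]:
    """Gromos-style leader clustering, explicit loops; sizes largest-first."""
    n = rmsd_matrix.shape[0]
    remaining = set(range(n))
    sizes = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if rmsd_matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = {j for j in remaining if rmsd_matrix[best, j] <= cutoff}
        sizes.append(len(members))
        remaining -= members
    return sorted(sizes, reverse=True)
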