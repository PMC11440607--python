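"""Trajectory-level geometric and occupancy descriptors.

These are the per-frame series and summary statistics used to characterize
how a peptide agonist sits in its receptor over a simulation: distances
between aromatic ring centroids (e.g. the ligand Trp indole against a
receptor Trp), side-chain χ1 rotamer populations, hydrogen-bond and
salt-bridge occupancies, the RMSD of a segment against a reference ensemble,
and the number of conformational clusters needed to cover most snapshots.

Atoms are addressed by (chain_id, residue_number, atom_name) triples in
author numbering; every operation resolves its selection against the
trajectory topology up front and rejects missing atoms by name.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajio import Trajectory

logger = logging.getLogger(__name__)

AtomId = tuple[str, int, str]  # (chain_id, residue_number, atom_name)

#: Atom names of the tryptophan indole ring.
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

#: Default geometric criteria for contacts, Å and degrees.
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0
SALTBRIDGE_DISTANCE_CUTOFF = 4.0


@dataclass(frozen=True)
class RingSelection:
    """One aromatic ring: its residue plus the ring atom names."""

    chain_id: str
    residue_number: int
    ring_atoms: tuple[str, ...] = TRP_RING_ATOMS

    def __post_init__(self) -> None:
        if len(self.ring_atoms) < 3:
            raise ValueError("a ring needs at least 3 atoms")

    def atom_ids(self) -> list[AtomId]:
        return [(self.chain_id, self.residue_number, name) for name in self.ring_atoms]


@dataclass(frozen=True)
class DihedralSpec:
    """Four ordered atoms defining a torsion; the signed angle convention is
    (-180°, 180°].  For a χ1 angle the atoms are N, Cα, Cβ, Cγ."""

    atoms: tuple[AtomId, AtomId, AtomId, AtomId]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("dihedral atoms must be distinct")


@dataclass(frozen=True)
class ContactSpec:
    """Geometric contact criterion scored per frame over all listed pairs.

    kind="hbond": donors is a list of (donor heavy atom, attached H or None);
    a pair qualifies when the heavy-atom donor–acceptor distance is within
    distance_cutoff AND, when the H is given, the D–H···A angle is at least
    angle_cutoff.  Donors without an explicit H are scored distance-only
    (logged as a downgrade).

    kind="saltbridge": donors lists cation-group nitrogens, acceptors lists
    anion-group oxygens; any N–O pair within distance_cutoff qualifies.
    """

    kind: str
    donors: tuple  # hbond: ((heavy, h|None), ...); saltbridge: (AtomId, ...)
    acceptors: tuple[AtomId, ...]
    distance_cutoff: float = 0.0
    angle_cutoff: float = HBOND_ANGLE_CUTOFF

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "saltbridge"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        cutoff = self.distance_cutoff or (
            HBOND_DISTANCE_CUTOFF if self.kind == "hbond"
            else SALTBRIDGE_DISTANCE_CUTOFF)
        if cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        object.__setattr__(self, "distance_cutoff", cutoff)
        if self.kind == "hbond" and self.angle_cutoff <= 0:
            raise ValueError("angle_cutoff must be > 0")


@dataclass
class DistributionSummary:
    n: int
    median: float
    mode: float  # center of the most populated histogram bin
    min: float
    max: float
    bin_width: float


@dataclass
class OccupancyResult:
    """Fraction of analyzed frames satisfying a contact criterion."""

    fraction: float
    n_frames: int
    equilibration_discard: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def _resolve(traj: Trajectory, atom_ids: list[AtomId]) -> np.ndarray:
    return np.array([traj.atom_index(*aid) for aid in atom_ids], dtype=int)


def centroid_distance_series(traj: Trajectory, a: RingSelection,
                             b: RingSelection) -> np.ndarray:
    """Per-frame distance between the unweighted centroids of two rings, Å."""
    idx_a = _resolve(traj, a.atom_ids())
    idx_b = _resolve(traj, b.atom_ids())
    cen_a = traj.coords[:, idx_a].mean(axis=1)
    cen_b = traj.coords[:, idx_b].mean(axis=1)
    return np.linalg.norm(cen_a - cen_b, axis=1)


def summarize_distribution(series: np.ndarray,
                           bin_width: float = 0.1) -> DistributionSummary:
    """Median (midpoint rule for even n), histogram mode, and range of a
    series.  Bins of the stated width are centered on the series minimum;
    mode ties resolve to the lowest bin."""
    series = np.asarray(series, dtype=float)
    series = series[np.isfinite(series)]
    if series.size == 0:
        raise ValueError("cannot summarize an empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = float(series.min()), float(series.max())
    n_bins = max(1, int(math.floor((hi - lo) / bin_width + 0.5)) + 1)
    edges = lo - bin_width / 2 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(series, bins=edges)
    mode = lo + bin_width * int(np.argmax(counts))
    return DistributionSummary(n=series.size, median=float(np.median(series)),
                               mode=mode, min=lo, max=hi, bin_width=bin_width)


def _torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle of four points per frame, degrees in (-180, 180];
    NaN where either bond-plane normal vanishes (collinear atoms)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of b0 and b2 perpendicular to the central bond
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    n1 = np.cross(-b0, b1)
    n2 = np.cross(b1, b2)
    angle = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    angle = np.where(bad, np.nan, angle)
    return np.where(angle <= -180.0, angle + 360.0, angle)


def dihedral_series(traj: Trajectory, spec: DihedralSpec) -> np.ndarray:
    """Per-frame signed torsion of the four spec atoms, degrees in
    (-180°, 180°].  Frames with collinear defining atoms yield NaN and are
    logged."""
    idx = _resolve(traj, list(spec.atoms))
    p = traj.coords[:, idx]
    angles = _torsion(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    n_bad = int(np.isnan(angles).sum())
    if n_bad:
        logger.warning("dihedral undefined (collinear atoms) in %d frames", n_bad)
    return angles


def classify_rotamer(angle: float) -> str:
    """χ1 rotamer class of a torsion angle.

    After normalization to (-180°, 180°]: gauche_minus on [-120°, 0°),
    gauche_plus on [0°, 120°), antiperiplanar on [120°, 180°] and
    (-180°, -120°).  The three sectors partition the circle.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    if -120.0 <= a < 0.0:
        return "gauche_minus"
    if 0.0 <= a < 120.0:
        return "gauche_plus"
    return "antiperiplanar"


def rotamer_fractions(angles: np.ndarray) -> dict[str, float]:
    """Population fraction of each χ1 class over the finite angles."""
    finite = [a for a in np.asarray(angles, dtype=float).ravel() if math.isfinite(a)]
    if not finite:
        raise ValueError("no finite angles")
    out = {"gauche_minus": 0, "gauche_plus": 0, "antiperiplanar": 0}
    for a in finite:
        out[classify_rotamer(a)] += 1
    return {k: v / len(finite) for k, v in out.items()}


def _retained_frames(traj: Trajectory, discard: float) -> np.ndarray:
    if not 0.0 <= discard < 1.0:
        raise ValueError("equilibration_discard must lie in [0, 1)")
    start = int(math.floor(discard * traj.n_frames))
    retained = np.arange(start, traj.n_frames)
    if retained.size == 0:
        raise ValueError("no frames remain after equilibration discard")
    return retained


def _pair_hits(traj: Trajectory, spec: ContactSpec,
               frames: np.ndarray) -> np.ndarray:
    """(n_frames, n_pairs) boolean matrix of satisfied donor-acceptor pairs."""
    hits = []
    downgraded = False
    if spec.kind == "saltbridge":
        pairs = [(d, a) for d in spec.donors for a in spec.acceptors]
        for donor, acceptor in pairs:
            di = traj.atom_index(*donor)
            ai = traj.atom_index(*acceptor)
            dist = np.linalg.norm(traj.coords[frames, di] - traj.coords[frames, ai],
                                  axis=1)
            hits.append(dist <= spec.distance_cutoff)
        return np.column_stack(hits)

    for heavy, hydrogen in spec.donors:
        hi = traj.atom_index(*heavy)
        hyd = traj.atom_index(*hydrogen) if hydrogen is not None else None
        if hyd is None and not downgraded:
            logger.warning("hbond donor %s has no explicit H; scoring distance-only",
                           heavy)
            downgraded = True
        for acceptor in spec.acceptors:
            ai = traj.atom_index(*acceptor)
            d_coords = traj.coords[frames, hi]
            a_coords = traj.coords[frames, ai]
            ok = np.linalg.norm(d_coords - a_coords, axis=1) <= spec.distance_cutoff
            if hyd is not None:
                h_coords = traj.coords[frames, hyd]
                v1 = d_coords - h_coords
                v2 = a_coords - h_coords
                cosang = np.sum(v1 * v2, axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                ok &= angle >= spec.angle_cutoff
            hits.append(ok)
    return np.column_stack(hits)


def contact_occupancy(traj: Trajectory, spec: ContactSpec,
                      equilibration_discard: float = 0.0) -> OccupancyResult:
    """Fraction of retained frames in which ANY listed donor-acceptor pair
    satisfies the geometric criterion."""
    frames = _retained_frames(traj, equilibration_discard)
    hits = _pair_hits(traj, spec, frames)
    return OccupancyResult(fraction=float(hits.any(axis=1).mean()),
                           n_frames=frames.size,
                           equilibration_discard=equilibration_discard)


def count_multiple_hbonds(traj: Trajectory, spec: ContactSpec, k: int,
                          equilibration_discard: float = 0.0) -> OccupancyResult:
    """Fraction of retained frames with at least k simultaneously satisfied
    donor-acceptor pairs (k=1 reduces to contact_occupancy)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    frames = _retained_frames(traj, equilibration_discard)
    hits = _pair_hits(traj, spec, frames)
    return OccupancyResult(fraction=float((hits.sum(axis=1) >= k).mean()),
                           n_frames=frames.size,
                           equilibration_discard=equilibration_discard)


def _kabsch_apply(mobile: np.ndarray, target: np.ndarray,
                  points: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` and apply the same
    rigid transform to ``points``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(points - mc) + tc


def segment_rmsd_vs_reference(
    traj: Trajectory,
    ref: Trajectory,
    fit_selection: list[AtomId],
    measure_selection: list[AtomId],
) -> float:
    """Mean RMSD of a segment against a reference ensemble, Å.

    The reference ensemble is reduced to its average structure after
    superposing every reference frame onto the first on the fit selection;
    each trajectory frame is then least-squares fitted onto that average on
    the fit selection, and the RMSD is measured over the measure selection.
    The fit region thus anchors the frame (typically the receptor core) while
    the measured region (typically the ligand) is free to deviate.
    """
    fit_t = _resolve(traj, fit_selection)
    mea_t = _resolve(traj, measure_selection)
    fit_r = _resolve(ref, fit_selection)
    mea_r = _resolve(ref, measure_selection)

    both = np.concatenate([fit_r, mea_r])
    aligned = np.empty((ref.n_frames, both.size, 3))
    target0 = ref.coords[0, fit_r]
    for k in range(ref.n_frames):
        aligned[k] = _kabsch_apply(ref.coords[k, fit_r], target0,
                                   ref.coords[k, both])
    ref_mean = aligned.mean(axis=0)
    ref_fit = ref_mean[: fit_r.size]
    ref_mea = ref_mean[fit_r.size:]

    rmsds = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        moved = _kabsch_apply(traj.coords[k, fit_t], ref_fit, traj.coords[k, mea_t])
        rmsds[k] = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
    return float(rmsds.mean())


def _pairwise_ca_rmsd(traj: Trajectory) -> np.ndarray:
    """All-vs-all Cα RMSD after pairwise least-squares superposition."""
    _, ca = traj.ca_indices()
    xyz = traj.coords[:, ca]
    centered = xyz - xyz.mean(axis=1, keepdims=True)
    n = traj.n_frames
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, rssd = Rotation.align_vectors(centered[i], centered[j])
            rmsd[i, j] = rmsd[j, i] = rssd / np.sqrt(ca.size)
    return rmsd


def cluster_coverage_count(traj: Trajectory, rmsd_cutoff: float,
                           coverage: float = 0.95) -> int:
    """Number of leader-clustering conformers covering a population fraction.

    Gromos-style leader clustering on the pairwise fitted Cα RMSD matrix:
    repeatedly take the frame with the most unclustered neighbors within the
    cutoff as a center (ties to the lowest frame index), remove its cluster,
    and continue.  Returns the minimal number of clusters, largest first,
    whose cumulative population reaches ``coverage`` of all frames.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be > 0")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    rmsd = _pairwise_ca_rmsd(traj)
    within = rmsd <= rmsd_cutoff
    remaining = np.ones(traj.n_frames, dtype=bool)
    sizes: list[int] = []
    while remaining.any():
        counts = (within & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = within[center] & remaining
        sizes.append(int(members.sum()))
        remaining &= ~members
    sizes.sort(reverse=True)
    needed = coverage * traj.n_frames
    cum = 0
    for k, size in enumerate(sizes, start=1):
        cum += size
        if cum >= needed - 1e-9:
            return k
    return len(sizes)
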