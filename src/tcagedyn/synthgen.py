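"""Synthetic data with known ground truth for every analysis stage.

Four generators mirror the four experimental inputs the pipeline consumes:

* hinge trajectories — quasi-rigid bodies of residues placed on an ideal
  α-helical Cα template, rotated against each other about random hinge axes
  with Gaussian amplitudes and dressed with per-atom positional jitter;
* chemical-shift tables — random-coil references plus injected helical and
  ring-current secondary shifts and Gaussian noise;
* NOESY peak lists — volumes following the d^-6 law around a reference
  (distance, volume) anchor, with multiplicative noise;
* melting series — sigmoid-in-temperature descriptor values.

Everything is deterministic for a given seed, and the injected ground truth
is always returned (or derivable from the spec) so downstream recovery can
be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nmrfold import RANDOM_COIL_HA, MeltingSeries, ShiftTable
from .noecalib import Peak, PeakList
from .trajio import AtomRecord, Trajectory

#: Ideal α-helix Cα trace: rise per residue (Å), twist per residue (deg),
#: helix radius (Å).
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3

#: Perpendicular displacement of flexible-linker templates off the
#: inter-body axis (Å), mimicking the bulge of a disordered loop.
BULGE_OFFSET = 6.0

#: Random-coil shifts for non-Hα protons named in ring-current perturbation
#: lists (ppm); Hα values come from nmrfold.RANDOM_COIL_HA.
RANDOM_COIL_OTHER: dict[str, float] = {
    "HE1": 10.10,  # Trp indole NH
    "HA2": 3.97, "HA3": 3.97,  # Gly
    "HB2": 2.05, "HB3": 2.05,
    "HD1": 3.65, "HD2": 3.65, "HD3": 3.65,
}


@dataclass(frozen=True)
class BodyRange:
    """Contiguous residue range (author numbering, inclusive) forming one
    quasi-rigid body or one flexible linker, with its internal jitter σ (Å)."""

    start: int
    end: int
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"range {self.start}-{self.end} is empty")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class RigidBodySpec:
    """Ground-truth decomposition: rigid bodies, flexible linkers, and the
    hinge amplitude (σ of the Gaussian rotation angle, degrees) applied at
    each joint between consecutive bodies."""

    bodies: list[BodyRange]
    linkers: list[BodyRange] = field(default_factory=list)
    #: σ of the Gaussian hinge angle, degrees; a scalar applies to every
    #: joint, a sequence gives one amplitude per joint (n_bodies - 1 values).
    hinge_amplitude: float | list[float] = 0.0

    def __post_init__(self) -> None:
        if not self.bodies:
            raise ValueError("need at least one body")
        amps = self.hinge_amplitudes()
        if any(a < 0 for a in amps):
            raise ValueError("hinge_amplitude must be >= 0")
        claimed: set[int] = set()
        for rng in [*self.bodies, *self.linkers]:
            overlap = claimed & set(rng.residues)
            if overlap:
                raise ValueError(f"overlapping residue ranges at {sorted(overlap)}")
            claimed.update(rng.residues)

    def hinge_amplitudes(self) -> list[float]:
        """Per-joint amplitudes, broadcasting a scalar to every joint."""
        n_joints = max(len(self.bodies) - 1, 0)
        if isinstance(self.hinge_amplitude, (int, float)):
            return [float(self.hinge_amplitude)] * n_joints
        amps = [float(a) for a in self.hinge_amplitude]
        if len(amps) != n_joints:
            raise ValueError(f"expected {n_joints} hinge amplitudes, got {len(amps)}")
        return amps

    def all_residues(self) -> list[int]:
        return sorted(set().union(*(r.residues for r in [*self.bodies, *self.linkers])))

    def body_of(self, residue: int) -> int | None:
        """Index of the body owning ``residue``, or None for a linker residue."""
        for k, body in enumerate(self.bodies):
            if residue in body.residues:
                return k
        return None


@dataclass(frozen=True)
class SimSpec:
    n_frames: int
    frame_interval: float = 100.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


def _helix_template(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.deg2rad(HELIX_TWIST * k)
    return np.column_stack([HELIX_RADIUS * np.cos(phi),
                            HELIX_RADIUS * np.sin(phi),
                            HELIX_RISE * k])


def _rotation_about(axis: np.ndarray, pivot: np.ndarray, angle_rad: float):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(axis * angle_rad)

    def apply(points: np.ndarray) -> np.ndarray:
        return rot.apply(points - pivot) + pivot

    return apply


def generate_hinge_trajectory(spec: RigidBodySpec, sim: SimSpec) -> Trajectory:
    """Cα-only trajectory of quasi-rigid bodies moving about shared hinges.

    Template geometry.  Body residues lie on an ideal helical Cα trace; the
    chain steps 1.5 Å per residue inside a body and 3.5 Å (extended) across
    flexible regions.  Flexible linker residues detour ~6 Å off the
    inter-body axis (a perpendicular bulge, direction drawn per linker per
    seed), as disordered loops do, and the template is statically kinked by
    90° about each hinge axis so the resting arrangement is non-collinear —
    a straight chain would hide hinge bending from internal distances to
    first order.

    Per-frame motion.  Each joint between consecutive bodies rotates
    everything downstream of the first body's C-terminus about a hinge axis
    (unit vector drawn once per joint per seed) through the midpoint between
    the adjacent body termini, by an angle ~ N(0, hinge_amplitude).  Linker
    residues sitting in a hinge gap do not ride rigidly with the downstream
    body: each draws its own independent angle about the same axis every
    frame, modelling a melted hinge whose residues move freely.  Isotropic
    per-atom Gaussian jitter with each range's own σ is added last.
    Bit-identical for identical spec and seed.
    """
    rng = np.random.default_rng(sim.seed)
    residues = spec.all_residues()
    n_res = len(residues)
    pos_of = {res: i for i, res in enumerate(residues)}
    bodies = sorted(spec.bodies, key=lambda b: b.start)
    body_residues = set().union(*(set(b.residues) for b in bodies))

    # chain template: helix inside bodies, extended steps elsewhere
    template = np.zeros((n_res, 3))
    phi = 0.0
    z = 0.0
    for i, res in enumerate(residues):
        if i > 0:
            in_body = res in body_residues and (res - 1) in body_residues and \
                spec.body_of(res) == spec.body_of(res - 1)
            z += HELIX_RISE if in_body else 3.5
            phi += math.radians(HELIX_TWIST)
        if res in body_residues:
            template[i] = (HELIX_RADIUS * math.cos(phi),
                           HELIX_RADIUS * math.sin(phi), z)
        else:
            template[i] = (0.0, 0.0, z)

    amplitudes = spec.hinge_amplitudes()
    joints = []
    in_gap: set[int] = set()
    for (left, right), amp in zip(zip(bodies, bodies[1:]), amplitudes):
        a = template[pos_of[left.end]]
        b = template[pos_of[right.start]]
        pivot = 0.5 * (a + b)
        chain_dir = (b - a) / np.linalg.norm(b - a)
        # bending axis: random orientation within the plane perpendicular to
        # the inter-body direction (an axis along the chain would be a twist
        # and leave internal distances unchanged to first order)
        raw = rng.normal(size=3)
        axis = raw - chain_dir * (raw @ chain_dir)
        axis /= np.linalg.norm(axis)
        # a melted hinge bends in a cone, not about one fixed line: a second
        # perpendicular bending axis removes orientations in which some
        # residue pair would be blind to the motion
        axis2 = np.cross(axis, chain_dir)
        axis2 /= np.linalg.norm(axis2)
        gap = [pos_of[r] for r in range(left.end + 1, right.start)
               if r in pos_of]  # melted-hinge residues between the termini
        in_gap.update(gap)
        # bulge the gap linker off the inter-body axis, within the swing plane
        for g in gap:
            template[g] += BULGE_OFFSET * axis2
        # static 90° kink: downstream bodies rest at an angle
        downstream = slice(pos_of[left.end] + 1, n_res)
        template[downstream] = _rotation_about(axis, pivot, np.pi / 2)(
            template[downstream])
        joints.append((pos_of[left.end], (axis, axis2), pivot, np.deg2rad(amp),
                       np.array(gap, dtype=int)))

    # flexible residues outside any hinge gap (terminal tails): random
    # perpendicular bulge, jitter only
    for linker in spec.linkers:
        tail = [pos_of[r] for r in linker.residues if pos_of[r] not in in_gap]
        if tail:
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            for g in tail:
                template[g][:2] += BULGE_OFFSET * direction

    sigma = np.zeros(n_res)
    for body in [*spec.bodies, *spec.linkers]:
        for res in body.residues:
            sigma[pos_of[res]] = body.jitter

    frames = np.empty((sim.n_frames, n_res, 3))
    for f in range(sim.n_frames):
        xyz = template.copy()
        for split_pos, (axis, axis2), pivot, amp_rad, gap in joints:
            if amp_rad > 0:
                angles = rng.normal(0.0, amp_rad, size=2)
                own = rng.normal(0.0, amp_rad, size=(gap.size, 2))
            else:
                angles = np.zeros(2)
                own = np.zeros((gap.size, 2))
            downstream = slice(split_pos + 1, n_res)
            saved_gap = xyz[gap]
            moved = _rotation_about(axis, pivot, angles[0])(xyz[downstream])
            xyz[downstream] = _rotation_about(axis2, pivot, angles[1])(moved)
            for k, g in enumerate(gap):
                point = _rotation_about(axis, pivot, own[k, 0])(saved_gap[k])
                xyz[g] = _rotation_about(axis2, pivot, own[k, 1])(point)
        jitter = rng.normal(size=(n_res, 3)) * sigma[:, None]
        frames[f] = xyz + jitter

    atoms = [AtomRecord("CA", "ALA", res, "A") for res in residues]
    return Trajectory(atoms=atoms, coords=frames,
                      frame_interval=sim.frame_interval, label="synthetic-hinge")


def generate_shift_table(
    sequence: list[tuple[int, str]],
    helix_scs: dict[int, float],
    ring_current_scs: dict[tuple[int, str], float],
    noise_sd: float,
    seed: int,
) -> tuple[ShiftTable, ShiftTable, dict[tuple[int, str], float]]:
    """Observed and random-coil shift tables with known injected SCS.

    sequence: (residue_number, 3-letter code) pairs in author numbering.
    helix_scs: per-residue Hα secondary shift (ppm), applied to HA (HA2/HA3
    for Gly).  ring_current_scs: per-proton secondary shift for explicitly
    named protons (e.g. (25, "HE1")); protons not already generated as Hα are
    added with literature random-coil values.  observed = random-coil +
    injected + N(0, noise_sd); the injected ground truth is returned so
    recovery is assertable (exactly so at noise 0).
    """
    resname_of = dict(sequence)
    for res in helix_scs:
        if res not in resname_of:
            raise ValueError(f"helix SCS names residue {res} absent from sequence")
    for res, atom in ring_current_scs:
        if res not in resname_of:
            raise ValueError(f"ring-current SCS names residue {res} absent from sequence")

    rc: dict[tuple[int, str], float] = {}
    for res, name in sequence:
        protons = ("HA2", "HA3") if name == "GLY" else ("HA",)
        for atom in protons:
            base = RANDOM_COIL_HA.get(name)
            if base is None:
                raise ValueError(f"unknown residue type {name!r}")
            rc[(res, atom)] = base if atom == "HA" else RANDOM_COIL_OTHER[atom]
    for (res, atom) in ring_current_scs:
        if (res, atom) not in rc:
            if atom not in RANDOM_COIL_OTHER:
                raise ValueError(f"no random-coil reference for proton {atom!r}")
            rc[(res, atom)] = RANDOM_COIL_OTHER[atom]

    truth: dict[tuple[int, str], float] = {key: 0.0 for key in rc}
    for res, value in helix_scs.items():
        protons = ("HA2", "HA3") if resname_of[res] == "GLY" else ("HA",)
        for atom in protons:
            truth[(res, atom)] += value
    for key, value in ring_current_scs.items():
        truth[key] += value

    rng = np.random.default_rng(seed)
    observed = {}
    for key in sorted(rc):
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        observed[key] = rc[key] + truth[key] + noise
    return (ShiftTable(entries=observed, label="synthetic-observed"),
            ShiftTable(entries=dict(sorted(rc.items())), label="synthetic-random-coil"),
            truth)


def generate_peak_list(
    distances: dict[tuple[int, str, int, str], float],
    v_ref: float,
    d_ref: float,
    seed: int,
    noise_frac: float = 0.0,
) -> PeakList:
    """NOESY peak list with volumes V = v_ref·(d_ref/d)^6·(1+ε), ε~N(0, noise_frac).

    distances maps (res_i, atom_i, res_j, atom_j) to the true interproton
    distance in Å (must be > 0).  Noise draws follow sorted key order, so the
    list is reproducible per seed.
    """
    if v_ref <= 0 or d_ref <= 0:
        raise ValueError("v_ref and d_ref must be > 0")
    rng = np.random.default_rng(seed)
    peaks = []
    for key in sorted(distances):
        d = distances[key]
        if d <= 0:
            raise ValueError(f"non-positive distance {d} for pair {key}")
        eps = rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0
        volume = v_ref * (d_ref / d) ** 6 * (1.0 + eps)
        if volume <= 0:  # extreme noise draw; resample deterministically
            volume = v_ref * (d_ref / d) ** 6 * abs(1.0 + eps)
        ri, ai, rj, aj = key
        peaks.append(Peak(ri, ai, rj, aj, volume))
    return PeakList(peaks=peaks, label="synthetic-peaks")


def melting_sigmoid(t: np.ndarray | float, start_value: float, end_value: float,
                    midpoint: float, steepness: float) -> np.ndarray | float:
    """Logistic melting model: start_value at low T, end_value at high T,
    half transition at ``midpoint`` °C, width set by ``steepness`` (°C)."""
    return start_value + (end_value - start_value) / (
        1.0 + np.exp(-(np.asarray(t, dtype=float) - midpoint) / steepness))


def generate_melting_series(
    t_grid: list[float] | np.ndarray,
    start_value: float,
    end_value: float,
    midpoint: float,
    steepness: float,
    noise_sd: float,
    seed: int,
    kind: str = "melting",
    label: str = "synthetic-melting",
) -> MeltingSeries:
    """Sigmoid-in-temperature descriptor series plus Gaussian noise.

    Monotone when noise_sd = 0 (decreasing when start > end).  Requires a
    strictly increasing grid of at least 3 temperatures.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 temperatures")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    values = np.asarray(melting_sigmoid(t, start_value, end_value,
                                        midpoint, steepness))
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return MeltingSeries(kind=kind, temperatures=t, values=values, label=label)
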