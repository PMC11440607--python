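"""Secondary-chemical-shift fold descriptors and melting-curve normalization.

The degree of folding of a Trp-cage (Tc) miniprotein is monitored here by two
NMR-derived descriptors and two CD-derived descriptors, all of which are
melted over temperature and put on a common scale:

* ``SCS_helix`` — sum of absolute Hα secondary chemical shifts over the
  N-terminal helical window, reporting on helicity.
* ``SCS_Tc`` — sum of secondary chemical shifts of the protons most affected
  by the ring current of the caged tryptophan indole, reporting on tertiary
  cage compactness.
* ``[Θ222nm]_MR`` — mean-residue molar ellipticity at 222 nm (helicity by CD).
* ``F%`` — folded fraction from CD spectrum deconvolution (consumed as an
  input; the deconvolution itself is out of scope).

A secondary chemical shift is the deviation of an observed shift from its
random-coil reference, SCS = δ_obs − δ_rc.  Because the four descriptors have
unrelated units, each melting series is divided by the value of a designated
reference variant at that method's lowest temperature, so the reference point
maps to exactly 1 and curves from different techniques become comparable.

Residue numbering follows the full-length agonist (Ex4) scheme throughout;
the truncated 25-mer constructs retain residues 15-39, so helical residues
16-27 in Ex4 numbering are residues 2-13 of the truncated chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Protons whose chemical shifts are perturbed by the Trp indole ring current
#: and therefore report on cage compactness (Ex4 numbering; the indole NH
#: proton of W25 appears once even though it anchors the whole set).
TC_PROTON_SET: frozenset[tuple[int, str]] = frozenset(
    {
        (25, "HE1"),  # W25 indole NH
        (21, "HA"),
        (30, "HA2"),
        (31, "HB2"),
        (35, "HA"),
        (37, "HA"),
        (37, "HB2"),
        (38, "HD1"),
        (38, "HD2"),
    }
)

#: Default Ex4-numbering window of the N-terminal helix used for SCS_helix.
HELIX_WINDOW: tuple[int, int] = (16, 27)

#: Random-coil Hα chemical shifts (ppm) by 3-letter residue code, standard
#: literature reference values for unstructured peptides.
RANDOM_COIL_HA: dict[str, float] = {
    "ALA": 4.35, "ARG": 4.38, "ASN": 4.75, "ASP": 4.76, "CYS": 4.69,
    "GLN": 4.37, "GLU": 4.29, "GLY": 3.97, "HIS": 4.63, "ILE": 4.23,
    "LEU": 4.38, "LYS": 4.36, "MET": 4.52, "PHE": 4.66, "PRO": 4.44,
    "SER": 4.50, "THR": 4.35, "TRP": 4.70, "TYR": 4.60, "VAL": 4.18,
}


@dataclass
class ShiftTable:
    """Chemical shifts keyed by (residue_number, atom_name), in ppm."""

    entries: dict[tuple[int, str], float]
    temperature: float | None = None  # °C
    label: str = ""

    def __post_init__(self) -> None:
        for key, ppm in self.entries.items():
            if not math.isfinite(ppm):
                raise ValueError(f"non-finite chemical shift for {key}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SCSResult:
    """Per-proton secondary chemical shifts δ_obs − δ_rc (ppm)."""

    scs: dict[tuple[int, str], float]
    observed_label: str = ""
    random_coil_label: str = ""


@dataclass
class FoldDescriptorSeries:
    """One fold descriptor measured over a temperature grid.

    kind is one of {"SCS_helix", "SCS_Tc", "theta222", "folded_fraction"}.
    Temperatures are °C, strictly increasing.
    """

    kind: str
    temperatures: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.size < 1 or self.temperatures.size != self.values.size:
            raise ValueError("series needs >= 1 (temperature, value) point")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


#: A raw melting series (temperature vs descriptor value) shares the container
#: of a fold-descriptor series; ``kind`` then names the measured quantity.
MeltingSeries = FoldDescriptorSeries


@dataclass
class NormalizedSeries(FoldDescriptorSeries):
    """A FoldDescriptorSeries divided by a recorded reference value."""

    reference_label: str = ""
    reference_temperature: float = float("nan")
    reference_value: float = float("nan")


def compute_scs(observed: ShiftTable, random_coil: ShiftTable) -> SCSResult:
    """Per-proton secondary chemical shifts, SCS = δ_obs − δ_rc.

    Only protons present in both tables contribute; one-sided protons are
    dropped with a log message.  Raises ValueError if the tables share no
    proton at all.
    """
    common = observed.entries.keys() & random_coil.entries.keys()
    if not common:
        raise ValueError("observed and random-coil tables share no proton")
    dropped = (observed.entries.keys() | random_coil.entries.keys()) - common
    if dropped:
        logger.info("compute_scs: %d protons present in only one table, dropped",
                    len(dropped))
    scs = {key: observed.entries[key] - random_coil.entries[key]
           for key in sorted(common)}
    return SCSResult(scs=scs, observed_label=observed.label,
                     random_coil_label=random_coil.label)


def scs_helix(scs: SCSResult, window: tuple[int, int] = HELIX_WINDOW) -> float:
    """Helicity descriptor: Σ |SCS(Hα)| over the helical residue window.

    Gly contributes through its HA2/HA3 protons.  Residues of the window with
    no Hα entry are logged and skipped; an entirely uncovered window raises.
    """
    lo, hi = window
    total = 0.0
    covered: set[int] = set()
    for (res, atom), value in scs.scs.items():
        if lo <= res <= hi and atom in ("HA", "HA2", "HA3"):
            total += abs(value)
            covered.add(res)
    if not covered:
        raise ValueError(f"no Hα SCS within window {lo}-{hi}")
    missing = set(range(lo, hi + 1)) - covered
    if missing:
        logger.info("scs_helix: %d window residues lack Hα SCS: %s",
                    len(missing), sorted(missing))
    return total


def scs_tc(
    scs: SCSResult,
    proton_set: frozenset[tuple[int, str]] = TC_PROTON_SET,
    mode: str = "absolute",
) -> float:
    """Cage-compactness descriptor: sum of SCS over the ring-current proton set.

    mode="absolute" (default) sums |SCS|, mirroring the SCS_helix convention;
    mode="signed" sums the raw values.  The coverage fraction of the proton
    set is logged; at least one listed proton must be present.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    present = [scs.scs[key] for key in sorted(proton_set) if key in scs.scs]
    if not present:
        raise ValueError("none of the cage protons has an SCS value")
    coverage = len(present) / len(proton_set)
    logger.info("scs_tc: coverage %.2f (%d/%d protons)",
                coverage, len(present), len(proton_set))
    if mode == "absolute":
        return float(sum(abs(v) for v in present))
    return float(sum(present))


def mean_residue_ellipticity(
    raw_mdeg: float, concentration: float, path_length: float, n_residues: int
) -> float:
    """Convert raw CD ellipticity (mdeg) to mean-residue molar ellipticity.

    [Θ]_MR = θ_raw / (10 · c · l · N) with c in mol/L, l in cm, N the residue
    count; the result carries deg·cm²·dmol⁻¹.
    """
    if concentration <= 0 or path_length <= 0 or n_residues <= 0:
        raise ValueError("concentration, path length and residue count must be > 0")
    return raw_mdeg / (10.0 * concentration * path_length * n_residues)


def normalize_series(
    series: FoldDescriptorSeries, reference: FoldDescriptorSeries
) -> NormalizedSeries:
    """Divide a descriptor series by the reference variant's value at the
    reference's lowest temperature.

    The reference is per method (per descriptor kind), so methods with
    different temperature grids each anchor to their own lowest-temperature
    reference point, which maps to exactly 1.
    """
    ref_t = float(reference.temperatures[0])
    ref_v = float(reference.values[0])
    if ref_v == 0.0:
        raise ValueError("reference value at lowest temperature is zero")
    return NormalizedSeries(
        kind=series.kind,
        temperatures=series.temperatures.copy(),
        values=series.values / ref_v,
        label=series.label,
        reference_label=reference.label,
        reference_temperature=ref_t,
        reference_value=ref_v,
    )


def crossing_temperature(norm: FoldDescriptorSeries, level: float = 1.0) -> float | None:
    """Lowest temperature at which the series attains ``level``.

    Linear interpolation between adjacent grid points; exact grid hits are
    returned as-is; None if the level is never attained.  Needs >= 2 points.
    """
    t = norm.temperatures
    v = norm.values
    if t.size < 2:
        raise ValueError("crossing needs at least 2 points")
    for k in range(t.size):
        if v[k] == level:
            return float(t[k])
        if k + 1 < t.size and (v[k] - level) * (v[k + 1] - level) < 0:
            frac = (level - v[k]) / (v[k + 1] - v[k])
            return float(t[k] + frac * (t[k + 1] - t[k]))
    return None


def value_at_temperature(norm: FoldDescriptorSeries, t: float) -> float:
    """Linearly interpolated descriptor value at temperature t (°C).

    Exact at grid points; extrapolation outside the measured range raises.
    """
    grid = norm.temperatures
    if t < grid[0] or t > grid[-1]:
        raise ValueError(
            f"temperature {t} outside measured range [{grid[0]}, {grid[-1]}]")
    return float(np.interp(t, grid, norm.values))
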