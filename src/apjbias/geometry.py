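"""Geometric observables on structures and trajectories.

Covers the standard MD-analysis toolbox used to diagnose receptor
conformation: optimal rigid-body superposition (Kabsch) and RMSD traces,
atom-pair distance series, geometric hydrogen-bond detection, Shrake-Rupley
solvent-accessible surface area with a Monte-Carlo occupied-volume estimate,
ligand-contact residues, and van-der-Waals steric-clash checks.

Distances are in Angstrom throughout; RMSD helpers for clustering convert
to nm at the clustering boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, MissingResidueError, SelectionError
from .structio import Atom, Structure, Trajectory, residue_atom_indices

__all__ = [
    "HBondCriterion", "DistanceSeries", "HBondSeries", "HBond", "SasaResult",
    "ClashReport", "kabsch_superpose", "apply_transform", "rmsd_trace",
    "pair_distance_series", "mean_distance", "window_occupancy",
    "detect_hbonds", "hbond_series", "sasa", "residue_contacts",
    "clash_check", "truncate_report",
]


def truncate_report(value: float, decimals: int = 2) -> float:
    """Truncate toward zero at a fixed number of decimals.

    Summary distances in this package's reports are truncated rather than
    rounded, matching the tabulation convention of the reference distance
    tables the bias diagnostic reproduces.
    """
    scale = 10 ** decimals
    return math.trunc(value * scale) / scale


# ---------------------------------------------------------------------------
# Series containers

@dataclass
class DistanceSeries:
    """A per-frame scalar observable (distance or RMSD) in Angstrom."""

    pair_label: str
    times_ns: np.ndarray
    distances_A: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.distances_A = np.asarray(self.distances_A, dtype=float)
        if self.times_ns.shape != self.distances_A.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances_A < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times_ns)


@dataclass
class HBondSeries:
    """Per-frame hydrogen-bond counts."""

    times_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times_ns.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    Defaults follow the common MD convention: donor-acceptor distance
    <= 3.5 A and hydrogen-donor-acceptor angle <= 30 deg.  The optimal
    window (2.7-3.3 A) is the distance band used for occupancy-style
    diagnostics of near-ideal bonds.
    """

    donor_acceptor_cutoff: float = 3.5
    angle_cutoff_deg: float = 30.0
    optimal_window: tuple[float, float] = (2.7, 3.3)

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0 or self.angle_cutoff_deg <= 0:
            raise ValueError("cutoffs must be positive")
        lo, hi = self.optimal_window
        if not lo < hi:
            raise ValueError("optimal window must satisfy lower < upper")


@dataclass
class HBond:
    donor: int
    hydrogen: Optional[int]
    acceptor: int
    distance_A: float
    angle_deg: Optional[float]
    distance_only: bool


@dataclass
class SasaResult:
    area_A2: float
    per_atom_area: np.ndarray
    volume_A3: Optional[float] = None
    volume_se_A3: Optional[float] = None


@dataclass
class ClashReport:
    min_distance_A: float
    overlapping_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    tolerance_A: float = 0.4

    @property
    def clash(self) -> bool:
        return len(self.overlapping_pairs) > 0


# ---------------------------------------------------------------------------
# Superposition / RMSD

def _paired_coords(obj, indices) -> np.ndarray:
    if isinstance(obj, Structure):
        xyz = obj.coords
    else:
        xyz = np.asarray(obj, dtype=float)
    if indices is not None:
        xyz = xyz[np.asarray(indices, dtype=int)]
    return xyz


def _check_nondegenerate(xyz: np.ndarray) -> None:
    if xyz.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs >= 3 paired atoms")
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("paired atoms are (near-)collinear")


def kabsch_superpose(
    mobile: Union[Structure, np.ndarray],
    reference: Union[Structure, np.ndarray],
    mobile_indices: Optional[Sequence[int]] = None,
    reference_indices: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired atom sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``x @ rotation.T + translation`` maps mobile coordinates onto the
    reference frame with minimal least-squares deviation; the rotation is
    proper (det +1).  The Kabsch solution is delegated to
    :func:`scipy.spatial.transform.Rotation.align_vectors` on centred
    coordinates.
    """
    P = _paired_coords(mobile, mobile_indices)
    Q = _paired_coords(reference, reference_indices)
    if P.shape != Q.shape:
        raise DegenerateGeometryError("paired selections must have equal length")
    _check_nondegenerate(P)
    _check_nondegenerate(Q)
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - q_mean, P - p_mean)
    R = rot.as_matrix()
    t = q_mean - R @ p_mean
    # recompute the deviation from the transform itself: more accurate than
    # the solver's reported residual for (near-)exact matches
    moved = P @ R.T + t
    rmsd = math.sqrt(float(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd_trace(
    traj: Trajectory,
    fit_selection: Sequence[int],
    measure_selection: Optional[Sequence[int]] = None,
) -> DistanceSeries:
    """Per-frame RMSD against frame 1 after superposing on ``fit_selection``.

    Each frame is rigid-body fitted onto the first frame using the fit
    selection; the RMSD is then measured on ``measure_selection`` (defaults
    to the fit selection).  The first frame's value is exactly zero.
    """
    fit = np.asarray(fit_selection, dtype=int)
    if fit.size == 0:
        raise SelectionError("fit selection is empty")
    meas = fit if measure_selection is None else np.asarray(measure_selection, int)
    if meas.size == 0:
        raise SelectionError("measure selection is empty")
    ref_fit = traj.frames[0][fit]
    ref_meas = traj.frames[0][meas]
    out = np.empty(traj.n_frames)
    out[0] = 0.0
    for i in range(1, traj.n_frames):
        R, t, _ = kabsch_superpose(traj.frames[i][fit], ref_fit)
        moved = apply_transform(traj.frames[i][meas], R, t)
        out[i] = math.sqrt(float(np.mean(np.sum((moved - ref_meas) ** 2, axis=1))))
    return DistanceSeries("rmsd_vs_frame1", traj.times_ns.copy(), out)


# ---------------------------------------------------------------------------
# Distances

def pair_distance_series(traj: Trajectory, atom_a: int, atom_b: int,
                         label: str = "") -> DistanceSeries:
    """Euclidean distance between two atoms per frame."""
    n = len(traj.topology)
    for idx in (atom_a, atom_b):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    d = np.linalg.norm(traj.frames[:, atom_a] - traj.frames[:, atom_b], axis=1)
    if not label:
        a, b = traj.topology.atoms[atom_a], traj.topology.atoms[atom_b]
        label = f"{a.residue_label}:{a.atom_name}-{b.residue_label}:{b.atom_name}"
    return DistanceSeries(label, traj.times_ns.copy(), d)


def mean_distance(series: DistanceSeries,
                  subsample_times: Optional[Sequence[float]] = None) -> float:
    """Arithmetic mean of a distance series, optionally at selected times.

    The full-precision mean is returned; reports truncate it to two
    decimals via :func:`truncate_report`.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    if subsample_times is None:
        return float(np.mean(series.distances_A))
    values = []
    for t in subsample_times:
        hits = np.flatnonzero(np.isclose(series.times_ns, t, rtol=0, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"time {t} ns not present in series")
        values.append(series.distances_A[hits[0]])
    return float(np.mean(values))


def window_occupancy(series: DistanceSeries,
                     window: tuple[float, float]) -> float:
    """Fraction of frames whose distance lies inside the closed window."""
    if len(series) == 0:
        raise ValueError("series is empty")
    lo, hi = window
    inside = (series.distances_A >= lo) & (series.distances_A <= hi)
    return float(np.mean(inside))


# ---------------------------------------------------------------------------
# Hydrogen bonds

_H_BOND_LENGTH_MAX = 1.25  # A; covalent D-H association by proximity


def _donor_hydrogens(frame: Structure, donor_idx: int) -> list[int]:
    """Hydrogens covalently associated with a donor heavy atom.

    Association is geometric: a hydrogen of the same residue within
    1.25 A of the donor.  This covers the usual naming conventions
    (OH<->HH, N<->H, OG<->HG, ...) without a bonded topology.
    """
    donor = frame.atoms[donor_idx]
    out = []
    for i, a in enumerate(frame.atoms):
        if a.element.upper() != "H":
            continue
        if (a.chain_id, a.residue_number) != (donor.chain_id, donor.residue_number):
            continue
        if np.linalg.norm(a.coords - donor.coords) <= _H_BOND_LENGTH_MAX:
            out.append(i)
    return out


def detect_hbonds(
    frame: Structure,
    criterion: HBondCriterion,
    donors: Sequence[int],
    acceptors: Sequence[int],
) -> list[HBond]:
    """Geometric hydrogen bonds between donor and acceptor heavy atoms.

    A bond is reported iff the donor-acceptor distance is within the
    cutoff and, when the donor carries at least one hydrogen, the best
    hydrogen-donor-acceptor angle is within the angle cutoff.  Donors
    without hydrogens fall back to the distance criterion alone and the
    bond is flagged ``distance_only``.
    """
    bonds: list[HBond] = []
    for d in donors:
        d_atom = frame.atoms[d]
        hydrogens = _donor_hydrogens(frame, d)
        for a in acceptors:
            if a == d:
                continue
            a_atom = frame.atoms[a]
            dist = float(np.linalg.norm(a_atom.coords - d_atom.coords))
            if dist > criterion.donor_acceptor_cutoff:
                continue
            if not hydrogens:
                bonds.append(HBond(d, None, a, dist, None, True))
                continue
            best_h, best_angle = None, None
            for h in hydrogens:
                v_h = frame.atoms[h].coords - d_atom.coords
                v_a = a_atom.coords - d_atom.coords
                denom = np.linalg.norm(v_h) * np.linalg.norm(v_a)
                if denom == 0:
                    continue
                cosang = float(np.clip(np.dot(v_h, v_a) / denom, -1.0, 1.0))
                ang = math.degrees(math.acos(cosang))
                if best_angle is None or ang < best_angle:
                    best_h, best_angle = h, ang
            if best_angle is not None and best_angle <= criterion.angle_cutoff_deg:
                bonds.append(HBond(d, best_h, a, dist, best_angle, False))
    return bonds


def hbond_series(
    traj: Trajectory,
    criterion: HBondCriterion,
    donors: Sequence[int],
    acceptors: Sequence[int],
) -> HBondSeries:
    """Per-frame hydrogen-bond counts over a trajectory."""
    counts = np.array(
        [len(detect_hbonds(traj.frame_structure(i), criterion, donors, acceptors))
         for i in range(traj.n_frames)],
        dtype=int,
    )
    return HBondSeries(traj.times_ns.copy(), counts)


# ---------------------------------------------------------------------------
# SASA and occupied volume

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    volume_samples: int = 0,
    seed: int = 0,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's expanded sphere (vdW radius + probe) is sampled with a
    deterministic golden-spiral point set; a point is accessible when it
    lies outside every neighbouring expanded sphere.  With
    ``volume_samples > 0`` the solvent-excluded occupied volume of the
    union of expanded spheres is estimated by seeded Monte-Carlo
    integration over the bounding box, and reported with its standard
    error.
    """
    if len(structure) == 0:
        raise ValueError("cannot compute SASA of an empty structure")
    centers = structure.coords
    radii = np.array([a.vdw_radius for a in structure.atoms]) + probe_radius
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(centers)
    max_r = radii.max()
    per_atom = np.zeros(len(structure))
    for i in range(len(structure)):
        pts = centers[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(centers[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            diff = pts[:, None, :] - centers[neighbors][None, :, :]
            buried = np.any(
                np.sum(diff * diff, axis=2) < (radii[neighbors] ** 2)[None, :],
                axis=1,
            )
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * frac

    volume = vol_se = None
    if volume_samples > 0:
        rng = np.random.default_rng(seed)
        lo = (centers - radii[:, None]).min(axis=0)
        hi = (centers + radii[:, None]).max(axis=0)
        box_vol = float(np.prod(hi - lo))
        inside = np.zeros(volume_samples, dtype=bool)
        chunk = 200_000
        samples = rng.uniform(lo, hi, size=(volume_samples, 3))
        for j in range(len(structure)):
            for start in range(0, volume_samples, chunk):
                sl = slice(start, start + chunk)
                d2 = np.sum((samples[sl] - centers[j]) ** 2, axis=1)
                inside[sl] |= d2 <= radii[j] ** 2
        p = inside.mean()
        volume = float(box_vol * p)
        vol_se = float(box_vol * math.sqrt(p * (1 - p) / volume_samples))
    return SasaResult(float(per_atom.sum()), per_atom, volume, vol_se)


# ---------------------------------------------------------------------------
# Contacts and clashes

def residue_contacts(
    complex_structure: Structure,
    ligand_selection: Sequence[int],
    cutoff: float = 4.0,
) -> list[str]:
    """Residues with >= 1 heavy atom within ``cutoff`` of a ligand heavy atom.

    The ligand's own residues are excluded; labels are sorted by residue
    number.
    """
    lig = list(ligand_selection)
    if not lig:
        raise SelectionError("ligand selection is empty")
    lig_set = set(lig)
    lig_residues = {
        (complex_structure.atoms[i].chain_id,
         complex_structure.atoms[i].residue_number)
        for i in lig
    }
    lig_xyz = np.array(
        [complex_structure.atoms[i].coords for i in lig
         if complex_structure.atoms[i].is_heavy]
    )
    if lig_xyz.size == 0:
        raise SelectionError("ligand selection contains no heavy atoms")
    found: dict[tuple[str, int], str] = {}
    for i, atom in enumerate(complex_structure.atoms):
        key = (atom.chain_id, atom.residue_number)
        if i in lig_set or key in lig_residues or key in found or not atom.is_heavy:
            continue
        d = np.linalg.norm(lig_xyz - atom.coords, axis=1)
        if np.any(d <= cutoff):
            found[key] = atom.residue_label
    return [label for _, label in sorted(found.items(), key=lambda kv: kv[0][1])]


def clash_check(
    receptor: Structure,
    partner: Structure,
    receptor_residue: str,
    partner_residue: str,
    tolerance: float = 0.4,
) -> ClashReport:
    """Steric clash between two named residues of two structures.

    A heavy-atom pair clashes when its distance is below the sum of vdW
    radii minus the tolerance; the report lists all overlapping pairs with
    overlap = (r_i + r_j - tolerance) - d.
    """
    r_idx = [i for i in residue_atom_indices(receptor, receptor_residue)
             if receptor.atoms[i].is_heavy]
    p_idx = [i for i in residue_atom_indices(partner, partner_residue)
             if partner.atoms[i].is_heavy]
    if not r_idx:
        raise MissingResidueError(
            f"residue {receptor_residue!r} not found in receptor structure")
    if not p_idx:
        raise MissingResidueError(
            f"residue {partner_residue!r} not found in partner structure")
    min_d = math.inf
    overlaps: list[tuple[str, str, float]] = []
    for i in r_idx:
        ai = receptor.atoms[i]
        for j in p_idx:
            aj = partner.atoms[j]
            d = float(np.linalg.norm(ai.coords - aj.coords))
            min_d = min(min_d, d)
            threshold = ai.vdw_radius + aj.vdw_radius - tolerance
            if d < threshold:
                overlaps.append(
                    (f"{ai.residue_label}:{ai.atom_name}",
                     f"{aj.residue_label}:{aj.atom_name}",
                     threshold - d)
                )
    return ClashReport(min_d, overlaps, tolerance)
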