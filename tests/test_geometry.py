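"""Geometric observables: superposition, distances, H-bonds, SASA, clashes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import apjbias as ab
from apjbias.datasets import tyr_pair_series
from apjbias.errors import (
    DegenerateGeometryError,
    MissingResidueError,
    SelectionError,
)
from apjbias.geometry import HBond, _fibonacci_sphere
from apjbias.structio import Atom


def _point_structure(points, names=None, residue_numbers=None, elements=None):
    atoms = []
    for i, p in enumerate(points):
        atoms.append(Atom(
            (names or ["CA"] * len(points))[i],
            "GLY",
            (residue_numbers or list(range(1, len(points) + 1)))[i],
            "A",
            (elements or ["C"] * len(points))[i],
            np.asarray(p, float),
        ))
    return ab.Structure(atoms)


# ---------------------------------------------------------------------------
# Kabsch superposition

def _brute_force_min_rmsd(P, Q):
    """Independent oracle: direct minimisation of RMSD over rotations.

    Coarse search over a quaternion-ish grid of rotation vectors followed by
    Nelder-Mead refinement of the raw objective; never touches the SVD path.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return math.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best = None
    grid = np.linspace(-np.pi, np.pi, 7)
    for ax in _fibonacci_sphere(40):
        for ang in grid:
            v = objective(ax * ang)
            if best is None or v < best[0]:
                best = (v, ax * ang)
    res = minimize(objective, best[1], method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-14, maxiter=20000))
    return min(best[0], float(res.fun))


def test_identical_structures_superpose_exactly():
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.5]])
    R, t, rmsd = ab.kabsch_superpose(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(R, np.eye(3), atol=1e-7)
    assert np.allclose(t, 0.0, atol=1e-7)


def test_rigid_motion_gives_zero_rmsd():
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.5]])
    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Q = P @ rot.T + np.array([5.0, -2.0, 1.0])
    R, t, rmsd = ab.kabsch_superpose(P, Q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(P @ R.T + t, Q, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kabsch_matches_brute_force_rotation_search(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(4, 3))
    Q = rng.normal(size=(4, 3))
    _, _, rmsd = ab.kabsch_superpose(P, Q)
    assert rmsd == pytest.approx(_brute_force_min_rmsd(P, Q), abs=1e-6)


def test_rmsd_symmetric_under_argument_swap(rng):
    P = rng.normal(size=(6, 3))
    Q = rng.normal(size=(6, 3))
    _, _, r1 = ab.kabsch_superpose(P, Q)
    _, _, r2 = ab.kabsch_superpose(Q, P)
    assert r1 == pytest.approx(r2, abs=1e-10)


def test_degenerate_geometries_rejected():
    with pytest.raises(DegenerateGeometryError):
        ab.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.raises(DegenerateGeometryError):
        ab.kabsch_superpose(line, line)


# ---------------------------------------------------------------------------
# RMSD trace and distances

def test_rmsd_trace_static_and_translated(short_traj, toy_receptor):
    static = ab.Trajectory(
        toy_receptor,
        np.repeat(toy_receptor.coords[None], 4, axis=0),
        np.arange(4.0),
    )
    sel = toy_receptor.select(atom_names="CA")
    assert np.allclose(ab.rmsd_trace(static, sel).distances_A, 0.0, atol=1e-9)
    shifted = ab.Trajectory(
        toy_receptor,
        np.stack([toy_receptor.coords + i * np.array([1.0, -2.0, 0.5])
                  for i in range(4)]),
        np.arange(4.0),
    )
    assert np.allclose(ab.rmsd_trace(shifted, sel).distances_A, 0.0, atol=1e-8)


def test_rmsd_trace_matches_direct_formula_for_fixed_fit_atoms():
    # fit atoms identical across frames -> superposition is the identity,
    # so the trace on the measured atom equals the plain displacement RMSD
    base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [1, 1, 1]],
                    dtype=float)
    disp = [0.0, 0.3, 1.2]
    frames = []
    for d in disp:
        f = base.copy()
        f[4, 0] += d
        frames.append(f)
    traj = ab.Trajectory(_point_structure(base), np.stack(frames),
                         np.arange(3.0))
    series = ab.rmsd_trace(traj, fit_selection=[0, 1, 2, 3],
                           measure_selection=[4])
    assert np.allclose(series.distances_A, disp, atol=1e-9)


def test_pair_distance_series_pythagorean():
    pts = np.array([[0, 0, 0], [3, 4, 0], [0, 0, 0]], float)
    traj = ab.Trajectory(_point_structure(pts), pts[None], [0.0])
    assert ab.pair_distance_series(traj, 0, 1).distances_A[0] == pytest.approx(5.0)
    assert ab.pair_distance_series(traj, 0, 2).distances_A[0] == 0.0
    with pytest.raises(IndexError):
        ab.pair_distance_series(traj, 0, 99)


def test_mean_distance_constant_and_subsample():
    s = ab.DistanceSeries("x", np.arange(5.0), np.full(5, 2.5))
    assert ab.mean_distance(s) == 2.5
    assert ab.mean_distance(s, subsample_times=[1.0, 3.0]) == 2.5
    with pytest.raises(ValueError):
        ab.mean_distance(s, subsample_times=[99.0])


def test_window_occupancy_hand_counts_from_reference_table():
    # counted by hand from the printed distance columns
    ec = tyr_pair_series("ec", "Tyr309")
    assert ab.window_occupancy(ec, (2.7, 3.3)) == pytest.approx(5 / 10)
    cmf = tyr_pair_series("cmf", "Tyr309")
    assert ab.window_occupancy(cmf, (2.7, 3.3)) == 0.0


@settings(derandomize=True, max_examples=30)
@given(lo=st.floats(0.0, 5.0), width1=st.floats(0.0, 3.0),
       extra=st.floats(0.0, 3.0))
def test_window_occupancy_monotone_in_window_width(lo, width1, extra):
    d = np.linspace(0.0, 8.0, 33)
    s = ab.DistanceSeries("x", np.arange(33.0), d)
    narrow = ab.window_occupancy(s, (lo, lo + width1))
    wide = ab.window_occupancy(s, (lo - extra, lo + width1 + extra))
    assert wide >= narrow


# ---------------------------------------------------------------------------
# Hydrogen bonds

def _dha_structure(d_a_dist, h_offset_deg=0.0, with_hydrogen=True):
    """Donor O at origin, acceptor O on x, hydrogen at 0.97 A from donor."""
    ang = math.radians(h_offset_deg)
    atoms = [
        Atom("OH", "TYR", 1, "A", "O", [0.0, 0.0, 0.0]),
        Atom("OH", "TYR", 2, "A", "O", [d_a_dist, 0.0, 0.0]),
    ]
    if with_hydrogen:
        atoms.append(Atom("HH", "TYR", 1, "A", "H",
                          [0.97 * math.cos(ang), 0.97 * math.sin(ang), 0.0]))
    return ab.Structure(atoms)


def test_detect_hbonds_distance_and_angle_criteria():
    crit = ab.HBondCriterion()
    assert len(ab.detect_hbonds(_dha_structure(2.9), crit, [0], [1])) == 1
    assert len(ab.detect_hbonds(_dha_structure(4.0), crit, [0], [1])) == 0
    assert len(ab.detect_hbonds(_dha_structure(3.0, h_offset_deg=60.0),
                                crit, [0], [1])) == 0


def test_detect_hbonds_without_hydrogen_is_distance_only():
    crit = ab.HBondCriterion()
    bonds = ab.detect_hbonds(_dha_structure(2.9, with_hydrogen=False),
                             crit, [0], [1])
    assert len(bonds) == 1
    assert bonds[0].distance_only and bonds[0].hydrogen is None


def _brute_force_hbonds(frame, crit, donors, acceptors):
    """Independent plain-python enumeration over all donor/acceptor pairs."""
    found = set()
    for d in donors:
        da = frame.atoms[d]
        hyds = [i for i, a in enumerate(frame.atoms)
                if a.element == "H"
                and a.residue_number == da.residue_number
                and a.chain_id == da.chain_id
                and math.dist(a.coords, da.coords) <= 1.25]
        for ac in acceptors:
            if ac == d:
                continue
            aa = frame.atoms[ac]
            dist = math.dist(da.coords, aa.coords)
            if dist > crit.donor_acceptor_cutoff:
                continue
            if not hyds:
                found.add((d, ac))
                continue
            angles = []
            for h in hyds:
                vh = frame.atoms[h].coords - da.coords
                va = aa.coords - da.coords
                c = np.dot(vh, va) / (np.linalg.norm(vh) * np.linalg.norm(va))
                angles.append(math.degrees(math.acos(max(-1.0, min(1.0, c)))))
            if min(angles) <= crit.angle_cutoff_deg:
                found.add((d, ac))
    return found


@pytest.mark.parametrize("seed", range(5))
def test_detect_hbonds_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_res = 8
    atoms = []
    for r in range(1, n_res + 1):
        center = rng.uniform(-4, 4, size=3)
        atoms.append(Atom("OH", "SER", r, "A", "O", center))
        if r % 2 == 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(Atom("HH", "SER", r, "A", "H",
                              center + 0.97 * direction))
    frame = ab.Structure(atoms)
    donors = [i for i, a in enumerate(frame.atoms) if a.atom_name == "OH"]
    acceptors = donors
    crit = ab.HBondCriterion()
    ours = {(b.donor, b.acceptor)
            for b in ab.detect_hbonds(frame, crit, donors, acceptors)}
    assert ours == _brute_force_hbonds(frame, crit, donors, acceptors)


def test_hbond_series_alternating_frames():
    s = _dha_structure(2.9)
    bonded = s.coords
    unbonded = bonded.copy()
    unbonded[1, 0] = 6.0  # move acceptor away
    frames = np.stack([bonded, unbonded, bonded, unbonded])
    traj = ab.Trajectory(s, frames, np.arange(4.0))
    series = ab.hbond_series(traj, ab.HBondCriterion(), [0], [1])
    assert list(series.counts) == [1, 0, 1, 0]


# ---------------------------------------------------------------------------
# SASA

def _sphere(radius=1.5, center=(0, 0, 0), number=1):
    return Atom("X", "SPH", number, "A", "C", np.asarray(center, float),
                vdw_radius=radius)


def test_single_sphere_matches_analytic_area():
    s = ab.Structure([_sphere(1.5)])
    res = ab.sasa(s, probe_radius=1.4, n_points=960)
    analytic = 4 * math.pi * 2.9 ** 2
    assert res.area_A2 == pytest.approx(analytic, rel=0.005)


def test_disjoint_spheres_are_additive():
    s = ab.Structure([_sphere(1.5, (0, 0, 0), 1), _sphere(1.5, (10, 0, 0), 2)])
    res = ab.sasa(s, probe_radius=1.4, n_points=960)
    assert res.area_A2 == pytest.approx(2 * 4 * math.pi * 2.9 ** 2, rel=0.005)
    assert np.all(res.per_atom_area >= 0)
    assert res.per_atom_area.sum() == pytest.approx(res.area_A2, rel=1e-9)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_overlapping_equal_spheres_match_spherical_cap_formula(d):
    # union of two equal spheres radius R at distance d: each sphere loses a
    # cap of height h = R - d/2, cap area 2*pi*R*h
    R = 1.5 + 1.4
    s = ab.Structure([_sphere(1.5, (0, 0, 0), 1), _sphere(1.5, (d, 0, 0), 2)])
    res = ab.sasa(s, probe_radius=1.4, n_points=2000)
    analytic = 2 * (4 * math.pi * R ** 2 - 2 * math.pi * R * (R - d / 2))
    assert res.area_A2 == pytest.approx(analytic, rel=0.01)


def test_volume_monte_carlo_matches_sphere():
    s = ab.Structure([_sphere(1.5)])
    res = ab.sasa(s, probe_radius=1.4, n_points=120, volume_samples=200_000,
                  seed=3)
    analytic = 4 / 3 * math.pi * 2.9 ** 3
    assert res.volume_A3 == pytest.approx(analytic, abs=4 * res.volume_se_A3)


def test_sasa_cross_checked_against_independent_library(toy_receptor):
    struc = pytest.importorskip("biotite.structure")
    res = ab.sasa(toy_receptor, probe_radius=1.4, n_points=960)
    arr = struc.AtomArray(len(toy_receptor))
    arr.coord = toy_receptor.coords
    arr.res_id = np.array([a.residue_number for a in toy_receptor.atoms])
    arr.atom_name = np.array([a.atom_name for a in toy_receptor.atoms])
    arr.res_name = np.array([a.residue_name for a in toy_receptor.atoms])
    arr.chain_id = np.array([a.chain_id for a in toy_receptor.atoms])
    arr.element = np.array([a.element for a in toy_receptor.atoms])
    radii = np.array([a.vdw_radius for a in toy_receptor.atoms])
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                        vdw_radii=radii).sum()
    assert res.area_A2 == pytest.approx(theirs, rel=0.02)


# ---------------------------------------------------------------------------
# Contacts and clashes

def test_residue_contacts_against_distance_matrix():
    # ligand residue 99 at origin; residues at 3, 4.5 and 6 A
    atoms = [
        Atom("C1", "LIG", 99, "L", "C", [0.0, 0.0, 0.0]),
        Atom("CA", "TRP", 85, "A", "C", [3.0, 0.0, 0.0]),
        Atom("CA", "ILE", 109, "A", "C", [0.0, 4.5, 0.0]),
        Atom("CA", "TYR", 182, "A", "C", [0.0, 0.0, 6.0]),
    ]
    s = ab.Structure(atoms)
    assert ab.residue_contacts(s, [0], cutoff=4.0) == ["TRP85"]
    assert ab.residue_contacts(s, [0], cutoff=5.0) == ["TRP85", "ILE109"]
    assert ab.residue_contacts(s, [0], cutoff=0.0) == []
    with pytest.raises(SelectionError):
        ab.residue_contacts(s, [], cutoff=4.0)


def test_clash_check_distance_thresholds():
    far_r = _point_structure([[0, 0, 0]], names=["CA"], residue_numbers=[127])
    far_p = _point_structure([[10, 0, 0]], names=["CA"], residue_numbers=[356])
    rep = ab.clash_check(far_r, far_p, "127", "356")
    assert not rep.clash and rep.min_distance_A == pytest.approx(10.0)

    near_p = _point_structure([[1.0, 0, 0]], names=["CA"],
                              residue_numbers=[356])
    rep = ab.clash_check(far_r, near_p, "127", "356")
    assert rep.clash
    # carbon/carbon: threshold 1.70 + 1.70 - 0.4 = 3.0; overlap = 3.0 - 1.0
    assert rep.overlapping_pairs[0][2] == pytest.approx(2.0)


def test_clash_flag_flips_exactly_at_vdw_threshold():
    # N (1.55) vs O (1.52), tolerance 0.4 -> threshold 2.67
    threshold = 1.55 + 1.52 - 0.4
    for d, expected in [(threshold - 0.01, True), (threshold + 0.01, False)]:
        r = ab.Structure([Atom("NH1", "ARG", 127, "A", "N", [0, 0, 0])])
        p = ab.Structure([Atom("OH", "TYR", 356, "G", "O", [d, 0, 0])])
        assert ab.clash_check(r, p, "ARG127", "TYR356").clash is expected


def test_clash_check_missing_residue_errors():
    r = _point_structure([[0, 0, 0]], residue_numbers=[127])
    with pytest.raises(MissingResidueError):
        ab.clash_check(r, r, "ARG999", "127")
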