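"""Synthetic structures, trajectories, templates, and assay tables.

Every downstream stage of the package can be exercised on data with known
ground truth generated here.  The generators emulate the *observables*
relevant to the bias diagnostic, not the physics: a toy receptor is an
idealised helical C-alpha scaffold carrying the named residues the
analyses address (Arg127, Tyr221, Tyr309), a trajectory drives the
tyrosine-pair O...O distance with a discrete mean-reverting
(Ornstein-Uhlenbeck) process with an optional regime switch emulating a
conformational transition part-way through a run, a template complex
provides a receptor chain plus a G-protein-like partner chain at a
controlled steric separation, and assay tables are drawn from the pharm
model curves with Gaussian noise.  All generators are deterministic under
their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import UnknownModelError
from .pharm import (
    DoseResponseTable,
    hill_binding_curve,
    inhibition_curve,
    operational_curve,
)
from .structio import Atom, Structure, Trajectory

__all__ = [
    "TrajectorySpec", "AssaySpec", "make_toy_receptor", "make_trajectory",
    "make_template_complex", "make_assay",
]

_HELIX_RADIUS_A = 2.3
_HELIX_RISE_A = 1.5
_HELIX_TURN_DEG = 100.0
_OH_BOND_A = 0.97       # phenolic O-H bond length
_PLAIN_NUMBER_BASE = 400  # keeps decorative residue numbers clear of 127/221/309


@dataclass
class TrajectorySpec:
    """Parameters of the controlled-distance synthetic trajectory.

    The tyrosine-pair O...O distance follows
    ``d[t+1] = d[t] + (mean - d[t]) / relaxation_frames
    + sd * sqrt(2 / relaxation_frames) * eps[t]``,
    whose stationary distribution has approximately the requested mean and
    standard deviation.  An optional regime switch at ``transition_frame``
    changes the target mean/sd, emulating a conformational transition.
    All non-controlled atoms receive small isotropic jitter.
    """

    n_frames: int
    dt_ns: float = 0.01
    pair_mean_A: float = 3.0
    pair_sd_A: float = 0.1
    relaxation_frames: float = 50.0
    seed: int = 0
    transition_frame: Optional[int] = None
    post_mean_A: Optional[float] = None
    post_sd_A: Optional[float] = None
    jitter_A: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pair_sd_A < 0 or (self.post_sd_A or 0) < 0:
            raise ValueError("sd must be >= 0")
        if self.relaxation_frames <= 0:
            raise ValueError("relaxation_frames must be positive")
        if self.transition_frame is not None:
            if not 0 <= self.transition_frame < self.n_frames:
                raise ValueError("transition_frame out of range")
            if self.post_mean_A is None:
                raise ValueError("transition requires post_mean_A")


@dataclass
class AssaySpec:
    """Parameters of a synthetic dose-response table."""

    model: str                       # hill_binding | operational | inhibition
    true_params: dict
    doses_M: np.ndarray = field(default_factory=lambda: np.logspace(-13, -7, 12))
    noise_sd_fraction: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses_M = np.asarray(self.doses_M, dtype=float)
        if np.any(self.doses_M <= 0):
            raise ValueError("doses must be positive")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def make_toy_receptor(
    n_residues: int = 120,
    include_tyr_pair: bool = True,
    pair_distance_A: float = 3.0,
    include_arg127: bool = True,
    chain_id: str = "A",
) -> Structure:
    """Idealised helical C-alpha scaffold with the diagnostic residues.

    Residues are numbered from 400 upward except the special positions:
    one third and two thirds of the way along, TYR residues numbered 221
    and 309 carry phenolic OH/HH atoms whose O...O distance equals
    ``pair_distance_A`` exactly (hydrogens sit on the O...O axis, so the
    geometric hydrogen-bond criterion is met whenever the distance is);
    one sixth of the way along, an ARG numbered 127 carries an NH1
    side-chain atom for the clash analysis.  Geometry is decorative
    beyond these controlled observables.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if pair_distance_A <= 0:
        raise ValueError("pair distance must be positive")
    theta = math.radians(_HELIX_TURN_DEG)
    i_arg = n_residues // 6
    i_tyr1 = n_residues // 3
    i_tyr2 = 2 * n_residues // 3

    atoms: list[Atom] = []
    ca_positions = []
    for i in range(n_residues):
        pos = np.array([
            _HELIX_RADIUS_A * math.cos(i * theta),
            _HELIX_RADIUS_A * math.sin(i * theta),
            i * _HELIX_RISE_A,
        ])
        ca_positions.append(pos)
        if include_arg127 and i == i_arg:
            name, number = "ARG", 127
        elif include_tyr_pair and i == i_tyr1:
            name, number = "TYR", 221
        elif include_tyr_pair and i == i_tyr2:
            name, number = "TYR", 309
        else:
            name, number = "ALA", _PLAIN_NUMBER_BASE + i
        atoms.append(Atom("CA", name, number, chain_id, "C", pos))
        if name == "ARG":
            outward = np.array([math.cos(i * theta), math.sin(i * theta), 0.0])
            atoms.append(Atom("NH1", "ARG", 127, chain_id, "N", pos + 3.0 * outward))

    if include_tyr_pair:
        mid = 0.5 * (ca_positions[i_tyr1] + ca_positions[i_tyr2])
        u = np.array([1.0, 0.0, 0.0])
        o1 = mid - 0.5 * pair_distance_A * u
        o2 = mid + 0.5 * pair_distance_A * u
        extras = [
            Atom("OH", "TYR", 221, chain_id, "O", o1),
            Atom("HH", "TYR", 221, chain_id, "H", o1 + _OH_BOND_A * u),
            Atom("OH", "TYR", 309, chain_id, "O", o2),
            Atom("HH", "TYR", 309, chain_id, "H", o2 - _OH_BOND_A * u),
        ]
        atoms.extend(extras)
    return Structure(atoms, label="toy receptor")


def _ou_distance_path(spec: TrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_frames
    k = spec.relaxation_frames
    means = np.full(n, spec.pair_mean_A)
    sds = np.full(n, spec.pair_sd_A)
    if spec.transition_frame is not None:
        means[spec.transition_frame:] = spec.post_mean_A
        sds[spec.transition_frame:] = (
            spec.post_sd_A if spec.post_sd_A is not None else spec.pair_sd_A)
    eps = rng.standard_normal(n)
    d = np.empty(n)
    d[0] = means[0]
    for t in range(n - 1):
        d[t + 1] = (d[t] + (means[t + 1] - d[t]) / k
                    + sds[t + 1] * math.sqrt(2.0 / k) * eps[t])
    return np.clip(d, 0.1, None)


def make_trajectory(spec: TrajectorySpec, base: Structure) -> Trajectory:
    """Trajectory whose tyrosine-pair O...O distance follows the OU process.

    The controlled atoms are the phenolic oxygens/hydrogens of TYR 221 and
    TYR 309 in ``base``: Tyr221's oxygen stays put, Tyr309's oxygen moves
    along the fixed pair axis to realise the sampled distance, and both
    hydrogens track the axis (collinear O-H...O), so distance and
    hydrogen-bond observables move together.  Every other atom is jittered
    isotropically by ``jitter_A``.
    """
    def one(sel_desc, **kw):
        idx = base.select(**kw)
        if len(idx) != 1:
            raise ValueError(f"base must contain exactly one {sel_desc}")
        return idx[0]

    o1 = one("TYR221 OH", residue_number=221, residue_name="TYR", atom_names="OH")
    h1 = one("TYR221 HH", residue_number=221, residue_name="TYR", atom_names="HH")
    o2 = one("TYR309 OH", residue_number=309, residue_name="TYR", atom_names="OH")
    h2 = one("TYR309 HH", residue_number=309, residue_name="TYR", atom_names="HH")

    rng = np.random.default_rng(spec.seed)
    distances = _ou_distance_path(spec, rng)
    base_xyz = base.coords
    u = base_xyz[o2] - base_xyz[o1]
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("tyrosine oxygens coincide in the base structure")
    u = u / norm

    n_atoms = len(base)
    controlled = np.array([o1, h1, o2, h2])
    jitter = rng.normal(0.0, spec.jitter_A, size=(spec.n_frames, n_atoms, 3))
    jitter[:, controlled, :] = 0.0
    frames = base_xyz[None, :, :] + jitter
    origin = base_xyz[o1]
    frames[:, o1] = origin
    frames[:, h1] = origin + _OH_BOND_A * u
    frames[:, o2] = origin + distances[:, None] * u
    frames[:, h2] = frames[:, o2] - _OH_BOND_A * u
    times = np.arange(spec.n_frames) * spec.dt_ns
    return Trajectory(base, frames, times)


def make_template_complex(
    separation_A: float = 8.0,
    n_residues: int = 120,
    receptor_chain: str = "R",
    partner_chain: str = "G",
) -> Structure:
    """Receptor/G-protein template at a controlled residue separation.

    Chain ``R`` is the same helical scaffold as :func:`make_toy_receptor`
    (without the tyrosine pair) so its C-alpha numbering pairs with a toy
    receptor's for superposition; chain ``G`` carries a TYR 356 whose
    phenolic oxygen sits exactly ``separation_A`` from Arg127's NH1 — the
    closest heavy-atom pair between the two residues — plus a short
    backbone for context.
    """
    if separation_A < 0:
        raise ValueError("separation must be >= 0")
    receptor = make_toy_receptor(
        n_residues, include_tyr_pair=False, include_arg127=True,
        chain_id=receptor_chain,
    )
    nh1_idx = receptor.select(residue_number=127, atom_names="NH1")[0]
    ca_idx = receptor.select(residue_number=127, atom_names="CA")[0]
    nh1 = receptor.atoms[nh1_idx].coords
    w = nh1 - receptor.atoms[ca_idx].coords
    w = w / np.linalg.norm(w)
    oh = nh1 + separation_A * w
    atoms = list(receptor.atoms)
    atoms.append(Atom("OH", "TYR", 356, partner_chain, "O", oh))
    atoms.append(Atom("CA", "TYR", 356, partner_chain, "C", oh + 2.4 * w))
    for k in range(3):  # decorative partner backbone
        atoms.append(
            Atom("CA", "GLY", 360 + k, partner_chain, "C",
                 oh + (4.0 + 3.8 * k) * w)
        )
    return Structure(atoms, label="synthetic receptor/G-protein template")


_MODEL_FUNCS = {
    "hill_binding": (hill_binding_curve, ("Bmax", "Kd", "h"), "Bmax"),
    "operational": (operational_curve, ("Em", "tau", "KA", "n"), "Em"),
    "inhibition": (inhibition_curve, ("top", "bottom", "IC50", "s"), "top"),
}


def make_assay(spec: AssaySpec) -> DoseResponseTable:
    """Dose-response table drawn from a named model with Gaussian noise.

    Noise standard deviation is ``noise_sd_fraction`` times the model's
    scale parameter (Bmax / Em / top); replicates repeat the dose series
    with independent noise.  Deterministic under ``seed``.
    """
    if spec.model not in _MODEL_FUNCS:
        raise UnknownModelError(
            f"unknown assay model {spec.model!r}; choose from "
            f"{sorted(_MODEL_FUNCS)}")
    func, param_names, scale_name = _MODEL_FUNCS[spec.model]
    missing = [p for p in param_names if p not in spec.true_params and p != "s"]
    if missing:
        raise ValueError(f"missing true_params for {spec.model}: {missing}")
    params = [spec.true_params.get(p, 1.0) for p in param_names]
    clean = func(spec.doses_M, *params)
    rng = np.random.default_rng(spec.seed)
    doses = np.tile(spec.doses_M, spec.replicates)
    signal = np.tile(clean, spec.replicates)
    sd = spec.noise_sd_fraction * abs(spec.true_params[scale_name])
    noise = rng.normal(0.0, sd, size=signal.shape) if sd > 0 else 0.0
    reps = np.repeat(np.arange(spec.replicates), len(spec.doses_M))
    return DoseResponseTable(doses, signal + noise, replicate_id=reps,
                             label=spec.model)
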