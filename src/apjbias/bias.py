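"""Structural diagnostic of biased agonism.

The diagnostic combines two observations made on an active-state receptor
trajectory:

1. the TM5-TM7 tyrosine pair (Tyr221/Tyr309 in apelin-receptor numbering)
   forming a persistent hydrogen bond, which closes the intracellular
   cavity and marks a beta-arrestin-competent conformation; and
2. a steric clash between the receptor's Arg127 (TM3) and the G-protein
   Tyr356 after superposing a representative receptor conformer onto a
   receptor/G-protein template complex, which precludes G-protein docking.

A persistent tyrosine bond together with a clash classifies the run as
beta-arrestin-biased; the absence of both classifies it as
G-protein-competent; any other combination is indeterminate.  The clash
call is computed from van-der-Waals overlap rather than by visual
inspection, and reports say so.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .clustering import gromos_cluster, pairwise_rmsd_matrix
from .errors import DegenerateGeometryError, MissingResidueError
from .geometry import (
    ClashReport,
    DistanceSeries,
    apply_transform,
    clash_check,
    kabsch_superpose,
    mean_distance,
    pair_distance_series,
    truncate_report,
    window_occupancy,
)
from .structio import Structure, Trajectory, parse_residue_label

__all__ = [
    "TyrPairReport", "BiasReport", "tyr_pair_report", "classify_bias",
    "gprotein_dock_assess", "run_bias_pipeline",
]

CALL_ARRESTIN = "beta-arrestin-biased"
CALL_GPROTEIN = "G-protein-competent"
CALL_INDETERMINATE = "indeterminate"


@dataclass
class TyrPairReport:
    """Distance diagnostics for the TM5-TM7 tyrosine pair.

    Two donor-direction series are reported Table-style (acceptor phenolic
    oxygen to donor hydroxyl hydrogen, both directions), plus the
    donor-acceptor heavy-atom (O...O) series on which window occupancy is
    evaluated, since the 2.7-3.3 A optimal band refers to donor/acceptor
    heavy atoms.
    """

    series_donor_a: DistanceSeries   # acceptor O of res_b ... H of res_a
    series_donor_b: DistanceSeries   # acceptor O of res_a ... H of res_b
    heavy_series: DistanceSeries     # O...O
    mean_donor_a: float
    mean_donor_b: float
    occupancy: float
    window: tuple[float, float]
    subsample_means: Optional[tuple[float, float]] = None

    @property
    def pair_means_A(self) -> tuple[float, float]:
        return (self.mean_donor_a, self.mean_donor_b)

    def reported_means(self) -> tuple[float, float]:
        """Means truncated to two decimals, the report convention."""
        return (truncate_report(self.mean_donor_a),
                truncate_report(self.mean_donor_b))

    def table(self, times_ns: Optional[Sequence[float]] = None) -> pd.DataFrame:
        """Per-time distance table for both donor directions."""
        df = pd.DataFrame(
            {
                "time_ns": self.series_donor_a.times_ns,
                self.series_donor_a.pair_label: self.series_donor_a.distances_A,
                self.series_donor_b.pair_label: self.series_donor_b.distances_A,
            }
        )
        if times_ns is not None:
            mask = np.isin(np.round(df["time_ns"], 9), np.round(times_ns, 9))
            df = df[mask].reset_index(drop=True)
        return df


@dataclass
class BiasReport:
    pair_means_A: tuple[float, float]
    occupancy: float
    hbond_persistent: bool
    clash: ClashReport
    call: str
    evidence: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pair_means_A": [round(m, 4) for m in self.pair_means_A],
            "occupancy": round(self.occupancy, 4),
            "hbond_persistent": self.hbond_persistent,
            "clash": {
                "clash": self.clash.clash,
                "min_distance_A": round(self.clash.min_distance_A, 4),
                "n_overlapping_pairs": len(self.clash.overlapping_pairs),
                "tolerance_A": self.clash.tolerance_A,
            },
            "call": self.call,
            "evidence": self.evidence,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"bias call: {self.call}", ""]
        lines += self.evidence
        return "\n".join(lines)


def _phenolic_atoms(traj: Trajectory, label: str) -> tuple[int, int]:
    """Indices of the phenolic oxygen (OH) and its hydrogen (HH)."""
    name, number = parse_residue_label(label)
    top = traj.topology
    o = top.select(residue_number=number, residue_name=name, atom_names="OH")
    h = top.select(residue_number=number, residue_name=name, atom_names="HH")
    if not o or not h:
        raise MissingResidueError(
            f"residue {label!r} with OH/HH atoms not found in topology")
    return o[0], h[0]


def tyr_pair_report(
    traj: Trajectory,
    res_a: str = "TYR221",
    res_b: str = "TYR309",
    window: tuple[float, float] = (2.7, 3.3),
    subsample_ns: Optional[Sequence[float]] = None,
) -> TyrPairReport:
    """Distance diagnostics for a tyrosine pair over a trajectory.

    Reports the acceptor-O to donor-H distance for both donor directions
    (labelled like ``Tyr309O-HTyr221``: acceptor oxygen on Tyr309, donor
    hydrogen on Tyr221), their full-trajectory means (and means at
    ``subsample_ns`` when given), and the fraction of frames whose
    heavy-atom O...O distance lies in the optimal hydrogen-bond window.
    """
    o_a, h_a = _phenolic_atoms(traj, res_a)
    o_b, h_b = _phenolic_atoms(traj, res_b)
    name_a = res_a.capitalize()
    name_b = res_b.capitalize()
    series_donor_a = pair_distance_series(
        traj, o_b, h_a, label=f"{name_b}O-H{name_a}")
    series_donor_b = pair_distance_series(
        traj, o_a, h_b, label=f"{name_a}O-H{name_b}")
    heavy = pair_distance_series(
        traj, o_a, o_b, label=f"{name_a}O-{name_b}O")
    sub = None
    if subsample_ns is not None:
        sub = (mean_distance(series_donor_a, subsample_ns),
               mean_distance(series_donor_b, subsample_ns))
    return TyrPairReport(
        series_donor_a=series_donor_a,
        series_donor_b=series_donor_b,
        heavy_series=heavy,
        mean_donor_a=mean_distance(series_donor_a),
        mean_donor_b=mean_distance(series_donor_b),
        occupancy=window_occupancy(heavy, window),
        window=tuple(window),
        subsample_means=sub,
    )


def classify_bias(
    tyr_report: Union[TyrPairReport, float],
    clash_report: ClashReport,
    occupancy_threshold: float = 0.5,
) -> BiasReport:
    """Combine tyrosine-pair occupancy and the G-protein clash into a call.

    ``tyr_report`` may be a :class:`TyrPairReport` or a bare occupancy
    fraction.  The hydrogen bond is deemed persistent when occupancy >=
    the threshold.  The classification is a pure function of
    (occupancy, clash): persistent + clash -> beta-arrestin-biased;
    neither -> G-protein-competent; otherwise indeterminate.
    """
    if isinstance(tyr_report, TyrPairReport):
        occupancy = tyr_report.occupancy
        means = tyr_report.pair_means_A
    else:
        occupancy = float(tyr_report)
        means = (math.nan, math.nan)
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be a fraction in [0, 1]")
    persistent = occupancy >= occupancy_threshold
    if persistent and clash_report.clash:
        call = CALL_ARRESTIN
    elif not persistent and not clash_report.clash:
        call = CALL_GPROTEIN
    else:
        call = CALL_INDETERMINATE
    evidence = [
        f"tyrosine-pair window occupancy {occupancy:.3f} "
        f"(threshold {occupancy_threshold:g}) -> "
        f"hydrogen bond {'persistent' if persistent else 'not persistent'}",
        f"receptor/G-protein residue pair minimum distance "
        f"{clash_report.min_distance_A:.2f} A; "
        f"{len(clash_report.overlapping_pairs)} van-der-Waals overlap(s) "
        f"(tolerance {clash_report.tolerance_A:g} A) -> "
        f"{'clash' if clash_report.clash else 'no clash'} "
        f"(computed from vdW overlap, not visual inspection)",
        f"call: {call}",
    ]
    return BiasReport(means, occupancy, persistent, clash_report, call, evidence)


def gprotein_dock_assess(
    receptor_centroid: Structure,
    template_complex: Structure,
    receptor_residue: str = "ARG127",
    partner_residue: str = "TYR356",
    receptor_chain: str = "R",
    partner_chain: str = "G",
    pair_residue_numbers: Optional[Sequence[int]] = None,
    tolerance: float = 0.4,
) -> ClashReport:
    """Can the G protein dock onto a receptor conformer?

    The conformer is superposed (Kabsch on paired C-alpha atoms) onto the
    template's receptor chain; the template receptor is then discarded and
    the steric clash between the conformer's ``receptor_residue`` and the
    retained partner (G-protein) chain's ``partner_residue`` is evaluated.
    C-alpha pairing is by residue numbers common to the conformer and the
    template receptor chain, optionally restricted to
    ``pair_residue_numbers``.
    """
    tmpl_receptor_idx = template_complex.select(chain=receptor_chain)
    partner_idx = template_complex.select(chain=partner_chain)
    if not tmpl_receptor_idx:
        raise MissingResidueError(
            f"template has no receptor chain {receptor_chain!r}")
    if not partner_idx:
        raise MissingResidueError(
            f"template has no partner chain {partner_chain!r}")

    def ca_map(structure: Structure, indices) -> dict[int, int]:
        out = {}
        for i in indices:
            a = structure.atoms[i]
            if a.atom_name.upper() == "CA":
                out.setdefault(a.residue_number, i)
        return out

    cen_ca = ca_map(receptor_centroid, range(len(receptor_centroid)))
    tmpl_ca = ca_map(template_complex, tmpl_receptor_idx)
    common = sorted(set(cen_ca) & set(tmpl_ca))
    if pair_residue_numbers is not None:
        common = [n for n in common if n in set(pair_residue_numbers)]
    if len(common) < 3:
        raise DegenerateGeometryError(
            f"only {len(common)} paired C-alpha atoms; need >= 3")
    mobile = np.array([receptor_centroid.atoms[cen_ca[n]].coords for n in common])
    ref = np.array([template_complex.atoms[tmpl_ca[n]].coords for n in common])
    R, t, _ = kabsch_superpose(mobile, ref)
    moved = receptor_centroid.with_coords(
        apply_transform(receptor_centroid.coords, R, t))
    partner = template_complex.subset(partner_idx, label="G-protein partner")
    return clash_check(moved, partner, receptor_residue, partner_residue,
                       tolerance=tolerance)


def run_bias_pipeline(
    traj: Trajectory,
    template_complex: Structure,
    res_a: str = "TYR221",
    res_b: str = "TYR309",
    receptor_residue: str = "ARG127",
    partner_residue: str = "TYR356",
    window: tuple[float, float] = (2.7, 3.3),
    occupancy_threshold: float = 0.5,
    cluster_cutoff_nm: float = 0.2,
    cluster_max_frames: int = 200,
    receptor_chain: str = "R",
    partner_chain: str = "G",
) -> tuple[BiasReport, TyrPairReport]:
    """End-to-end bias diagnostic on one trajectory.

    Computes the tyrosine-pair report on every frame, clusters a strided
    subsample of the trajectory (C-alpha RMSD, GROMOS scheme) capped at
    ``cluster_max_frames`` frames, takes the top cluster's centroid as the
    representative conformer, assesses the G-protein clash against the
    template, and classifies the run.
    """
    tyr = tyr_pair_report(traj, res_a, res_b, window)
    ca_sel = traj.topology.select(atom_names="CA")
    stride = max(1, math.ceil(traj.n_frames / cluster_max_frames))
    sub = traj.subsample(stride)
    matrix = pairwise_rmsd_matrix(sub, ca_sel)
    clusters = gromos_cluster(matrix, cluster_cutoff_nm)
    centroid_frame = clusters.centroids[0] * stride
    centroid = traj.frame_structure(centroid_frame, label="top-cluster centroid")
    clash = gprotein_dock_assess(
        centroid, template_complex,
        receptor_residue=receptor_residue, partner_residue=partner_residue,
        receptor_chain=receptor_chain, partner_chain=partner_chain,
    )
    report = classify_bias(tyr, clash, occupancy_threshold)
    report.evidence.insert(
        0,
        f"clustered {sub.n_frames} frames (stride {stride}) at "
        f"{cluster_cutoff_nm:g} nm -> {clusters.n_clusters} cluster(s); "
        f"centroid frame {centroid_frame}",
    )
    return report, tyr
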