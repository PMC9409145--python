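"""GROMOS-style conformational clustering of trajectory frames.

Implements the greedy neighbour-counting partition (Daura et al.): the
frame with the most neighbours within the RMSD cutoff becomes a cluster
centre, it and its neighbours are removed, and the step repeats until all
frames are assigned.  Pairwise frame RMSDs are Kabsch-minimised on a
selection (typically the C-alpha trace) and expressed in nm, matching the
customary 0.2 nm cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .structio import Trajectory

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "gromos_cluster"]


@dataclass
class ClusterResult:
    cutoff_nm: float
    assignments: np.ndarray   # frame -> cluster id (0 = largest cluster)
    centroids: list[int]      # one frame index per cluster, same order
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def pairwise_rmsd_matrix(traj: Trajectory, selection: Sequence[int]) -> np.ndarray:
    """Symmetric matrix of Kabsch-minimised frame-to-frame RMSDs, in nm.

    Uses the closed-form SVD expression for the minimised RMSD between two
    centred point sets, batched over frame pairs.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise SelectionError("cluster selection is empty")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    X = traj.frames[:, sel, :]
    X = X - X.mean(axis=1, keepdims=True)
    n_atoms = sel.size
    G = np.einsum("fij,fij->f", X, X)        # squared norms per frame
    F = traj.n_frames
    out = np.zeros((F, F))
    for i in range(F - 1):
        # covariance matrices of frame i against all later frames
        H = np.einsum("nk,jnm->jkm", X[i], X[i + 1:])
        U, S, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(U @ Vt))
        D = S[:, 0] + S[:, 1] + sign * S[:, 2]
        msd = np.maximum(G[i] + G[i + 1:] - 2.0 * D, 0.0) / n_atoms
        out[i, i + 1:] = np.sqrt(msd)
    out = out + out.T
    return out / 10.0  # Angstrom -> nm


def gromos_cluster(matrix: np.ndarray, cutoff_nm: float = 0.2) -> ClusterResult:
    """Greedy neighbour-counting clustering on a pairwise RMSD matrix.

    Repeatedly takes the unassigned frame with the largest number of
    unassigned neighbours within the cutoff (ties broken by lowest frame
    index) as a centroid; the centroid and its neighbours form a cluster.
    Clusters are numbered by decreasing size.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("RMSD matrix must be square")
    n = matrix.shape[0]
    adjacency = matrix <= cutoff_nm
    np.fill_diagonal(adjacency, True)
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    sizes: list[int] = []
    cluster_id = 0
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))       # argmax takes the lowest index on ties
        members = adjacency[center] & remaining
        assignments[members] = cluster_id
        centroids.append(center)
        sizes.append(int(members.sum()))
        remaining &= ~members
        cluster_id += 1
    # the greedy rule yields non-increasing sizes; sort defensively (stable)
    order = sorted(range(len(sizes)), key=lambda k: (-sizes[k], centroids[k]))
    remap = {old: new for new, old in enumerate(order)}
    assignments = np.array([remap[a] for a in assignments], dtype=int)
    centroids = [centroids[k] for k in order]
    sizes = [sizes[k] for k in order]
    return ClusterResult(float(cutoff_nm), assignments, centroids, sizes)
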