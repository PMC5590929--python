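"""Rigid-body superposition and structural clustering of 7-residue site windows.

Each window is represented by 8 corresponded atoms (the seven Cα and the Cβ of
the central S/T).  Pairs of windows are superimposed by the Kabsch algorithm
(least-squares rigid rotation + translation, proper rotations only) and the
resulting RMSD matrix is clustered by complete linkage, which guarantees that
every cluster cut at height *t* has diameter ≤ *t*.  A bootstrap null —
resampling windows centred on unmodified S/T from the same pool of chains —
gives the distribution of cluster counts expected without any modification-
specific structural motif.
"""

from __future__ import annotations

import string
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "RmsdMatrix",
    "ClusterResult",
    "kabsch_rmsd",
    "pairwise_matrix",
    "complete_linkage_clusters",
    "consensus_ss",
    "bootstrap_null",
]


@dataclass
class RmsdMatrix:
    """Symmetric matrix of pairwise superposition RMSDs (Å)."""

    window_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if len(self.window_ids) != v.shape[0]:
            raise ValueError("window_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("RMSD matrix needs zero diagonal and values >= 0")
        self.values = v

    def submatrix(self, indices: np.ndarray) -> "RmsdMatrix":
        idx = np.asarray(indices)
        return RmsdMatrix([self.window_ids[i] for i in idx],
                          self.values[np.ix_(idx, idx)])


@dataclass
class ClusterResult:
    """Complete-linkage clusters (size ≥ 2) and singlets at a fixed RMSD cut."""

    clusters: list[list]
    singlets: list
    threshold: float
    linkage: str = "complete"
    consensus_ss3: dict[str, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    def labels(self) -> dict:
        """Map member id -> cluster label (A, B, ... by descending size,
        ties broken by lexicographically smallest first member) or '-' for
        singlets."""
        out = {}
        alphabet = string.ascii_uppercase
        for k, members in enumerate(self.clusters):
            label = alphabet[k] if k < 26 else f"C{k + 1}"
            for m in members:
                out[m] = label
        for s in self.singlets:
            out[s] = "-"
        return out


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two corresponded point sets over rigid motions.

    Uses the Kabsch/SVD solution with the determinant sign correction so that
    only proper rotations (no reflections) are allowed.

    Parameters
    ----------
    a, b : (n, 3) arrays
        Corresponded coordinates; for site windows n = 8 (7 Cα + central Cβ).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # optimal proper rotation, reflection guard on the smallest singular
    # direction; the explicit residual avoids the cancellation error of the
    # trace formula
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    resid = ac @ rot - bc
    return float(np.sqrt(np.sum(resid * resid) / a.shape[0]))


def _batched_rmsd(coords: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """RMSD for index pairs (ii, jj) of a (m, n, 3) stack, batched over SVD."""
    centred = coords - coords.mean(axis=1, keepdims=True)
    h = np.einsum("pij,pik->pjk", centred[ii], centred[jj])
    u, _s, vt = np.linalg.svd(h)
    # det(H) < 0 implies the optimal proper rotation flips the smallest
    # singular direction
    sign = np.where(np.linalg.det(h) < 0, -1.0, 1.0)
    u = u.copy()
    u[:, :, 2] *= sign[:, None]
    rot = u @ vt
    resid = np.einsum("pij,pjk->pik", centred[ii], rot) - centred[jj]
    msd = np.einsum("pij,pij->p", resid, resid) / coords.shape[1]
    return np.sqrt(msd)


def pairwise_matrix(windows, coords: np.ndarray | None = None) -> RmsdMatrix:
    """All-against-all superposition RMSD matrix.

    Parameters
    ----------
    windows : sequence
        Either window ids paired with ``coords``, or objects exposing
        ``window_id`` and ``superposition_atoms`` (e.g. ``SiteWindow``).
    coords : (m, n, 3) array, optional
        Coordinates per window; taken from the window objects when omitted.
    """
    if coords is None:
        ids = []
        stack = []
        for w in windows:
            atoms = getattr(w, "superposition_atoms", None)
            if atoms is None:
                raise ValueError(f"window {w!r} has no superposition atoms "
                                 "(incomplete backbone); filter upstream")
            ids.append(getattr(w, "window_id"))
            stack.append(np.asarray(atoms, dtype=float))
        coords = np.stack(stack)
    else:
        ids = list(windows)
        coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    if m < 2:
        raise ValueError("need at least 2 windows")
    ii, jj = np.triu_indices(m, k=1)
    vals = _batched_rmsd(coords, ii, jj)
    mat = np.zeros((m, m))
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    return RmsdMatrix(ids, mat)


def complete_linkage_clusters(m: RmsdMatrix, threshold: float = 3.0
                              ) -> ClusterResult:
    """Cut a complete-linkage dendrogram at ``threshold`` Å.

    Merges at height ≤ threshold (inclusive) are kept, so every returned
    cluster has maximum pairwise RMSD ≤ threshold.  Size-1 clusters are
    reported separately as singlets.  Clusters are ordered by descending
    size, then by lexicographically smallest first member.
    """
    n = len(m.window_ids)
    if n == 1:
        return ClusterResult([], list(m.window_ids), threshold)
    z = linkage(squareform(m.values, checks=False), method="complete")
    flat = fcluster(z, t=threshold, criterion="distance")
    groups: dict[int, list] = {}
    for idx, lab in enumerate(flat):
        groups.setdefault(lab, []).append(m.window_ids[idx])
    clusters = [g for g in groups.values() if len(g) >= 2]
    singlets = [g[0] for g in groups.values() if len(g) == 1]
    clusters.sort(key=lambda g: (-len(g), str(min(g, key=str))))
    return ClusterResult(clusters, singlets, threshold)


def consensus_ss(cluster_members, annotations: dict) -> str:
    """Per-offset plurality vote of 3-state secondary structure over members.

    ``annotations`` maps member id -> 7-token ss3 string; a member missing an
    offset (token not in {H, E, C}) abstains at that offset.  Ties, including
    the no-votes case, resolve to C.
    """
    tokens = []
    for offset in range(7):
        votes = Counter()
        for member in cluster_members:
            ss = annotations.get(member)
            if ss is None or len(ss) <= offset:
                continue
            tok = ss[offset]
            if tok in "HEC":
                votes[tok] += 1
        if not votes:
            tokens.append("C")
            continue
        best = max(votes.values())
        leaders = [t for t, c in votes.items() if c == best]
        tokens.append(leaders[0] if len(leaders) == 1 else "C")
    return "".join(tokens)


@dataclass
class BootstrapNull:
    """Null distribution of multi-member cluster counts under resampling."""

    counts: np.ndarray
    n_sampled: int
    threshold: float

    def percentile_interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.percentile(self.counts, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)


def bootstrap_null(pool_matrix: RmsdMatrix, n: int = 132, reps: int = 1000,
                   threshold: float = 3.0, seed: int | None = None
                   ) -> BootstrapNull:
    """Bootstrap the number of clusters from windows on unmodified S/T.

    Each replicate samples ``n`` windows with replacement from the pool,
    clusters them at ``threshold`` Å and records the number of multi-member
    clusters.  Because RMSD depends only on the pair, replicates reuse the
    precomputed pool matrix.  A single seed drives independent per-replicate
    substreams.
    """
    pool = len(pool_matrix.window_ids)
    if pool < 1:
        raise ValueError("empty window pool")
    if pool < n:
        warnings.warn(f"pool size {pool} < sample size {n}; "
                      "sampling with replacement proceeds")
    ss = np.random.SeedSequence(seed)
    counts = np.empty(reps, dtype=int)
    for r, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, pool, size=n)
        sub = pool_matrix.submatrix(idx)
        # duplicate draws give zero off-diagonal distances, which is the
        # intended with-replacement behaviour
        res = complete_linkage_clusters(sub, threshold)
        counts[r] = res.n_clusters
    return BootstrapNull(counts, n, threshold)
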