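"""Connectopic mapping primitives.

The pipeline: voxel-wise connectivity fingerprints (Pearson correlation of
each ROI voxel's time series with every parcel's mean series) -> eta-squared
similarity between fingerprints -> maximally-thresholded connected similarity
graph -> Laplacian eigenmap (generalized eigenproblem (D - W) v = lambda D v)
-> oriented, min-max scaled gradient. Hemispheres share one fingerprint /
similarity computation but each hemisphere gets its own graph and eigenmap,
so left and right gradients are independent scalar fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.sparse.csgraph import connected_components

from .volumes import LEFT, RIGHT, CoordinateTable

logger = logging.getLogger(__name__)

__all__ = [
    "fingerprints",
    "eta_squared",
    "similarity_matrix",
    "SimilarityGraph",
    "build_connected_graph",
    "EigenSystem",
    "laplacian_eigenmap",
    "orient_and_scale",
    "GradientMap",
    "compute_gradient",
    "group_gradient",
    "partition_rostral_caudal",
    "projection_map",
]

# value resolution of a scaled gradient; makes symmetric phantoms exactly tied
_GRADIENT_DECIMALS = 9


def fingerprints(roi_ts: np.ndarray, parcel_ts: np.ndarray) -> np.ndarray:
    """Pearson correlation of each ROI voxel series with each parcel series.

    Returns a (voxels x parcels) matrix in CoordinateTable row order.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    parcel_ts = np.asarray(parcel_ts, dtype=float)
    if roi_ts.shape[1] != parcel_ts.shape[1]:
        raise ValueError("ROI and parcel series have different lengths")
    if roi_ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    p_sd = parcel_ts.std(axis=1)
    bad = np.flatnonzero(p_sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance parcel series at rows {bad.tolist()}")
    v_sd = roi_ts.std(axis=1)
    bad = np.flatnonzero(v_sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance ROI voxel series at rows {bad.tolist()}; "
            "exclude or impute upstream"
        )
    T = roi_ts.shape[1]
    zr = (roi_ts - roi_ts.mean(axis=1, keepdims=True)) / v_sd[:, None]
    zp = (parcel_ts - parcel_ts.mean(axis=1, keepdims=True)) / p_sd[:, None]
    F = zr @ zp.T / T
    return np.clip(F, -1.0, 1.0)


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Eta-squared similarity between two fingerprint rows.

    eta2 = 1 - sum_i [(a_i - m_i)^2 + (b_i - m_i)^2]
             / sum_i [(a_i - M)^2 + (b_i - M)^2]

    with m_i = (a_i + b_i)/2 the pointwise mean and M the grand mean of both
    rows. 1 means identical profiles; 0 means deviations from the grand mean
    are entirely anti-shared.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1D arrays of size >= 2")
    m = (a + b) / 2.0
    M = m.mean()
    num = ((a - m) ** 2 + (b - m) ** 2).sum()
    den = ((a - M) ** 2 + (b - M) ** 2).sum()
    if den == 0.0:
        warnings.warn("identical constant profiles; eta-squared defined as 1")
        return 1.0
    return float(1.0 - num / den)


def similarity_matrix(F: np.ndarray) -> np.ndarray:
    """Eta-squared similarity between all pairs of fingerprint rows.

    Vectorized over pairs; diagonal set to 1. Entries are clipped into [0, 1]
    only to absorb floating-point excursions.
    """
    F = np.asarray(F, dtype=float)
    V, n = F.shape
    s1 = F.sum(axis=1)
    s2 = (F**2).sum(axis=1)
    M = (s1[:, None] + s1[None, :]) / (2.0 * n)
    # sum (a-m)^2 + (b-m)^2 = 0.5 * ||a - b||^2
    num = 0.5 * (s2[:, None] + s2[None, :] - 2.0 * (F @ F.T))
    den = s2[:, None] + s2[None, :] - 2.0 * M * (s1[:, None] + s1[None, :]) + 2.0 * n * M**2
    with np.errstate(divide="ignore", invalid="ignore"):
        S = 1.0 - num / den
    S[den == 0.0] = 1.0
    S = np.clip(S, 0.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


@dataclass
class SimilarityGraph:
    """Thresholded similarity graph: weights W, degrees, threshold used."""

    W: np.ndarray
    degrees: np.ndarray
    threshold: float


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def build_connected_graph(S: np.ndarray) -> SimilarityGraph:
    """Keep edges with the largest similarity threshold that preserves a
    single connected component.

    The retention rule is a binary search over the sorted unique off-diagonal
    similarities for the largest t such that the graph with edge set
    {eta2 >= t} is connected; retained edges keep their eta-squared weight.
    Zero-weight pairs never count as edges; if even the all-positive-edges
    graph is disconnected, that is an error.
    """
    S = np.asarray(S, dtype=float)
    V = S.shape[0]
    if V < 2:
        raise ValueError("need at least 2 voxels")
    off = S[~np.eye(V, dtype=bool)]
    vals = np.unique(off[off > 0])
    if vals.size == 0 or not _is_connected(S > 0):
        raise ValueError("similarity graph is disconnected even with all positive edges")
    lo, hi = 0, vals.size - 1  # connectivity is monotone non-increasing in t
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _is_connected(S >= vals[mid]):
            lo = mid
        else:
            hi = mid - 1
    t = float(vals[lo])
    W = np.where(S >= t, S, 0.0)
    np.fill_diagonal(W, 0.0)
    return SimilarityGraph(W=W, degrees=W.sum(axis=1), threshold=t)


@dataclass
class EigenSystem:
    """Solution of (D - W) v = lambda D v, constant mode removed.

    ``eigenvalues``/``eigenvectors`` hold the requested number of smallest
    *nonzero* modes; vectors are D-orthonormal. ``lambda0`` is the discarded
    trivial eigenvalue (~0, constant eigenvector).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lambda0: float
    unstable: bool = False


def laplacian_eigenmap(G: SimilarityGraph, n_components: int = 1) -> EigenSystem:
    """Dense generalized eigendecomposition of the graph Laplacian.

    ROI graphs here have at most a few hundred nodes, so a dense symmetric
    solver is both exact and fast. The first returned eigenvector (smallest
    nonzero eigenvalue) is the dominant connectopic gradient.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    W = np.asarray(G.W, dtype=float)
    d = np.asarray(G.degrees, dtype=float)
    if np.any(d <= 0):
        raise ValueError("graph has isolated nodes")
    L = np.diag(d) - W
    evals, evecs = linalg.eigh(L, np.diag(d))
    if evals[0] > 1e-8:
        raise ValueError("no ~zero eigenvalue found; graph may be disconnected")
    if n_components + 1 > evals.size:
        raise ValueError("n_components exceeds available nontrivial modes")
    unstable = False
    if evals.size > 2 and (evals[2] - evals[1]) < 1e-10:
        warnings.warn("smallest nonzero eigenvalue is (numerically) repeated; "
                      "gradient direction unstable")
        unstable = True
    sel = slice(1, 1 + n_components)
    return EigenSystem(
        eigenvalues=evals[sel].copy(),
        eigenvectors=evecs[:, sel].copy(),
        lambda0=float(evals[0]),
        unstable=unstable,
    )


def orient_and_scale(vec: np.ndarray, world_y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fix the arbitrary eigenvector sign and scale to [0, 1].

    The sign is flipped when the Spearman correlation with the
    anterior-posterior (world y) coordinate is negative, so rostral
    (anterior) ends up high; then the vector is min-max scaled.
    Returns (values, flipped).
    """
    vec = np.asarray(vec, dtype=float)
    if np.ptp(vec) == 0:
        raise ValueError("constant eigenvector: degenerate gradient")
    rho = stats.spearmanr(vec, world_y).statistic
    flipped = bool(np.isfinite(rho) and rho < 0)
    if flipped:
        vec = -vec
    scaled = (vec - vec.min()) / np.ptp(vec)
    return np.round(scaled, _GRADIENT_DECIMALS), flipped


@dataclass
class GradientMap:
    """Dominant connectivity gradient over the ROI voxels.

    ``values`` lies in [0, 1] (0 = most caudal-like, 1 = most rostral-like
    connectivity) in CoordinateTable row order. Per-hemisphere metadata keeps
    the graph threshold, leading eigenvalues and orientation flips auditable.
    """

    values: np.ndarray
    coords: CoordinateTable
    thresholds: dict = field(default_factory=dict)
    eigenvalues: dict = field(default_factory=dict)
    flipped: dict = field(default_factory=dict)
    source: str = "subject"

    def hemi_values(self, hemisphere: str) -> np.ndarray:
        return self.values[self.coords.hemi_rows(hemisphere)]

    def to_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=float)
        out[tuple(self.coords.indices.T)] = self.values
        return out


def compute_gradient(
    S: np.ndarray, coords: CoordinateTable, source: str = "subject"
) -> GradientMap:
    """Per-hemisphere graph + eigenmap + orientation from one similarity matrix."""
    S = np.asarray(S, dtype=float)
    if S.shape[0] != len(coords):
        raise ValueError("similarity matrix does not match coordinate table")
    values = np.empty(len(coords))
    thresholds, eigenvalues, flipped = {}, {}, {}
    for name, code in (("left", LEFT), ("right", RIGHT)):
        rows = coords.hemi_rows(code)
        G = build_connected_graph(S[np.ix_(rows, rows)])
        eig = laplacian_eigenmap(G, n_components=1)
        vals, flip = orient_and_scale(eig.eigenvectors[:, 0], coords.world[rows, 1])
        values[rows] = vals
        thresholds[name] = G.threshold
        eigenvalues[name] = eig.eigenvalues.tolist()
        flipped[name] = flip
    return GradientMap(
        values=values,
        coords=coords,
        thresholds=thresholds,
        eigenvalues=eigenvalues,
        flipped=flipped,
        source=source,
    )


def group_gradient(S_list, coords: CoordinateTable) -> GradientMap:
    """Group gradient: average the similarity matrices, then decompose once.

    Averaging at the similarity level sidesteps per-subject eigenvector sign
    and ordering alignment, which is exactly where individual gradient
    estimates are unstable.
    """
    S_list = list(S_list)
    if not S_list:
        raise ValueError("empty similarity list")
    S = np.mean(np.stack(S_list), axis=0)
    return compute_gradient(S, coords, source="group")


def partition_rostral_caudal(g: GradientMap) -> np.ndarray:
    """Label voxels 'rostral' (value > 0.5) or 'caudal' (<= 0.5)."""
    return np.where(np.asarray(g.values) > 0.5, "rostral", "caudal")


def projection_map(F, voxel_labels, parcel_ids=None) -> dict:
    """Label each parcel by the partition label of its best-correlated voxel.

    ``F`` is one fingerprint matrix or a list of them (one per subject), with
    matching ``voxel_labels`` (one array, or a list). For a single subject the
    parcel inherits the label of the ROI voxel with maximal correlation (ties
    resolved to the first voxel in CoordinateTable order, logged); across
    subjects the per-subject labels are reduced by majority vote, ties going
    to 'rostral'.
    """
    multi = isinstance(F, (list, tuple))
    F_list = list(F) if multi else [F]
    if multi and isinstance(voxel_labels, (list, tuple)):
        lab_list = list(voxel_labels)
    else:
        lab_list = [np.asarray(voxel_labels)] * len(F_list)
    P = F_list[0].shape[1]
    if parcel_ids is None:
        parcel_ids = list(range(P))
    votes = {pid: [] for pid in parcel_ids}
    for Fi, labs in zip(F_list, lab_list):
        labs = np.asarray(labs)
        for p, pid in enumerate(parcel_ids):
            col = Fi[:, p]
            best = np.flatnonzero(col == col.max())
            if best.size > 1:
                logger.info("parcel %s: %d-way tie in max correlation; "
                            "first voxel in order used", pid, best.size)
            votes[pid].append(str(labs[best[0]]))
    out = {}
    for pid, vs in votes.items():
        n_r = sum(v == "rostral" for v in vs)
        out[pid] = "rostral" if n_r * 2 >= len(vs) else "caudal"
    return out
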