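"""Mutual-information correlation networks and eigenvector centrality.

Residue-pair coupling is measured as the generalized correlation coefficient

    r_MI[x_i, x_j] = (1 - exp(-(2/3) I[x_i, x_j]))^(1/2)

where ``I`` is the mutual information (nats) between the two residues' 3-D
Cα displacement vectors, I = S[x_i] + S[x_j] - S[x_i, x_j] in terms of
marginal and joint Shannon entropies.  The exponent 2/3 is fixed by the
3-dimensional variables; logarithms are natural throughout.  r_MI ranges from
0 (uncorrelated) to 1 (fully correlated).

Two estimators are provided: the Gaussian closed form (default; fast and
analytically testable) and a Kraskov-style k-nearest-neighbour estimate for
non-Gaussian ensembles.  The per-pair r_MI values form a symmetric adjacency
matrix A whose leading eigenvector (Perron-Frobenius, unit L2 norm) is the
eigenvector-centrality profile; differences of normalized profiles between
two states localize where a perturbation (effector analog, heating) shifts
the communication network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import digamma

from .ensembles import Ensemble
from .errors import DegenerateNetworkError, InsufficientDataError
from .structure import superpose

__all__ = [
    "I_CAP",
    "MIEstimate",
    "CorrelationNetwork",
    "CentralityProfile",
    "estimate_mi",
    "generalized_correlation",
    "ca_displacements",
    "build_network",
    "eigenvector_centrality",
    "centrality_difference",
]

#: cap (nats) returned for degenerate / fully correlated pairs
I_CAP = 30.0

MIN_FRAMES = 100


@dataclass(frozen=True)
class MIEstimate:
    """Mutual information (nats) between two 3-D displacement streams.

    Marginal/joint differential entropies are reported by the Gaussian
    estimator and ``None`` for knn (which never materializes densities).
    """

    I: float
    S_i: float | None = None
    S_j: float | None = None
    S_ij: float | None = None
    estimator: str = "gaussian"
    degenerate: bool = False


@dataclass
class CorrelationNetwork:
    """Symmetric r_MI adjacency matrix over residue nodes (zero diagonal)."""

    nodes: list[str]
    matrix: np.ndarray          # (N, N) r_MI values in [0, 1]
    estimator: str = "gaussian"
    n_frames: int = 0

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("r_MI entries must lie in [0, 1]")
        self.matrix = a


@dataclass
class CentralityProfile:
    """Leading eigenpair of a correlation network: unit-L2, non-negative."""

    nodes: list[str]
    centrality: np.ndarray      # (N,) >= 0, ||c||_2 = 1
    eigenvalue: float
    normalization: str = "l2"


def _gaussian_mi(x: np.ndarray, y: np.ndarray) -> MIEstimate:
    d = x.shape[1]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = len(xc)
    cov_i = xc.T @ xc / (n - 1)
    cov_j = yc.T @ yc / (n - 1)
    cov_ij = np.cov(np.hstack([xc, yc]).T)
    si, ldi = np.linalg.slogdet(cov_i)
    sj, ldj = np.linalg.slogdet(cov_j)
    sij, ldij = np.linalg.slogdet(cov_ij)
    const = 0.5 * d * (1.0 + np.log(2 * np.pi))
    if si <= 0 or sj <= 0 or sij <= 0:
        return MIEstimate(I=I_CAP, estimator="gaussian", degenerate=True)
    entropy_i = const + 0.5 * ldi
    entropy_j = const + 0.5 * ldj
    entropy_ij = 2 * const + 0.5 * ldij
    mi = entropy_i + entropy_j - entropy_ij
    if not np.isfinite(mi) or mi >= I_CAP:
        return MIEstimate(I=I_CAP, S_i=entropy_i, S_j=entropy_j, S_ij=entropy_ij,
                          estimator="gaussian", degenerate=True)
    return MIEstimate(I=max(mi, 0.0), S_i=entropy_i, S_j=entropy_j,
                      S_ij=entropy_ij, estimator="gaussian")


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int) -> MIEstimate:
    # Kraskov-Stögbauer-Grassberger estimator (algorithm 1), Chebyshev metric
    n = len(x)
    z = np.hstack([x, y])
    dist, _ = cKDTree(z).query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    if np.any(eps <= 0):
        return MIEstimate(I=I_CAP, estimator=f"knn(k={k})", degenerate=True)
    shrink = eps * (1 - 1e-10)
    nx = cKDTree(x).query_ball_point(x, r=shrink, p=np.inf, return_length=True) - 1
    ny = cKDTree(y).query_ball_point(y, r=shrink, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return MIEstimate(I=float(np.clip(mi, 0.0, I_CAP)),
                      estimator=f"knn(k={k})", degenerate=bool(mi >= I_CAP))


def estimate_mi(x_i: np.ndarray, x_j: np.ndarray,
                estimator: str = "gaussian", k: int = 6) -> MIEstimate:
    """Mutual information between two per-frame 3-vector streams.

    ``x_i`` and ``x_j`` are ``(frames, 3)`` mean-centered displacement vectors
    (centering is re-applied defensively).  The Gaussian estimator returns the
    closed form ``0.5 ln(det Σ_i det Σ_j / det Σ_ij)``; ``knn`` the
    Kraskov-style estimate with ``k`` neighbours.  Results are clamped to
    ``[0, I_CAP]``; a singular joint covariance yields ``I_CAP`` with the
    degeneracy flag set.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"frame-count mismatch: {x_i.shape} vs {x_j.shape}")
    if x_i.ndim != 2:
        raise ValueError("inputs must be (frames, d) arrays")
    if len(x_i) < MIN_FRAMES:
        raise InsufficientDataError(
            f"need >= {MIN_FRAMES} frames for MI estimation, got {len(x_i)}")
    if estimator == "gaussian":
        return _gaussian_mi(x_i, x_j)
    if estimator == "knn":
        return _ksg_mi(x_i - x_i.mean(axis=0), x_j - x_j.mean(axis=0), k)
    raise ValueError(f"unknown estimator {estimator!r}")


def generalized_correlation(I: float) -> float:
    """Map mutual information (nats) to the generalized correlation r_MI.

    r_MI = (1 - exp(-(2/3) I))^(1/2); monotone, r_MI(0) = 0, r_MI -> 1 as
    I -> infinity.
    """
    if I < 0:
        raise ValueError(f"mutual information must be >= 0, got {I}")
    return float(np.sqrt(-np.expm1(-2.0 * I / 3.0)))


def ca_displacements(ensemble: Ensemble, n_iterations: int = 2) -> np.ndarray:
    """Mean-centered Cα displacements after iterated superposition onto the mean.

    Returns ``(frames, residues, 3)``.  Rigid-body motion is removed by a
    Kabsch fit of every frame onto the ensemble mean, iterated so the mean is
    self-consistent.
    """
    aligned, _ = superpose(ensemble, reference="mean", n_iterations=n_iterations)
    ca = aligned.ca_coords
    return ca - ca.mean(axis=0)


def build_network(ensemble: Ensemble, estimator: str = "gaussian", k: int = 6,
                  superpose_frames: bool = True) -> CorrelationNetwork:
    """Build the r_MI adjacency matrix over all residue pairs.

    Each node is a residue's Cα.  Frames are superposed onto the ensemble mean
    first (disable only for pre-aligned displacement data).  The Gaussian
    estimator is evaluated from one pooled 3N x 3N displacement covariance,
    which makes the all-pairs build O(N²) small determinants.
    """
    if ensemble.n_frames < MIN_FRAMES:
        raise InsufficientDataError(
            f"need >= {MIN_FRAMES} frames to build a network, got {ensemble.n_frames}")
    if superpose_frames:
        disp = ca_displacements(ensemble)
    else:
        ca = ensemble.ca_coords
        disp = ca - ca.mean(axis=0)
    n_frames, n_res, _ = disp.shape
    a = np.zeros((n_res, n_res))
    if estimator == "gaussian":
        flat = disp.reshape(n_frames, 3 * n_res)
        cov = np.cov(flat.T)
        blocks = cov.reshape(n_res, 3, n_res, 3)
        idx = np.arange(n_res)
        sign_m, ld_m = np.linalg.slogdet(blocks[idx, :, idx, :])
        iu, ju = np.triu_indices(n_res, k=1)
        joint = np.empty((len(iu), 6, 6))
        joint[:, :3, :3] = blocks[iu, :, iu, :]
        joint[:, 3:, 3:] = blocks[ju, :, ju, :]
        joint[:, :3, 3:] = blocks[iu, :, ju, :]
        joint[:, 3:, :3] = np.swapaxes(blocks[iu, :, ju, :], 1, 2)
        sign_j, ld_j = np.linalg.slogdet(joint)
        mi = 0.5 * (ld_m[iu] + ld_m[ju] - ld_j)
        mi = np.where((sign_m[iu] <= 0) | (sign_m[ju] <= 0) | (sign_j <= 0),
                      I_CAP, mi)
        mi = np.clip(mi, 0.0, I_CAP)
        a[iu, ju] = np.sqrt(-np.expm1(-2.0 * mi / 3.0))
        a[ju, iu] = a[iu, ju]
    else:
        for i in range(n_res):
            for j in range(i + 1, n_res):
                est = estimate_mi(disp[:, i], disp[:, j], estimator=estimator, k=k)
                a[i, j] = a[j, i] = generalized_correlation(est.I)
    return CorrelationNetwork(nodes=ensemble.topology.labels, matrix=a,
                              estimator=estimator, n_frames=n_frames)


def eigenvector_centrality(network: CorrelationNetwork,
                           method: str = "dense",
                           tol: float = 1e-14, max_iter: int = 100000
                           ) -> CentralityProfile:
    """Leading eigenpair of the adjacency matrix (Perron-Frobenius sign fix).

    On a disconnected network the profile is computed on the largest connected
    component; nodes outside it get centrality 0 (with a warning).  ``method``
    is ``"dense"`` (symmetric eigendecomposition, default) or ``"power"``
    (power iteration); both satisfy ``A c = ε c`` to 1e-8.
    """
    a = network.matrix
    if np.all(a == 0):
        raise DegenerateNetworkError("all-zero adjacency matrix has no centrality")
    n_comp, comp = connected_components((a > 0).astype(int), directed=False)
    keep = np.arange(len(a))
    if n_comp > 1:
        sizes = np.bincount(comp)
        largest = int(np.argmax(sizes))
        keep = np.nonzero(comp == largest)[0]
        warnings.warn(
            f"network has {n_comp} components; centrality computed on the "
            f"largest ({len(keep)} nodes), others set to 0")
    sub = a[np.ix_(keep, keep)]
    if method == "dense":
        evals, evecs = np.linalg.eigh(sub)
        eps = float(evals[-1])
        vec = evecs[:, -1]
    elif method == "power":
        rng = np.random.default_rng(0)
        vec = np.abs(rng.standard_normal(len(sub))) + 1.0
        vec /= np.linalg.norm(vec)
        eps = 0.0
        for _ in range(max_iter):
            nxt = sub @ vec
            eps = float(np.linalg.norm(nxt))
            nxt /= eps
            if np.linalg.norm(nxt - vec) < tol:
                vec = nxt
                break
            vec = nxt
    else:
        raise ValueError(f"unknown method {method!r}")
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec = vec / np.linalg.norm(vec)
    c = np.zeros(len(a))
    c[keep] = vec
    return CentralityProfile(nodes=list(network.nodes), centrality=c,
                             eigenvalue=eps)


def centrality_difference(profile_a: CentralityProfile,
                          profile_b: CentralityProfile) -> dict:
    """Per-residue ΔEC = c(B) - c(A) on unit-L2 profiles.

    Returns a dict with the per-node difference and the summed positive /
    negative parts (the sideR/sideL-style aggregation).
    """
    if list(profile_a.nodes) != list(profile_b.nodes):
        extra = set(profile_a.nodes) ^ set(profile_b.nodes)
        raise ValueError(f"node sets differ: {sorted(extra)}")
    delta = profile_b.centrality - profile_a.centrality
    return {
        "nodes": list(profile_a.nodes),
        "delta": delta,
        "positive_sum": float(delta[delta > 0].sum()),
        "negative_sum": float(delta[delta < 0].sum()),
    }
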