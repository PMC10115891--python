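"""Essential dynamics: PCA of aligned Cα/backbone coordinates.

The covariance matrix of flattened, mean-free coordinates is diagonalized
with a dense symmetric solver (deterministic; no truncated/randomized
routines), modes sorted by descending eigenvalue (Å²).  Besides the standard
variance-explained spectrum, a second metric is reported: the cumulative sum
of the *squared* eigenvalues normalized by their total — the "total kinetic
variance" convention some ensemble-comparison figures use.  Both are labeled
distinctly and neither silently replaces the other.

A joint basis fitted on the frame-concatenated coordinates of several states
lets the states be projected into one shared low-dimensional space; the
overlap of their 1-D projection histograms (Bhattacharyya coefficient) per
component quantifies how separable the states are along each mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import Ensemble

__all__ = [
    "PCAModel",
    "fit_pca",
    "project",
    "variance_metrics",
    "joint_basis",
    "projection_overlap",
]


@dataclass
class PCAModel:
    """Eigenmodes of the coordinate covariance, descending eigenvalue order."""

    mean: np.ndarray            # (3M,) flattened mean of the selected atoms
    modes: np.ndarray           # (3M, K) orthonormal columns
    eigenvalues: np.ndarray     # (K,) >= 0, non-increasing, Å²
    basis: str                  # "single-state" | "joint"
    selection: str              # "ca" | "backbone"
    atom_indices: np.ndarray    # indices of the selected atoms in the topology

    def __post_init__(self):
        lam = self.eigenvalues
        if np.any(lam < -1e-8):
            raise ValueError("negative eigenvalue in PCA model")
        if np.any(np.diff(lam) > 1e-8):
            raise ValueError("eigenvalues must be non-increasing")
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("modes are not orthonormal")


def _selected_atoms(ensemble: Ensemble, selection: str) -> np.ndarray:
    top = ensemble.topology
    if selection == "ca":
        return top.ca_indices
    if selection == "backbone":
        mask = np.isin(top.atom_names, ("N", "CA", "C", "O"))
        return np.nonzero(mask)[0]
    raise ValueError(f"unknown selection {selection!r}")


def _flat(ensemble: Ensemble, atoms: np.ndarray) -> np.ndarray:
    return ensemble.coords[:, atoms, :].reshape(ensemble.n_frames, -1)


def fit_pca(ensemble: Ensemble, selection: str = "ca") -> PCAModel:
    """Diagonalize the covariance of the selected coordinates.

    The ensemble must be aligned (``superpose`` records this as a pipeline
    step); PCA on unaligned frames would mix rigid-body and internal motion.
    """
    if not ensemble.aligned:
        raise ValueError("ensemble must be aligned before PCA (run superpose)")
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    atoms = _selected_atoms(ensemble, selection)
    x = _flat(ensemble, atoms)
    mean = x.mean(axis=0)
    cov = np.cov((x - mean).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return PCAModel(mean=mean, modes=evecs[:, order],
                    eigenvalues=np.clip(evals[order], 0.0, None),
                    basis="single-state", selection=selection,
                    atom_indices=atoms)


def project(ensemble: Ensemble, model: PCAModel,
            n_components: int | None = None) -> np.ndarray:
    """Per-frame projections ``(frame - mean) · modes``, shape (F, k)."""
    atoms = _selected_atoms(ensemble, model.selection)
    if len(atoms) != len(model.atom_indices):
        raise ValueError("ensemble selection does not match the PCA model")
    x = _flat(ensemble, atoms) - model.mean
    k = model.modes.shape[1] if n_components is None else int(n_components)
    return x @ model.modes[:, :k]


def variance_metrics(model: PCAModel, k: int | None = None) -> dict:
    """Variance spectra up to component ``k``.

    Returns per-mode variance fractions ``λ_m / Σλ`` with their cumulative
    sum (``variance_explained`` / ``cumulative_variance``), and the
    squared-eigenvalue cumulative metric ``Σ_{m<=k} λ_m² / Σ λ²``
    (``cumulative_squared_eigenvalue``), each labeled distinctly.
    """
    lam = model.eigenvalues
    if k is None:
        k = len(lam)
    if k > len(lam):
        raise ValueError(f"k={k} exceeds the {len(lam)} available modes")
    total = lam.sum()
    total_sq = np.sum(lam ** 2)
    frac = lam[:k] / total if total > 0 else np.zeros(k)
    frac_sq = lam[:k] ** 2 / total_sq if total_sq > 0 else np.zeros(k)
    return {
        "variance_explained": frac,
        "cumulative_variance": np.cumsum(frac),
        "cumulative_squared_eigenvalue": np.cumsum(frac_sq),
        "eigenvalues": lam[:k],
    }


def joint_basis(ensembles: list[Ensemble], selection: str = "ca") -> PCAModel:
    """PCA on the frame-concatenated coordinates of several aligned states.

    All ensembles must share a topology (atom counts and roles) and be
    aligned to a common reference; the shared mean and modes define one
    transformation applied to every state.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    atoms0 = _selected_atoms(ensembles[0], selection)
    blocks = []
    for ens in ensembles:
        if not ens.aligned:
            raise ValueError("all ensembles must be aligned before joint PCA")
        atoms = _selected_atoms(ens, selection)
        if len(atoms) != len(atoms0):
            raise ValueError("ensembles have mismatched topologies")
        blocks.append(_flat(ens, atoms))
    x = np.vstack(blocks)
    mean = x.mean(axis=0)
    cov = np.cov((x - mean).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return PCAModel(mean=mean, modes=evecs[:, order],
                    eigenvalues=np.clip(evals[order], 0.0, None),
                    basis="joint", selection=selection, atom_indices=atoms0)


def projection_overlap(proj_a: np.ndarray, proj_b: np.ndarray,
                       bins: int = 50) -> float:
    """Bhattacharyya coefficient of two 1-D projection histograms.

    1 means indistinguishable distributions, 0 disjoint support; shared bin
    edges span the pooled range.
    """
    lo = min(proj_a.min(), proj_b.min())
    hi = max(proj_a.max(), proj_b.max())
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(proj_a, bins=edges, density=False)
    pb, _ = np.histogram(proj_b, bins=edges, density=False)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.sum(np.sqrt(pa * pb)))
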