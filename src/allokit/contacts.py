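"""Residue-residue atomic contact networks and their state differences.

A contact exists between two residues in a frame for every atom pair (one
atom from each residue) closer than a distance cutoff (default 5 Å).  The
edge weight ``w_ij`` is the mean atomic-contact count per frame, so the
conventional perturbation threshold ``w_t = 6`` is independent of how many
frames were sampled (a raw-total aggregation over frames is available via
``aggregate="sum"``).

Two modes:

* ``symmetric`` — all heavy atoms of both residues (hydrogens excluded);
* ``asymmetric`` — the backbone amide (NH) group of residue i (N plus its
  amide H if present) against the heavy atoms of every other residue; this
  view is directional and mirrors what an amide-proton chemical shift "sees".

Differencing two states yields the dynamical perturbation contact network
(DPCN): edges with ``|Δw|`` above the threshold, signed by contact gain or
loss.  Rank (Spearman) correlation between two DPCNs over their supra-floor
pair union measures how similar two perturbations are — e.g. effector binding
versus heating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ensembles import Ensemble
from .errors import InsufficientDataError

__all__ = [
    "ContactNetwork",
    "PerturbationNetwork",
    "count_contacts",
    "perturbation_network",
    "network_similarity",
]


@dataclass
class ContactNetwork:
    """Mean atomic contact counts per residue pair."""

    nodes: list[str]
    matrix: np.ndarray          # (R, R); symmetric in symmetric mode
    mode: str                   # "symmetric" | "asymmetric"
    cutoff: float               # Å
    n_frames: int
    min_seq_sep: int = 1
    aggregate: str = "mean"


@dataclass
class PerturbationNetwork:
    """Contact-weight differences Δw = w(B) - w(A) with threshold ``w_t``."""

    nodes: list[str]
    matrix: np.ndarray          # Δw per pair
    w_t: float = 6.0
    mode: str = "symmetric"

    def edges(self):
        """Supra-threshold edges [(i, j, Δw), ...], |Δw| > w_t.

        Unordered pairs in symmetric mode, ordered in asymmetric mode.
        """
        out = []
        n = len(self.nodes)
        symmetric = self.mode == "symmetric"
        for i in range(n):
            rng = range(i + 1, n) if symmetric else range(n)
            for j in rng:
                if j != i and abs(self.matrix[i, j]) > self.w_t:
                    out.append((i, j, float(self.matrix[i, j])))
        return out

    def node_strengths(self):
        """Per-residue totals of gained and lost supra-threshold contacts."""
        gained = np.zeros(len(self.nodes))
        lost = np.zeros(len(self.nodes))
        for i, j, dw in self.edges():
            tgt = gained if dw > 0 else lost
            tgt[i] += abs(dw)
            tgt[j] += abs(dw)
        return gained, lost


def _eligible_pair_mask(top, min_seq_sep: int) -> np.ndarray:
    n = top.n_residues
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    same_chain = top.chain_tags[ii] == top.chain_tags[jj]
    sep = np.abs(top.res_ids[ii] - top.res_ids[jj])
    mask = ~((same_chain & (sep < min_seq_sep)) | (ii == jj))
    return mask


def count_contacts(ensemble: Ensemble, cutoff: float = 5.0,
                   mode: str = "symmetric", min_seq_sep: int = 1,
                   aggregate: str = "mean", chunk: int = 100) -> ContactNetwork:
    """Count per-frame atomic contacts between residues, averaged over frames.

    ``min_seq_sep`` excludes pairs with within-chain sequence separation below
    it (the default 1 excludes only self-contacts and keeps i, i+1).
    """
    if mode not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    top = ensemble.topology
    heavy = top.heavy_mask
    if not heavy.any():
        raise ValueError("topology has no heavy atoms")
    n_res = top.n_residues

    if mode == "symmetric":
        rows_sel = np.nonzero(heavy)[0]
        cols_sel = rows_sel
    else:
        is_nh = (top.atom_names == "N") | (top.atom_names == "H")
        rows_sel = np.nonzero(is_nh)[0]         # NH group atoms (donor side)
        cols_sel = np.nonzero(heavy)[0]         # heavy atoms (environment side)
        if len(rows_sel) == 0:
            raise ValueError("no backbone N/H atoms for asymmetric mode")

    row_res = top.atom_residue[rows_sel]
    col_res = top.atom_residue[cols_sel]
    pair_idx = row_res[:, None] * n_res + col_res[None, :]
    eligible = _eligible_pair_mask(top, min_seq_sep)[row_res[:, None], col_res[None, :]]
    if mode == "symmetric":
        # count each unordered atom pair once: keep strictly increasing atom index
        eligible = eligible & (rows_sel[:, None] < cols_sel[None, :])

    counts = np.zeros(n_res * n_res)
    cutoff2 = cutoff * cutoff
    coords = ensemble.coords
    # flatten to an explicit eligible atom-pair list: O(frames * pairs)
    pr, pc = np.nonzero(eligible)
    atoms_i = rows_sel[pr]
    atoms_j = cols_sel[pc]
    sel_pairs = pair_idx[pr, pc]
    for start in range(0, ensemble.n_frames, chunk):
        block = coords[start:start + chunk]
        diff = block[:, atoms_i, :] - block[:, atoms_j, :]
        within = np.einsum("fpx,fpx->fp", diff, diff) < cutoff2
        counts += np.bincount(
            np.broadcast_to(sel_pairs, within.shape)[within],
            minlength=n_res * n_res)
    w = counts.reshape(n_res, n_res)
    if mode == "symmetric":
        w = w + w.T     # fold the i<j counts into a symmetric matrix
    if aggregate == "mean":
        w = w / ensemble.n_frames
    return ContactNetwork(nodes=top.labels, matrix=w, mode=mode, cutoff=cutoff,
                          n_frames=ensemble.n_frames, min_seq_sep=min_seq_sep,
                          aggregate=aggregate)


def perturbation_network(net_a: ContactNetwork, net_b: ContactNetwork,
                         w_t: float = 6.0) -> PerturbationNetwork:
    """Difference two contact networks into a perturbation network.

    Requires identical topology, mode, cutoff and aggregation.  Swapping A
    and B flips every edge sign.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("contact networks cover different residue sets")
    for attr in ("mode", "cutoff", "min_seq_sep", "aggregate"):
        if getattr(net_a, attr) != getattr(net_b, attr):
            raise ValueError(
                f"contact networks differ in {attr}: "
                f"{getattr(net_a, attr)!r} vs {getattr(net_b, attr)!r}")
    return PerturbationNetwork(nodes=list(net_a.nodes),
                               matrix=net_b.matrix - net_a.matrix,
                               w_t=w_t, mode=net_a.mode)


def network_similarity(pn_1: PerturbationNetwork, pn_2: PerturbationNetwork,
                       weight_floor: float = 6.0) -> tuple[float, int]:
    """Spearman rank correlation between two perturbation networks.

    Compared over the union of residue pairs whose ``|Δw|`` reaches the floor
    in either network.  Returns ``(rho, n_pairs)``.
    """
    if pn_1.nodes != pn_2.nodes:
        raise ValueError("perturbation networks cover different residue sets")
    n = len(pn_1.nodes)
    if pn_1.mode == "symmetric" and pn_2.mode == "symmetric":
        iu, ju = np.triu_indices(n, k=1)
    else:
        iu, ju = np.nonzero(~np.eye(n, dtype=bool))
    d1 = pn_1.matrix[iu, ju]
    d2 = pn_2.matrix[iu, ju]
    keep = (np.abs(d1) >= weight_floor) | (np.abs(d2) >= weight_floor)
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} residue pairs pass the weight floor; need >= 3")
    rho, _ = stats.spearmanr(d1[keep], d2[keep])
    return float(rho), int(keep.sum())
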