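"""Structural metrics over ensembles: superposition, RMSF, secondary
structure persistency, hinge angles and hydrogen-bond series.

Superposition is the standard least-squares rigid fit (Kabsch construction
with a reflection guard) on Cα atoms.  Secondary structure uses a simplified
Kabsch-Sander assigner: backbone hydrogen bonds are scored with the
electrostatic energy model

    E = q1 q2 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332 kcal/mol

(q1 q2 * 332 = 27.888 kcal Å/mol), a bond existing when E < -0.5 kcal/mol;
helix is read off i -> i+4 (plus i+3 / i+5) turn patterns, sheet off bridge
patterns, everything else coil — the 3-class helix/sheet/coil mapping used to
compare per-residue persistency between states.  Per-frame external
assignment tables are also accepted, so the assigner is never a bottleneck
for real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import Ensemble
from .errors import DegenerateFitError

__all__ = [
    "SSERecord",
    "AngleSeries",
    "HBondSeries",
    "kabsch_rotation",
    "superpose",
    "rmsf",
    "assign_sse",
    "sse_persistency",
    "hinge_angle",
    "hbond_series",
]

HB_ENERGY_FACTOR = 27.888      # q1*q2*332 kcal*Å/mol (Kabsch-Sander)
HB_ENERGY_CUTOFF = -0.5        # kcal/mol


# ---------------------------------------------------------------------------
# superposition / fluctuations


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix mapping centered ``mobile`` onto centered
    ``target`` (det = +1 enforced)."""
    h = mobile.T @ target
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def _check_not_degenerate(ca: np.ndarray) -> None:
    if len(ca) < 3:
        raise DegenerateFitError("need >= 3 Cα atoms for a rigid fit")
    centered = ca - ca.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateFitError("Cα set is collinear; rigid fit under-determined")


def superpose(ensemble: Ensemble, reference="mean", n_iterations: int = 20,
              tol: float = 1e-12) -> tuple[Ensemble, np.ndarray]:
    """Least-squares rigid fit of every frame onto a reference (Cα atoms).

    ``reference`` is ``"mean"`` (the ensemble mean, iterated to
    self-consistency so the operation is idempotent), a frame index, or an
    explicit ``(atoms, 3)`` coordinate array.  Returns the aligned ensemble
    (flagged ``aligned=True``) and the per-frame Cα RMSD to the reference,
    in Å.
    """
    coords = ensemble.coords.copy()
    ca_idx = ensemble.topology.ca_indices
    to_mean = isinstance(reference, str) and reference == "mean"
    if to_mean:
        ref_full = coords.mean(axis=0)
        iterations = max(1, n_iterations)
    elif isinstance(reference, (int, np.integer)):
        ref_full = ensemble.coords[int(reference)]
        iterations = 1
    else:
        ref_full = np.asarray(reference, dtype=float)
        if ref_full.shape != coords.shape[1:]:
            raise ValueError("reference coordinates do not match topology")
        iterations = 1
    rmsd = np.zeros(ensemble.n_frames)
    for _ in range(iterations):
        ref_ca = ref_full[ca_idx]
        _check_not_degenerate(ref_ca)
        ref_centroid = ref_ca.mean(axis=0)
        shift = 0.0
        for f in range(len(coords)):
            ca = coords[f, ca_idx]
            centroid = ca.mean(axis=0)
            rot = kabsch_rotation(ca - centroid, ref_ca - ref_centroid)
            new = (coords[f] - centroid) @ rot.T + ref_centroid
            shift = max(shift, float(np.abs(new - coords[f]).max()))
            coords[f] = new
            rmsd[f] = np.sqrt(np.mean(
                np.sum((coords[f, ca_idx] - ref_ca) ** 2, axis=1)))
        if not to_mean:
            break
        ref_full = coords.mean(axis=0)
        if shift < tol:
            break
    return ensemble.with_coords(coords, aligned=True), rmsd


def rmsf(ensemble: Ensemble) -> np.ndarray:
    """Per-residue Cα root-mean-square fluctuation (Å) of an aligned ensemble.

    RMSF_i = sqrt(<|r_i - <r_i>|²>) over frames.  A single-frame ensemble
    returns zeros with a warning.
    """
    if not ensemble.aligned:
        raise ValueError("rmsf requires an aligned ensemble (run superpose first)")
    ca = ensemble.ca_coords
    if len(ca) < 2:
        warnings.warn("single-frame ensemble: RMSF is identically zero")
        return np.zeros(ca.shape[1])
    dev = ca - ca.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# secondary structure


@dataclass
class SSERecord:
    """Per-frame 3-class secondary-structure assignment.

    ``classes`` holds ``"H"`` (helix), ``"E"`` (sheet) or ``"C"`` (coil) per
    frame and residue; ``reference`` is the per-residue reference class the
    persistency is computed against (for synthetic systems, the generator's
    design assignment; for real data, a crystal-structure assignment).
    """

    nodes: list[str]
    classes: np.ndarray                 # (F, R) of "H"/"E"/"C"
    reference: np.ndarray | None = None

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SSERecord":
        """Build from a long-format table with columns frame, residue, sse."""
        pivot = table.pivot(index="frame", columns="residue", values="sse")
        return cls(nodes=list(pivot.columns), classes=pivot.to_numpy())


def _reconstruct_amide_h(n_pos, prev_c, prev_o):
    # DSSP convention: H sits 1.0 Å from N, anti-parallel to the preceding C=O
    direction = prev_c - prev_o
    direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
    return n_pos + direction


def assign_sse(ensemble: Ensemble) -> SSERecord:
    """Simplified Kabsch-Sander assignment into helix/sheet/coil.

    Requires backbone N, CA, C, O; the amide H is reconstructed geometrically
    (1 Å from N, anti-parallel to the preceding carbonyl).  Residues missing a
    backbone atom are forced to coil with a warning.  Helix covers the
    α/3₁₀/π patterns (i -> i+4, i+3, i+5 turns), sheet covers parallel and
    antiparallel bridges, everything else is coil.
    """
    top = ensemble.topology
    n_res = top.n_residues
    idx = {}
    missing = np.zeros(n_res, dtype=bool)
    for role in ("N", "CA", "C", "O"):
        rows = np.full(n_res, -1, dtype=int)
        sel = top.atom_names == role
        rows[top.atom_residue[sel]] = np.nonzero(sel)[0]
        if np.any(rows < 0):
            missing |= rows < 0
        idx[role] = rows
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} residue(s) missing backbone atoms; forced to coil")
    coords = ensemble.coords
    f_cnt = len(coords)
    chain = top.chain_tags
    same_chain_prev = np.zeros(n_res, dtype=bool)
    same_chain_prev[1:] = chain[1:] == chain[:-1]

    def pos(role):
        safe = np.where(idx[role] >= 0, idx[role], 0)
        return coords[:, safe, :]

    n_pos, c_pos, o_pos = pos("N"), pos("C"), pos("O")
    h_pos = n_pos.copy()
    prev_ok = same_chain_prev & ~missing
    prev_ok[1:] &= ~missing[:-1]
    ok = np.nonzero(prev_ok)[0]
    h_pos[:, ok] = _reconstruct_amide_h(
        n_pos[:, ok],
        coords[:, idx["C"][ok - 1], :],
        coords[:, idx["O"][ok - 1], :])

    def dist(a, b):  # (F, R, R) pairwise between acceptor-residue i and donor j
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    r_on = dist(o_pos, n_pos)
    r_ch = dist(c_pos, h_pos)
    r_oh = dist(o_pos, h_pos)
    r_cn = dist(c_pos, n_pos)
    with np.errstate(divide="ignore"):
        energy = HB_ENERGY_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    hbond = energy < HB_ENERGY_CUTOFF
    # invalidate: self/adjacent pairs, residues without backbone or without a
    # reconstructable donor H
    ii, jj = np.meshgrid(np.arange(n_res), np.arange(n_res), indexing="ij")
    invalid = (np.abs(ii - jj) < 2) | missing[ii] | missing[jj] | ~prev_ok[jj]
    hbond[:, invalid] = False

    classes = np.full((f_cnt, n_res), "C", dtype="U1")
    same_run = np.ones(n_res, dtype=bool)   # consecutive-in-chain guard
    same_run[1:] = same_chain_prev[1:]

    def turn(n_sep):
        t = np.zeros((f_cnt, n_res), dtype=bool)
        for i in range(n_res - n_sep):
            if chain[i] == chain[i + n_sep] and same_run[i + 1:i + n_sep + 1].all():
                t[:, i] = hbond[:, i, i + n_sep]
        return t

    helix = np.zeros((f_cnt, n_res), dtype=bool)
    for n_sep in (4, 3, 5):
        t = turn(n_sep)
        # two consecutive n-turns make residues i .. i+n_sep-1 helical
        both = t[:, :-1] & t[:, 1:]
        for i in range(both.shape[1]):
            frames = both[:, i]
            if frames.any():
                helix[frames, i + 1:i + n_sep] = True
    # bridges
    sheet = np.zeros((f_cnt, n_res), dtype=bool)
    anti = hbond & np.swapaxes(hbond, 1, 2)
    para = np.zeros_like(anti)
    para[:, 1:-1, 1:-1] = hbond[:, :-2, 1:-1] & np.swapaxes(hbond, 1, 2)[:, 2:, 1:-1]
    far = np.abs(ii - jj) > 2
    for mat in (anti, para):
        mat &= far
        sheet |= mat.any(axis=2) | mat.any(axis=1)
    sheet &= ~helix
    classes[helix] = "H"
    classes[sheet] = "E"
    classes[:, missing] = "C"
    return SSERecord(nodes=top.labels, classes=classes)


def sse_persistency(record: SSERecord, reference: np.ndarray | list[str]
                    ) -> np.ndarray:
    """Fraction of frames in which each residue retains its reference class."""
    ref = np.asarray(reference, dtype="U1")
    if ref.shape[0] != record.classes.shape[1]:
        raise ValueError("reference assignment must cover all residues")
    return np.mean(record.classes == ref[None, :], axis=0)


# ---------------------------------------------------------------------------
# angles and hydrogen bonds


@dataclass
class AngleSeries:
    """Per-frame angle (degrees) at a vertex Cα between two arm Cα vectors."""

    labels: tuple[str, str, str]        # (arm, vertex, arm)
    angles: np.ndarray                  # (F,) degrees in [0, 180]

    @property
    def mean(self) -> float:
        return float(np.mean(self.angles))

    @property
    def sd(self) -> float:
        return float(np.std(self.angles))


@dataclass
class HBondSeries:
    """Per-frame donor-acceptor distance (Å) and occupancy under a cutoff."""

    donor: str
    acceptor: str
    distances: np.ndarray
    cutoff: float = 3.5

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.distances < self.cutoff))

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances))


def hinge_angle(ensemble: Ensemble, triple: tuple[str, str, str]) -> AngleSeries:
    """Hinge/breathing angle at the middle residue of an ordered Cα triple.

    The angle is between the vectors vertex -> first and vertex -> third, in
    degrees.  Raises on frames with coincident points.
    """
    top = ensemble.topology
    i, v, j = (top.find(lbl) for lbl in triple)
    ca = ensemble.ca_coords
    a = ca[:, i] - ca[:, v]
    b = ca[:, j] - ca[:, v]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        bad = int(np.nonzero((na == 0) | (nb == 0))[0][0])
        raise ValueError(f"coincident Cα positions in frame {bad}: angle undefined")
    cosang = np.clip(np.sum(a * b, axis=1) / (na * nb), -1.0, 1.0)
    return AngleSeries(labels=tuple(triple), angles=np.degrees(np.arccos(cosang)))


def hbond_series(ensemble: Ensemble, donor: str, acceptor: str,
                 cutoff: float = 3.5) -> HBondSeries:
    """Backbone hydrogen-bond distance series for a named atom pair.

    ``donor``/``acceptor`` are ``"fL63:N"`` style labels (residue label,
    colon, atom name).  The criterion is distance-only: occupancy is the
    fraction of frames with the donor-acceptor distance below ``cutoff``.
    """
    top = ensemble.topology

    def atom(spec: str) -> int:
        res_label, _, name = spec.partition(":")
        if not name:
            raise ValueError(f"atom label {spec!r} must be 'residue:atom'")
        return top.atom_index(top.find(res_label), name)

    d_idx, a_idx = atom(donor), atom(acceptor)
    dist = np.linalg.norm(
        ensemble.coords[:, d_idx] - ensemble.coords[:, a_idx], axis=1)
    return HBondSeries(donor=donor, acceptor=acceptor, distances=dist,
                       cutoff=cutoff)
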