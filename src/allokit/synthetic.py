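"""Synthetic conformational ensembles with planted, known ground truth.

Real inputs of this kind of pipeline are microsecond MD trajectories; nothing
here integrates equations of motion.  Instead, ensembles are draws from a
multivariate Gaussian over Cα displacements around a self-avoiding coarse
reference chain, which gives every downstream statistic an analytic oracle:

* planted per-axis correlations between residue pairs fix the pairwise mutual
  information (and hence the generalized correlation) in closed form;
* a scalar ``temperature_scale`` multiplies the covariance, emulating the
  variance increase of a 30 °C → 50 °C heat step;
* two-state "apo/holo analog" pairs differ only by planted coupling changes
  and/or reference-geometry contact shifts, and are emitted together with a
  ground-truth table of expected effect signs;
* amide-shift tables over temperature carry planted linear/quadratic profiles.

All randomness flows through one explicit seed per call; there is no global
random state, and fixed seeds are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensembles import AA_3TO1, Ensemble, Topology

__all__ = [
    "PlantedEnsembleSpec",
    "PlantedShiftSpec",
    "ContactShift",
    "CouplingChange",
    "make_toy_topology",
    "build_covariance",
    "sample_gaussian_ensemble",
    "make_two_state_pair",
    "make_shift_table",
    "make_study_triple",
]

_AA_POOL = [a for a in AA_3TO1 if a != "GLY"]  # toy residues all carry a CB
_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE")


# ---------------------------------------------------------------------------
# toy topology


def _self_avoiding_walk(n: int, rng: np.random.Generator,
                        step: float = 3.8, min_sep: float = 4.0) -> np.ndarray:
    """Compact self-avoiding Cα trace: fixed 3.8 Å steps, non-adjacent beads
    kept >= min_sep, confined to a protein-like globular radius so that a
    realistic fraction of residues ends up buried."""
    radius = max(12.0, 2.9 * n ** (1.0 / 3.0) * 1.7)
    pos = np.zeros((n, 3))
    direction = _unit(rng.standard_normal(3))
    for i in range(1, n):
        for attempt in range(800):
            trial_dir = direction + 0.8 * rng.standard_normal(3)
            # steer back toward the centroid once the chain nears the wall
            if np.linalg.norm(pos[i - 1]) > 0.75 * radius:
                trial_dir -= 0.9 * pos[i - 1] / np.linalg.norm(pos[i - 1])
            trial_dir = _unit(trial_dir)
            trial = pos[i - 1] + step * trial_dir
            ok_sep = i < 2 or np.min(
                np.linalg.norm(pos[: i - 1] - trial, axis=1)) >= min_sep
            if ok_sep and np.linalg.norm(trial) <= radius:
                pos[i] = trial
                direction = trial_dir
                break
        else:  # pragma: no cover - extremely unlikely with the bias above
            raise RuntimeError("self-avoiding walk failed to place a residue")
    return pos - pos.mean(axis=0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_toy_topology(n_residues: int, split: float = 0.5, seed: int = 0,
                      max_sidechain: int = 4) -> tuple[Topology, np.ndarray]:
    """Generate a toy two-chain topology and its reference coordinates.

    Each residue carries backbone N, CA, C, O, an amide H, and 0..max_sidechain
    sidechain heavy atoms within 2.5 Å of the Cα.  Consecutive Cα are ~3.8 Å
    apart and the chain is self-avoiding.  The first ``round(split *
    n_residues)`` residues form chain ``f``, the rest chain ``h``.

    Returns ``(topology, reference_coords)`` with coordinates shaped
    ``(n_atoms, 3)``.  Deterministic for a fixed seed.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if not 0.0 <= split <= 1.0:
        raise ValueError("split must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ca = _self_avoiding_walk(n_residues, rng)

    n_f = int(round(split * n_residues))
    chain_tags, res_ids = [], []
    for i in range(n_residues):
        tag = "f" if i < n_f else "h"
        chain_tags.append(tag)
        res_ids.append(i + 1 if tag == "f" else i - n_f + 1)
    res_names = rng.choice(_AA_POOL, size=n_residues)

    atom_names, elements, atom_residue, coords = [], [], [], []
    for i in range(n_residues):
        # local orthonormal frame along the chain
        nxt = ca[i + 1] - ca[i] if i + 1 < n_residues else ca[i] - ca[i - 1]
        e1 = _unit(nxt)
        helper = rng.standard_normal(3)
        e2 = _unit(np.cross(e1, helper))
        e3 = np.cross(e1, e2)
        n_pos = ca[i] - 1.46 * (0.6 * e1 + 0.8 * e2)
        c_pos = ca[i] + 1.52 * (0.6 * e1 - 0.8 * e2)
        o_pos = c_pos + 1.23 * _unit(-0.3 * e1 - 0.6 * e2 + 0.74 * e3)
        h_pos = n_pos + 1.01 * _unit(-0.5 * e1 - 0.6 * e2 - 0.62 * e3)
        for name, elem, pos in (
            ("N", "N", n_pos), ("CA", "C", ca[i]), ("C", "C", c_pos),
            ("O", "O", o_pos), ("H", "H", h_pos),
        ):
            atom_names.append(name)
            elements.append(elem)
            atom_residue.append(i)
            coords.append(pos)
        n_side = int(rng.integers(1, max_sidechain + 1)) if max_sidechain else 0
        base_dir = _unit(0.2 * e1 + 0.5 * e2 + 0.84 * e3)
        for k in range(n_side):
            radius = 1.5 + 1.0 * k / max(1, max_sidechain - 1)
            jitter = _unit(base_dir + 0.25 * rng.standard_normal(3))
            atom_names.append(_SIDECHAIN_NAMES[k])
            elements.append("C")
            atom_residue.append(i)
            coords.append(ca[i] + min(radius, 2.5) * jitter)

    top = Topology(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        atom_residue=np.array(atom_residue, dtype=int),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(res_names, dtype=object),
        chain_tags=np.array(chain_tags, dtype=object),
    )
    return top, np.array(coords)


# ---------------------------------------------------------------------------
# planted Gaussian ensembles


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Specification of a planted Cα-displacement Gaussian.

    ``covariance_kind``:

    * ``"block"``: identity base (variance ``base_variance`` per coordinate)
      with per-axis correlation ``rho`` planted on each pair in
      ``planted_pairs`` (same rho on x, y and z; axes independent);
    * ``"elastic_network"``: pseudo-inverse of a Kirchhoff matrix built from
      the reference Cα trace with a 7 Å cutoff, Kronecker-expanded to 3N;
    * ``"custom"``: ``custom_covariance`` is the full 3N x 3N matrix.

    ``temperature_scale`` multiplies the covariance (a 50 °C analog of a 30 °C
    state uses a scale > 1).
    """

    n_residues: int
    n_frames: int
    covariance_kind: str = "block"
    planted_pairs: Mapping[tuple[int, int], float] = field(default_factory=dict)
    temperature_scale: float = 1.0
    base_variance: float = 1.0
    custom_covariance: np.ndarray | None = None
    en_cutoff: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.covariance_kind not in ("block", "elastic_network", "custom"):
            raise ValueError(f"unknown covariance_kind {self.covariance_kind!r}")
        for (i, j), rho in dict(self.planted_pairs).items():
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues) or i == j:
                raise KeyError(f"planted pair ({i}, {j}) addresses unknown residues")
            if not abs(rho) < 1.0:
                raise ValueError(f"planted rho for pair ({i}, {j}) must satisfy |rho| < 1")


def build_covariance(spec: PlantedEnsembleSpec,
                     reference_ca: np.ndarray | None = None) -> np.ndarray:
    """Materialize the 3N x 3N displacement covariance for a spec."""
    n3 = 3 * spec.n_residues
    if spec.covariance_kind == "custom":
        cov = np.array(spec.custom_covariance, dtype=float)
        if cov.shape != (n3, n3):
            raise ValueError(f"custom covariance must be {n3} x {n3}")
    elif spec.covariance_kind == "elastic_network":
        if reference_ca is None:
            raise ValueError("elastic_network covariance needs reference Cα coordinates")
        d = np.linalg.norm(reference_ca[:, None] - reference_ca[None, :], axis=-1)
        contact = (d < spec.en_cutoff) & ~np.eye(spec.n_residues, dtype=bool)
        kirchhoff = -contact.astype(float)
        np.fill_diagonal(kirchhoff, contact.sum(axis=1))
        gamma_inv = np.linalg.pinv(kirchhoff, hermitian=True)
        cov = spec.base_variance * np.kron(gamma_inv, np.eye(3))
    else:  # block
        cov = spec.base_variance * np.eye(n3)
        for (i, j), rho in dict(spec.planted_pairs).items():
            for ax in range(3):
                cov[3 * i + ax, 3 * j + ax] = rho * spec.base_variance
                cov[3 * j + ax, 3 * i + ax] = rho * spec.base_variance
    cov = spec.temperature_scale * cov
    return cov


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
    tol = -1e-8 * max(1.0, float(evals.max(initial=1.0)))
    if evals.min() < tol:
        raise ValueError(
            f"covariance is not positive semi-definite: eigenvalue {evals.min():.3e}"
        )
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def sample_gaussian_ensemble(topology: Topology, reference: np.ndarray,
                             spec: PlantedEnsembleSpec, *,
                             state: str | None = None,
                             temperature: float | None = None) -> Ensemble:
    """Draw an ensemble: frame = reference + Gaussian Cα displacement.

    All atoms of a residue move rigidly with that residue's Cα displacement,
    so Cα-level correlations and heavy-atom contact statistics share one
    planted ground truth.
    """
    if topology.n_residues != spec.n_residues:
        raise ValueError("spec.n_residues does not match topology")
    ref_ca = reference[topology.ca_indices]
    cov = build_covariance(spec, reference_ca=ref_ca)
    factor = _covariance_factor(cov)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3 * spec.n_residues))
    disp = (z @ factor.T).reshape(spec.n_frames, spec.n_residues, 3)
    coords = reference[None, :, :] + disp[:, topology.atom_residue, :]
    return Ensemble(
        topology=topology, coords=coords, state=state, temperature=temperature,
        metadata={"spec_seed": spec.seed, "covariance_kind": spec.covariance_kind,
                  "temperature_scale": spec.temperature_scale},
    )


# ---------------------------------------------------------------------------
# two-state pairs with ground truth


@dataclass(frozen=True)
class CouplingChange:
    """Add ``delta_rho`` to the planted per-axis correlation of ``pair``."""
    pair: tuple[int, int]
    delta_rho: float


@dataclass(frozen=True)
class ContactShift:
    """Move residue ``pair[1]`` along the pair axis so the reference Cα
    distance becomes ``distance`` (Å) in state B."""
    pair: tuple[int, int]
    distance: float


def make_two_state_pair(
    topology: Topology,
    reference: np.ndarray,
    base_spec: PlantedEnsembleSpec,
    perturbations: Sequence[CouplingChange | ContactShift] = (),
    *,
    contact_cutoff: float = 5.0,
    state_labels: tuple[str, str] = ("A", "B"),
) -> tuple[Ensemble, Ensemble, list[dict]]:
    """Sample a two-state pair differing only by planted perturbations.

    Returns ``(ensemble_A, ensemble_B, ground_truth)``.  Ground-truth records
    are dicts: coupling changes predict the sign of the eigenvector-centrality
    difference on both residues of the pair; contact shifts predict the sign
    (and reference-geometry magnitude) of the contact-weight difference for
    every residue pair whose geometry changed materially — moving a residue
    necessarily also moves it relative to its chain neighbours, and those
    secondary edges are part of the planted truth.
    """
    from .contacts import count_contacts  # local import; contacts builds on ensembles

    pairs_b = dict(base_spec.planted_pairs)
    ref_b = reference.copy()
    moved = []
    for pert in perturbations:
        i, j = pert.pair
        if not (0 <= i < topology.n_residues and 0 <= j < topology.n_residues):
            raise KeyError(f"perturbation addresses unknown residue pair ({i}, {j})")
        if isinstance(pert, CouplingChange):
            key = (min(i, j), max(i, j))
            rho = pairs_b.get(key, 0.0) + pert.delta_rho
            if not abs(rho) < 1.0:
                raise ValueError(f"perturbed rho {rho:.3f} for pair {key} outside (-1, 1)")
            pairs_b[key] = rho
        else:
            ca = ref_b[topology.ca_indices]
            axis = _unit(ca[j] - ca[i])
            target = ca[i] + pert.distance * axis
            shift = target - ca[j]
            ref_b[topology.atom_residue == j] += shift
            moved.append(j)
    # self-avoidance check on the perturbed reference
    ca_b = ref_b[topology.ca_indices]
    for j in moved:
        others = np.delete(np.arange(topology.n_residues), j)
        dmin = np.min(np.linalg.norm(ca_b[others] - ca_b[j], axis=1))
        if dmin < 3.0:
            raise ValueError(
                f"contact shift leaves residue {j} within {dmin:.2f} Å of the chain"
            )

    spec_a = base_spec
    spec_b = replace(base_spec, planted_pairs=pairs_b, seed=base_spec.seed + 1)
    ens_a = sample_gaussian_ensemble(topology, reference, spec_a, state=state_labels[0])
    ens_b = sample_gaussian_ensemble(topology, ref_b, spec_b, state=state_labels[1])

    truth: list[dict] = []
    for pert in perturbations:
        if isinstance(pert, CouplingChange):
            i, j = sorted(pert.pair)
            truth.append({
                "kind": "coupling", "pair": [i, j], "delta_rho": pert.delta_rho,
                "expected_dec_sign": int(np.sign(pert.delta_rho)),
            })
    if moved:
        # exact-geometry contact oracle: contact-count both references once
        ref_net_a = count_contacts(
            Ensemble(topology=topology, coords=reference[None]), cutoff=contact_cutoff)
        ref_net_b = count_contacts(
            Ensemble(topology=topology, coords=ref_b[None]), cutoff=contact_cutoff)
        delta_ref = ref_net_b.matrix - ref_net_a.matrix
        affected = np.abs(delta_ref) >= 0.5   # any integer contact-count change
        for i, j in zip(*np.nonzero(np.triu(affected, k=1))):
            truth.append({
                "kind": "contact", "pair": [int(i), int(j)],
                "expected_delta_w": float(delta_ref[i, j]),
                "expected_dw_sign": int(np.sign(delta_ref[i, j])),
            })
    return ens_a, ens_b, truth


# ---------------------------------------------------------------------------
# planted shift tables


@dataclass(frozen=True)
class PlantedShiftSpec:
    """Amide-shift series over temperature with planted polynomial profiles.

    ``slopes`` are ppb/K and ``quads`` ppb/K²; ``intercepts`` and ``noise_sd``
    are ppm.  ``t_ref`` defaults to the lowest temperature.
    """

    residues: tuple[str, ...]
    temperatures: tuple[float, ...]
    intercepts: tuple[float, ...]
    slopes: tuple[float, ...]
    quads: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    nucleus: str = "HN"
    t_ref: float | None = None
    seed: int = 0

    def __post_init__(self):
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 2:
            raise ValueError("need at least 2 temperatures")
        if np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must be strictly increasing (no duplicates)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        n = len(self.residues)
        for name in ("intercepts", "slopes"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per residue")
        if self.quads is not None and len(self.quads) != n:
            raise ValueError("quads must have one entry per residue")


def make_shift_table(spec: PlantedShiftSpec) -> pd.DataFrame:
    """Build a shift table: columns residue, nucleus, temperature_K, shift_ppm,
    source.  δ(T) = intercept + slope·(T−T_ref)/1000 + quad·(T−T_ref)²/1000 + ε."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.temperatures, dtype=float)
    t0 = spec.t_ref if spec.t_ref is not None else t.min()
    quads = spec.quads if spec.quads is not None else (0.0,) * len(spec.residues)
    rows = []
    for res, b0, b1, b2 in zip(spec.residues, spec.intercepts, spec.slopes, quads):
        dt = t - t0
        delta = b0 + b1 * dt / 1000.0 + b2 * dt ** 2 / 1000.0
        if spec.noise_sd > 0:
            delta = delta + rng.normal(0.0, spec.noise_sd, size=len(t))
        for temp, val in zip(t, delta):
            rows.append((res, spec.nucleus, temp, val, "experimental"))
    return pd.DataFrame(
        rows, columns=["residue", "nucleus", "temperature_K", "shift_ppm", "source"]
    )


# ---------------------------------------------------------------------------
# the three-state study analog


def make_study_triple(n_residues: int = 48, n_frames: int = 4000, seed: int = 0,
                      split: float = 0.5):
    """Generate the apo30 / apo50 / holo30 analog triple with ground truth.

    The inactive apo30 analog carries moderate couplings routing the
    source-to-destination communication through the most *buried* residues of
    the toy fold.  The "activated" states (apo50 and holo30 analogs) share a
    planted perturbation set: stronger coupling gains chaining the
    effector-site analog residues to the active-site analog through the most
    *solvent-exposed* residues (the internal-to-external transition), plus
    one contact gain between a distant residue pair.  The apo50 analog
    additionally scales its covariance by 1.4, the heating analog.  Returns a
    dict with the three ensembles, topology/reference, source/destination
    labels and the ground-truth records.
    """
    from .pathways import relative_sasa

    top, ref = make_toy_topology(n_residues, split=split, seed=seed)
    n_f = int(np.sum(top.chain_tags == "f"))
    sources = [1, max(2, n_f - 2)]          # effector-site analogs on chain f
    dest = min(n_residues - 2, n_f + 2)     # active-site analog on chain h
    special = {*sources, dest}
    rel = relative_sasa(top, ref)
    order = np.argsort(rel)
    internal_relay = [int(i) for i in order if i not in special][:2]
    external_relay = [int(i) for i in order[::-1]
                      if int(i) not in special and int(i) not in internal_relay][:2]
    internal_chain = [sources[0], *internal_relay, dest]
    external_chain = [sources[0], *external_relay, dest]
    # chained couplings must keep the coupling-graph covariance PSD; with the
    # internal (0.40) and external (0.45) routes forming a 6-cycle the
    # spectrum stays safely positive
    base_pairs = {(min(a, b), max(a, b)): 0.40
                  for a, b in zip(internal_chain, internal_chain[1:])}
    base_pairs[(min(sources[1], internal_relay[0]),
                max(sources[1], internal_relay[0]))] = 0.30
    couplings = [
        CouplingChange(pair=(a, b), delta_rho=0.45)
        for a, b in zip(external_chain, external_chain[1:])
    ] + [CouplingChange(pair=(sources[1], external_relay[0]), delta_rho=0.35)]
    base = PlantedEnsembleSpec(
        n_residues=n_residues, n_frames=n_frames, covariance_kind="block",
        planted_pairs=base_pairs, base_variance=0.35, seed=seed + 10,
    )
    far_pair = _pick_contact_pair(top, ref)
    perturbations = [*couplings, ContactShift(pair=far_pair, distance=4.2)]
    apo30, holo30, truth = make_two_state_pair(
        top, ref, base, perturbations, state_labels=("apo30-analog", "holo30-analog"))
    hot_spec = replace(base, temperature_scale=1.4, seed=seed + 20)
    _, apo50, _ = make_two_state_pair(
        top, ref, hot_spec, perturbations, state_labels=("apo30-analog", "apo50-analog"))
    apo30.temperature, apo50.temperature, holo30.temperature = 303.0, 323.0, 303.0
    return {
        "topology": top, "reference": ref,
        "apo30": apo30, "apo50": apo50, "holo30": holo30,
        "sources": [top.label(s) for s in sources], "dest": top.label(dest),
        "internal_relay": [top.label(i) for i in internal_relay],
        "external_relay": [top.label(i) for i in external_relay],
        "ground_truth": truth,
    }


def _pick_contact_pair(top: Topology, ref: np.ndarray,
                       distance: float = 4.2) -> tuple[int, int]:
    """A residue pair far apart in the reference whose contact shift keeps the
    chain self-avoiding: the pair with the best clearance at the target site."""
    ca = ref[top.ca_indices]
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    n = top.n_residues
    best, best_clear = None, 0.0
    for i in range(n):
        for j in range(i + 3, n):
            if d[i, j] <= max(8.0, distance + 3.0):
                continue
            target = ca[i] + distance * (ca[j] - ca[i]) / d[i, j]
            others = np.delete(np.arange(n), [i, j])
            clear = float(np.min(np.linalg.norm(ca[others] - target, axis=1)))
            if clear > best_clear:
                best, best_clear = (i, j), clear
    if best is None or best_clear < 3.2:
        raise ValueError("no residue pair admits a self-avoiding contact shift")
    return best
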