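"""Shared ensemble data model and file I/O.

The :class:`Ensemble` is the universal input of every analysis stage: a
topology (residues, chains, atom roles) plus a ``frames x atoms x 3``
coordinate array in Å.  Residues live on one of two chains tagged ``f`` and
``h`` (the cyclase/glutaminase two-subunit convention), and user-facing labels
follow the ``fL63`` style: chain tag, one-letter residue code, 1-based residue
number.  Internally every index is 0-based.

Supported formats: multi-model PDB (via biotite) and a compact ``.npz`` array
container with a JSON sidecar; edge lists and per-residue profiles are TSV.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdbio

from .errors import FormatError

__all__ = [
    "Topology",
    "Ensemble",
    "ResidueLabel",
    "parse_residue_label",
    "format_residue_label",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "read_npz",
    "write_npz",
    "write_edge_list",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: backbone atom roles that must be unique within a residue
BACKBONE_ROLES = ("N", "CA", "C", "O")

_LABEL_RE = re.compile(r"^([fh])([A-Z]?)(\d+)$")


@dataclass(frozen=True)
class ResidueLabel:
    """A residue identifier in the two-subunit ``fL63`` naming convention."""

    chain: str          # "f" or "h"
    number: int         # 1-based residue number within the chain
    name: str = ""      # optional one-letter residue code

    def __str__(self) -> str:
        return f"{self.chain}{self.name}{self.number}"


def parse_residue_label(text: str) -> ResidueLabel:
    """Parse ``fL63`` / ``hG50`` style labels; formatting is the exact inverse."""
    m = _LABEL_RE.match(text)
    if m is None:
        raise ValueError(f"malformed residue label: {text!r}")
    chain, name, number = m.groups()
    return ResidueLabel(chain=chain, number=int(number), name=name)


def format_residue_label(label: ResidueLabel) -> str:
    return str(label)


@dataclass
class Topology:
    """Atom-level topology: per-atom arrays plus per-residue arrays.

    ``atom_residue`` maps every atom to its residue index (a total map);
    hydrogens are flagged non-heavy and excluded from contact counting.
    """

    atom_names: np.ndarray      # (A,) str
    elements: np.ndarray        # (A,) str
    atom_residue: np.ndarray    # (A,) int -> residue index
    res_ids: np.ndarray         # (R,) int, 1-based, increasing within a chain
    res_names: np.ndarray       # (R,) str, 3-letter codes
    chain_tags: np.ndarray      # (R,) str, "f" or "h"

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_tags = np.asarray(self.chain_tags, dtype=object)
        if self.atom_residue.min(initial=0) < 0 or (
            self.n_residues and self.atom_residue.max(initial=0) >= self.n_residues
        ):
            raise ValueError("atom_residue must map every atom to a residue")
        for tag in np.unique(self.chain_tags):
            ids = self.res_ids[self.chain_tags == tag]
            if not np.all(np.diff(ids) > 0):
                raise ValueError(f"residue ids not strictly increasing in chain {tag!r}")
        for role in BACKBONE_ROLES:
            counts = np.bincount(
                self.atom_residue[self.atom_names == role], minlength=self.n_residues
            )
            if np.any(counts > 1):
                bad = int(np.argmax(counts > 1))
                raise ValueError(f"residue {bad} has duplicate backbone atom {role}")
        if np.any(np.bincount(
            self.atom_residue[self.atom_names == "CA"], minlength=self.n_residues
        ) != 1):
            raise ValueError("every residue must have exactly one CA")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean per-atom mask; hydrogens excluded from contact counting."""
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    @property
    def ca_indices(self) -> np.ndarray:
        """Atom index of the Cα of each residue, in residue order."""
        idx = np.full(self.n_residues, -1, dtype=int)
        sel = self.atom_names == "CA"
        idx[self.atom_residue[sel]] = np.nonzero(sel)[0]
        return idx

    def atom_index(self, residue: int, name: str) -> int:
        """Index of atom ``name`` in residue ``residue`` (0-based residue index)."""
        sel = np.nonzero((self.atom_residue == residue) & (self.atom_names == name))[0]
        if len(sel) == 0:
            raise KeyError(
                f"atom {name!r} not found in residue {self.label(residue)}"
            )
        return int(sel[0])

    def label(self, residue: int) -> str:
        one = AA_3TO1.get(str(self.res_names[residue]), "")
        return f"{self.chain_tags[residue]}{one}{self.res_ids[residue]}"

    @property
    def labels(self) -> list[str]:
        return [self.label(i) for i in range(self.n_residues)]

    def find(self, label: str | ResidueLabel) -> int:
        """Residue index for an ``fL63``-style label (name part optional)."""
        if isinstance(label, str):
            label = parse_residue_label(label)
        sel = np.nonzero(
            (self.chain_tags == label.chain) & (self.res_ids == label.number)
        )[0]
        if len(sel) == 0:
            raise KeyError(f"residue {label} not in topology")
        return int(sel[0])


@dataclass
class Ensemble:
    """A conformational ensemble: topology + per-frame coordinates (Å)."""

    topology: Topology
    coords: np.ndarray                  # (F, A, 3) float64, Å
    state: str | None = None            # e.g. "apo30-analog"
    temperature: float | None = None    # K
    aligned: bool = False               # set by structure.superpose
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms \
                or self.coords.shape[2] != 3:
            raise ValueError(
                f"coordinate array {self.coords.shape} inconsistent with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = int(np.nonzero(~np.isfinite(self.coords).all(axis=(1, 2)))[0][0])
            raise ValueError(f"non-finite coordinates in frame {bad}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, shape (frames, residues, 3)."""
        return self.coords[:, self.topology.ca_indices, :]

    def mean_structure(self) -> np.ndarray:
        """Per-atom mean coordinates over frames, shape (atoms, 3)."""
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, **changes) -> "Ensemble":
        return replace(self, coords=coords, **changes)


# ---------------------------------------------------------------------------
# biotite bridge

_DEFAULT_CHAIN_IDS = {"f": "F", "h": "H"}


def to_atom_array(ensemble_or_topology, coords: np.ndarray | None = None,
                  chain_ids: dict[str, str] | None = None):
    """Build a biotite AtomArray (coords: (A,3)) or AtomArrayStack ((F,A,3))."""
    if isinstance(ensemble_or_topology, Ensemble):
        top = ensemble_or_topology.topology
        if coords is None:
            coords = ensemble_or_topology.coords
    else:
        top = ensemble_or_topology
        if coords is None:
            raise ValueError("coords required when passing a bare topology")
    chain_ids = chain_ids or _DEFAULT_CHAIN_IDS
    coords = np.asarray(coords, dtype=np.float32)
    single = coords.ndim == 2
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([chain_ids[t] for t in top.chain_tags[top.atom_residue]])
    arr.res_id = top.res_ids[top.atom_residue].astype(int)
    arr.res_name = top.res_names[top.atom_residue].astype("U5")
    arr.atom_name = top.atom_names.astype("U6")
    arr.element = np.array([e.upper() for e in top.elements], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    if single:
        arr.coord = coords
        return arr
    stack = struc.stack([arr] * coords.shape[0])
    stack.coord = coords
    return stack


def _scan_model_atom_counts(path) -> list[int]:
    counts, current, in_model, seen_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model, seen_model, current = True, True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
                if not seen_model:
                    in_model = True
    if not seen_model:
        counts = [current]
    return counts


def read_multi_model_pdb(path, chain_map: dict[str, str] | None = None) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL.  Chain tags map ``f`` to the first chain ID in file
    order and ``h`` to the second unless ``chain_map`` overrides this.  Unknown
    elements produce a warning and the atom is kept, with the heavy flag
    inferred from the atom name.
    """
    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        ref = counts[0]
        for i, c in enumerate(counts[1:], start=2):
            if c != ref:
                raise FormatError(
                    f"MODEL {i} has {c} atoms, expected {ref}: inconsistent models"
                )
    pdb_file = _pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    arr0 = stack[0]
    elements = []
    for name, elem in zip(arr0.atom_name, arr0.element):
        e = str(elem).strip()
        if e == "":
            warnings.warn(f"atom {name!r} has no element; inferring from name")
            e = re.sub(r"[^A-Za-z]", "", str(name))[:1] or "C"
        elements.append(e.capitalize() if len(e) > 1 else e.upper())
    # residue bookkeeping in file order
    res_starts = struc.get_residue_starts(arr0)
    atom_residue = np.searchsorted(res_starts, np.arange(arr0.array_length()),
                                   side="right") - 1
    res_ids = arr0.res_id[res_starts].astype(int)
    res_names = arr0.res_name[res_starts].astype(object)
    chains_in_order = list(dict.fromkeys(arr0.chain_id.tolist()))
    if chain_map is None:
        tags = ["f", "h"]
        chain_map = {c: tags[i] if i < 2 else "h" for i, c in enumerate(chains_in_order)}
    chain_tags = np.array([chain_map[c] for c in arr0.chain_id[res_starts]],
                          dtype=object)
    top = Topology(
        atom_names=arr0.atom_name.astype(object),
        elements=np.array(elements, dtype=object),
        atom_residue=atom_residue,
        res_ids=res_ids,
        res_names=res_names,
        chain_tags=chain_tags,
    )
    return Ensemble(topology=top, coords=np.asarray(stack.coord, dtype=float))


def write_multi_model_pdb(ensemble: Ensemble, path) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL per frame)."""
    stack = to_atom_array(ensemble)
    pdb_file = _pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# binary container: .npz + JSON sidecar

def write_npz(ensemble: Ensemble, path, sidecar: dict | None = None) -> None:
    """Compact array container: ``path`` (.npz) plus ``path + '.json'`` sidecar."""
    path = Path(path)
    np.savez_compressed(path, coords=ensemble.coords)
    top = ensemble.topology
    doc = {
        "atom_names": top.atom_names.tolist(),
        "elements": top.elements.tolist(),
        "atom_residue": top.atom_residue.tolist(),
        "res_ids": top.res_ids.tolist(),
        "res_names": top.res_names.tolist(),
        "chain_tags": top.chain_tags.tolist(),
        "state": ensemble.state,
        "temperature": ensemble.temperature,
        "aligned": ensemble.aligned,
        "metadata": ensemble.metadata,
    }
    if sidecar:
        doc.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(doc, fh, indent=1)


def read_npz(path) -> Ensemble:
    path = Path(path)
    with open(str(path) + ".json") as fh:
        doc = json.load(fh)
    top = Topology(
        atom_names=np.array(doc["atom_names"], dtype=object),
        elements=np.array(doc["elements"], dtype=object),
        atom_residue=np.array(doc["atom_residue"], dtype=int),
        res_ids=np.array(doc["res_ids"], dtype=int),
        res_names=np.array(doc["res_names"], dtype=object),
        chain_tags=np.array(doc["chain_tags"], dtype=object),
    )
    with np.load(path) as data:
        coords = data["coords"]
    return Ensemble(
        topology=top, coords=coords, state=doc.get("state"),
        temperature=doc.get("temperature"), aligned=bool(doc.get("aligned", False)),
        metadata=doc.get("metadata") or {},
    )


# ---------------------------------------------------------------------------
# edge lists

def write_edge_list(network, path, threshold: float = 0.0) -> None:
    """Write a network as a TSV edge list.

    ``network`` must expose ``nodes`` (labels) and ``matrix`` (square weight
    matrix).  Only rows with ``|weight| > threshold`` are emitted, sorted by
    ``|weight|`` descending, ties broken by lexical node order.  Symmetric
    matrices emit each unordered pair once; directional matrices emit ordered
    pairs.
    """
    nodes = list(network.nodes)
    w = np.asarray(network.matrix, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("network contains non-finite weights")
    symmetric = np.allclose(w, w.T, atol=1e-12)
    rows = []
    n = len(nodes)
    for i in range(n):
        js = range(i + 1, n) if symmetric else (j for j in range(n) if j != i)
        for j in js:
            if abs(w[i, j]) > threshold:
                rows.append((nodes[i], nodes[j], w[i, j]))
    rows.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\tsign\n")
        for a, b, x in rows:
            sign = "+" if x > 0 else ("-" if x < 0 else "0")
            fh.write(f"{a}\t{b}\t{x:.6g}\t{sign}\n")
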