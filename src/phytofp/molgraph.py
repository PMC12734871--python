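"""SMILES -> molecular graph conversion and numeric featurization.

Heavy-atom graphs only (hydrogens stay implicit).  Nodes carry atom type,
degree, hybridization, formal charge and aromaticity; edges carry bond type
and conjugation.  Categorical features are one-hot encoded against a
:class:`FeatureVocab` fitted on the training molecules, with unseen values
routed to an ``other`` bucket so inference never fails on exotic atoms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomFeatures",
    "BondFeatures",
    "MoleculeGraph",
    "FeatureVocab",
    "GraphBatch",
    "SmilesError",
    "smiles_to_graph",
    "featurize_batch",
    "read_molecule_csv",
]

HYBRIDIZATIONS = ("sp", "sp2", "sp3", "other")
BOND_TYPES = ("single", "double", "triple", "aromatic")

_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}
_BOND_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


@dataclass(frozen=True)
class AtomFeatures:
    element: str
    degree: int
    hybridization: str
    formal_charge: int
    aromatic: bool


@dataclass(frozen=True)
class BondFeatures:
    bond_type: str
    conjugated: bool


@dataclass
class MoleculeGraph:
    """Undirected heavy-atom graph of one molecule."""

    name: str
    nodes: list[AtomFeatures]
    edges: list[tuple[int, int]]
    edge_features: list[BondFeatures]
    smiles: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        n = self.n_nodes
        deg = [0] * n
        for (i, j), _ in zip(self.edges, self.edge_features):
            if i == j:
                raise ValueError(f"{self.name}: self-loop at atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.name}: edge ({i},{j}) out of range")
            deg[i] += 1
            deg[j] += 1
        for idx, node in enumerate(self.nodes):
            if node.degree != deg[idx]:
                raise ValueError(
                    f"{self.name}: atom {idx} degree field {node.degree} != incident edges {deg[idx]}"
                )


def smiles_to_graph(smiles: str, name: str = "") -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Raises :class:`SmilesError` carrying the offending string on parse or
    sanitization (valence) failure.  Stereochemistry is discarded.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise SmilesError(f"sanitization failed for {smiles!r}: {exc}") from exc
    nodes = [
        AtomFeatures(
            element=atom.GetSymbol(),
            degree=atom.GetDegree(),
            hybridization=_HYB_MAP.get(atom.GetHybridization(), "other"),
            formal_charge=atom.GetFormalCharge(),
            aromatic=atom.GetIsAromatic(),
        )
        for atom in mol.GetAtoms()
    ]
    edges: list[tuple[int, int]] = []
    efeats: list[BondFeatures] = []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeats.append(
            BondFeatures(
                bond_type=_BOND_MAP.get(bond.GetBondType(), "single"),
                conjugated=bond.GetIsConjugated(),
            )
        )
    graph = MoleculeGraph(name=name or smiles, nodes=nodes, edges=edges,
                          edge_features=efeats, smiles=smiles)
    graph.validate()
    return graph


@dataclass
class FeatureVocab:
    """Categorical vocabularies shared between training and inference.

    Elements and formal charges outside the fitted sets map to a trailing
    ``other`` bucket.  Degrees are clipped at ``max_degree``.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    max_degree: int = 5
    charges: tuple[int, ...] = (-1, 0, 1)

    @classmethod
    def fit(cls, graphs: Iterable[MoleculeGraph]) -> "FeatureVocab":
        elements: set[str] = set()
        charges: set[int] = set()
        max_deg = 1
        for g in graphs:
            for node in g.nodes:
                elements.add(node.element)
                charges.add(node.formal_charge)
                max_deg = max(max_deg, node.degree)
        return cls(tuple(sorted(elements)), max_deg, tuple(sorted(charges)))

    @property
    def node_dim(self) -> int:
        # +1: "other" element bucket; +1: "other" charge; +1 aromatic flag
        return (len(self.elements) + 1) + (self.max_degree + 1) + len(HYBRIDIZATIONS) \
            + (len(self.charges) + 1) + 1

    @property
    def edge_dim(self) -> int:
        return len(BOND_TYPES) + 1  # + conjugated flag

    def encode_node(self, node: AtomFeatures, warn_oov: bool = True) -> np.ndarray:
        vec = np.zeros(self.node_dim)
        off = 0
        try:
            vec[off + self.elements.index(node.element)] = 1.0
        except ValueError:
            if warn_oov:
                warnings.warn(
                    f"element {node.element!r} not in vocabulary; using 'other' bucket",
                    stacklevel=3,
                )
            vec[off + len(self.elements)] = 1.0
        off += len(self.elements) + 1
        vec[off + min(node.degree, self.max_degree)] = 1.0
        off += self.max_degree + 1
        vec[off + HYBRIDIZATIONS.index(node.hybridization)] = 1.0
        off += len(HYBRIDIZATIONS)
        try:
            vec[off + self.charges.index(node.formal_charge)] = 1.0
        except ValueError:
            vec[off + len(self.charges)] = 1.0
        off += len(self.charges) + 1
        vec[off] = float(node.aromatic)
        return vec

    def encode_edge(self, bond: BondFeatures) -> np.ndarray:
        vec = np.zeros(self.edge_dim)
        vec[BOND_TYPES.index(bond.bond_type)] = 1.0
        vec[len(BOND_TYPES)] = float(bond.conjugated)
        return vec

    def to_json(self) -> str:
        return json.dumps(
            {"elements": list(self.elements), "max_degree": self.max_degree,
             "charges": list(self.charges)}
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureVocab":
        d = json.loads(text)
        return cls(tuple(d["elements"]), int(d["max_degree"]), tuple(d["charges"]))


@dataclass
class GraphBatch:
    """Disjoint-union encoding of a list of molecular graphs.

    ``node_x``: (N, node_dim) one-hot features; ``edge_index``: (M, 2)
    undirected pairs in batch-global indices; ``edge_x``: (M, edge_dim);
    ``graph_ids``: (N,) graph membership of each node.
    """

    node_x: np.ndarray
    edge_index: np.ndarray
    edge_x: np.ndarray
    graph_ids: np.ndarray
    n_graphs: int

    def __len__(self) -> int:
        return self.n_graphs


def featurize_batch(
    graphs: Sequence[MoleculeGraph], vocab: FeatureVocab, warn_oov: bool = True
) -> GraphBatch:
    """Encode graphs as one numeric disjoint-union batch."""
    if not graphs:
        raise ValueError("cannot featurize an empty graph list")
    node_rows: list[np.ndarray] = []
    edge_rows: list[np.ndarray] = []
    edge_index: list[tuple[int, int]] = []
    gids: list[int] = []
    offset = 0
    for gi, g in enumerate(graphs):
        for node in g.nodes:
            node_rows.append(vocab.encode_node(node, warn_oov=warn_oov))
            gids.append(gi)
        for (i, j), bf in zip(g.edges, g.edge_features):
            edge_index.append((offset + i, offset + j))
            edge_rows.append(vocab.encode_edge(bf))
        offset += g.n_nodes
    edge_x = (np.array(edge_rows) if edge_rows
              else np.zeros((0, vocab.edge_dim)))
    eidx = (np.array(edge_index, dtype=np.int64) if edge_index
            else np.zeros((0, 2), dtype=np.int64))
    return GraphBatch(
        node_x=np.array(node_rows),
        edge_index=eidx,
        edge_x=edge_x,
        graph_ids=np.array(gids, dtype=np.int64),
        n_graphs=len(graphs),
    )


def read_molecule_csv(path: str | Path) -> tuple[list[MoleculeGraph], dict[str, dict[str, str]]]:
    """Read a molecule table: name, SMILES and optional per-level label columns.

    Returns the parsed graphs and, per molecule name, whatever of
    ``pathway``/``superclass``/``class`` columns were present.
    """
    import csv

    graphs: list[MoleculeGraph] = []
    labels: dict[str, dict[str, str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = {f.lower(): f for f in reader.fieldnames or []}
        name_col = fields.get("name")
        smi_col = fields.get("smiles")
        if smi_col is None:
            raise ValueError("molecule file must have a 'smiles' column")
        for row in reader:
            name = row[name_col] if name_col else row[smi_col]
            graphs.append(smiles_to_graph(row[smi_col], name))
            lab = {
                lvl: row[fields[lvl]]
                for lvl in ("pathway", "superclass", "class")
                if lvl in fields and row[fields[lvl]]
            }
            if lab:
                labels[name] = lab
    return graphs, labels
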