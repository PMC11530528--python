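"""Two-scale data model and readers for standard formats.

Entity-level structural graphs (:class:`MolecularGraph`) are built from PDB
chains (residue contact graphs over Cα coordinates), from SMILES strings
(atom/bond graphs via RDKit), or from the bundled JSON graph-interchange
format. Entity-to-entity links live in :class:`InteractionNetwork`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

GRAPH_SCHEMA_VERSION = "muse-graph/1"

OBSERVED = "observed"
UNOBSERVED = "unobserved"
PSEUDO = "pseudo"
_STATUSES = (OBSERVED, UNOBSERVED, PSEUDO)


# ----------------------------------------------------------------------
# Residue features
# ----------------------------------------------------------------------

#: Per-residue physicochemical properties, in this fixed column order:
#:   0 isoelectric point (pI)
#:   1 polarity (Grantham scale)
#:   2 acidity/alkalinity (-1 acidic, 0 neutral, +1 basic at pH 7)
#:   3 hydrogen-bond acceptor count (side chain)
#:   4 hydrogen-bond donor count (side chain)
#:   5 octanol-water partition coefficient (Fauchere-Pliska pi scale)
#:   6 topological polar surface area of the side chain (A^2)
#: Values compiled from standard amino-acid property tables.
RESIDUE_PROPERTY_NAMES = (
    "isoelectric_point",
    "polarity",
    "acidity_alkalinity",
    "h_bond_acceptor",
    "h_bond_donor",
    "octanol_water_logp",
    "topological_polar_surface_area",
)

_RESIDUE_TABLE = {
    "A": (6.00, 8.1, 0, 0, 0, 0.31, 0.0),
    "R": (10.76, 10.5, 1, 3, 4, -1.01, 95.9),
    "N": (5.41, 11.6, 0, 2, 2, -0.60, 63.6),
    "D": (2.77, 13.0, -1, 3, 1, -0.77, 58.6),
    "C": (5.07, 5.5, 0, 0, 1, 1.54, 38.8),
    "Q": (5.65, 10.5, 0, 2, 2, -0.22, 63.6),
    "E": (3.22, 12.3, -1, 3, 1, -0.64, 58.6),
    "G": (5.97, 9.0, 0, 0, 0, 0.00, 0.0),
    "H": (7.59, 10.4, 1, 1, 1, 0.13, 28.7),
    "I": (6.02, 5.2, 0, 0, 0, 1.80, 0.0),
    "L": (5.98, 4.9, 0, 0, 0, 1.70, 0.0),
    "K": (9.74, 11.3, 1, 1, 2, -0.99, 26.0),
    "M": (5.74, 5.7, 0, 1, 0, 1.23, 25.3),
    "F": (5.48, 5.2, 0, 0, 0, 1.79, 0.0),
    "P": (6.30, 8.0, 0, 0, 0, 0.72, 0.0),
    "S": (5.68, 9.2, 0, 1, 1, -0.04, 20.2),
    "T": (5.60, 8.6, 0, 1, 1, 0.26, 20.2),
    "W": (5.89, 5.4, 0, 0, 1, 2.25, 15.8),
    "Y": (5.66, 6.2, 0, 1, 1, 0.96, 20.2),
    "V": (5.96, 5.9, 0, 0, 0, 1.22, 0.0),
}


@dataclass(frozen=True)
class ResidueFeatureTable:
    """Map one-letter residue codes to a 7-vector of properties."""

    table: dict = field(default_factory=lambda: dict(_RESIDUE_TABLE))

    def __post_init__(self):
        for aa in "ARNDCQEGHILKMFPSTWYV":
            if aa not in self.table:
                raise ValueError(f"residue feature table missing {aa!r}")
            if len(self.table[aa]) != 7:
                raise ValueError(f"residue {aa!r} must have 7 properties")

    def __getitem__(self, code: str) -> np.ndarray:
        return np.asarray(self.table[code], dtype=np.float64)

    def __contains__(self, code: str) -> bool:
        return code in self.table


DEFAULT_RESIDUE_TABLE = ResidueFeatureTable()


# ----------------------------------------------------------------------
# Core types
# ----------------------------------------------------------------------

def canonicalize_edges(edges: Sequence[Sequence[int]]) -> np.ndarray:
    """Unordered edge list -> unique (i<j) pairs, sorted lexicographically."""
    if len(edges) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    arr = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    lo = arr.min(axis=1)
    hi = arr.max(axis=1)
    canon = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return canon


@dataclass
class MolecularGraph:
    """One entity's atomic/residue-level structural graph."""

    entity_id: str
    entity_kind: str  # protein | drug | generic
    node_features: np.ndarray  # n x d_n
    edges: np.ndarray  # m x 2, canonical i<j
    edge_features: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0), dtype=np.float64)
    )
    coords: Optional[np.ndarray] = None  # n x 3, Angstrom

    def __post_init__(self):
        if self.entity_kind not in ("protein", "drug", "generic"):
            raise ValueError(f"unknown entity kind: {self.entity_kind!r}")
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.node_features.ndim != 2:
            raise ValueError("node_features must be 2-D (n x d_n)")
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = self.n_nodes
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoint out of range")
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loop edges are not allowed")
        self.edges = canonicalize_edges(self.edges)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 3):
                raise ValueError(
                    f"coords must be {n} x 3, got {self.coords.shape}"
                )

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.float64)
        if self.edges.size:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a


@dataclass
class Link:
    i: int
    j: int
    label: np.ndarray  # [0,1]^C
    status: str = OBSERVED
    confidence: float = 1.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"self-interaction ({self.i}, {self.i}) forbidden")
        if self.i > self.j:
            self.i, self.j = self.j, self.i
        if self.status not in _STATUSES:
            raise ValueError(f"unknown link status {self.status!r}")
        self.label = np.asarray(self.label, dtype=np.float64).ravel()
        if self.status == OBSERVED:
            self.confidence = 1.0

    @property
    def pair(self) -> tuple:
        return (self.i, self.j)


@dataclass
class InteractionNetwork:
    """Entities plus labeled links with observed/unobserved/pseudo provenance."""

    entity_ids: list
    label_space: str  # binary | multilabel
    n_classes: int
    links: list = field(default_factory=list)

    def __post_init__(self):
        if self.label_space not in ("binary", "multilabel"):
            raise ValueError(f"unknown label space {self.label_space!r}")
        seen = set()
        for link in self.links:
            if not (0 <= link.i < len(self.entity_ids)):
                raise ValueError("link endpoint out of range")
            if not (0 <= link.j < len(self.entity_ids)):
                raise ValueError("link endpoint out of range")
            if link.pair in seen:
                raise ValueError(f"duplicate link {link.pair}")
            seen.add(link.pair)
            if link.label.shape != (self.n_classes,):
                raise ValueError("link label has wrong class count")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def links_with_status(self, *statuses: str) -> list:
        return [l for l in self.links if l.status in statuses]

    def adjacency(self, include_pseudo: bool = True) -> np.ndarray:
        """Symmetric 0/1 matrix over observed (and optionally pseudo) links."""
        statuses = (OBSERVED, PSEUDO) if include_pseudo else (OBSERVED,)
        a = np.zeros((self.n_entities, self.n_entities), dtype=np.float64)
        for link in self.links:
            if link.status in statuses:
                a[link.i, link.j] = 1.0
                a[link.j, link.i] = 1.0
        return a

    def link_index(self) -> dict:
        return {l.pair: l for l in self.links}


# ----------------------------------------------------------------------
# Interaction tables
# ----------------------------------------------------------------------

def read_interaction_table(
    path: Union[str, Path],
    label_space: str = "binary",
    classes: Optional[Sequence[str]] = None,
) -> InteractionNetwork:
    """Read a tab-separated ``id_a  id_b  label[,label...]  [status]`` table.

    Entity ids are index-mapped in first-appearance order. Pairs are
    canonicalized; a pair listed twice with identical labels collapses to
    one link, conflicting labels raise.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"columns, got {len(parts)}"
                )
            id_a, id_b, label_field = parts[0], parts[1], parts[2]
            status = parts[3] if len(parts) > 3 else OBSERVED
            if id_a == id_b:
                raise ValueError(
                    f"{path}:{lineno}: self-interaction {id_a!r} forbidden"
                )
            if status not in _STATUSES:
                raise ValueError(f"{path}:{lineno}: unknown status {status!r}")
            rows.append((lineno, id_a, id_b, label_field, status))

    entity_ids: list = []
    index: dict = {}
    for _, id_a, id_b, _, _ in rows:
        for eid in (id_a, id_b):
            if eid not in index:
                index[eid] = len(entity_ids)
                entity_ids.append(eid)

    if label_space == "binary":
        class_list = ["1"]
    elif classes is not None:
        class_list = list(classes)
    else:
        class_list = []
        for _, _, _, label_field, _ in rows:
            for tok in label_field.split(","):
                tok = tok.strip()
                if tok and tok not in class_list:
                    class_list.append(tok)
    class_index = {c: k for k, c in enumerate(class_list)}

    def parse_label(lineno: int, field_: str) -> np.ndarray:
        vec = np.zeros(len(class_list), dtype=np.float64)
        if label_space == "binary":
            tok = field_.strip()
            if tok not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: binary label must be 0 or 1, "
                    f"got {tok!r}"
                )
            vec[0] = float(tok)
            return vec
        for tok in field_.split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok not in class_index:
                raise ValueError(
                    f"{path}:{lineno}: unknown label token {tok!r}"
                )
            vec[class_index[tok]] = 1.0
        return vec

    links: dict = {}
    for lineno, id_a, id_b, label_field, status in rows:
        i, j = sorted((index[id_a], index[id_b]))
        label = parse_label(lineno, label_field)
        if (i, j) in links:
            prev = links[(i, j)]
            if not np.array_equal(prev.label, label) or prev.status != status:
                raise ValueError(
                    f"{path}:{lineno}: pair ({id_a}, {id_b}) listed twice "
                    f"with conflicting labels"
                )
            continue
        links[(i, j)] = Link(i=i, j=j, label=label, status=status)

    return InteractionNetwork(
        entity_ids=entity_ids,
        label_space=label_space,
        n_classes=len(class_list),
        links=list(links.values()),
    )


def write_interaction_table(
    network: InteractionNetwork,
    path: Union[str, Path],
    classes: Optional[Sequence[str]] = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for link in network.links:
            id_a = network.entity_ids[link.i]
            id_b = network.entity_ids[link.j]
            if network.label_space == "binary":
                label = "1" if link.label[0] >= 0.5 else "0"
            else:
                names = classes or [str(k) for k in range(network.n_classes)]
                label = ",".join(
                    names[k] for k in np.flatnonzero(link.label >= 0.5)
                )
            fh.write(f"{id_a}\t{id_b}\t{label}\t{link.status}\n")


# ----------------------------------------------------------------------
# PDB chains and contact graphs
# ----------------------------------------------------------------------

def parse_structure_chain(path: Union[str, Path], chain_id: str):
    """Extract (sequence, Cα coordinates) for one chain of a PDB file.

    Residues lacking a Cα atom are dropped with a warning.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    from biotite.sequence import ProteinSequence

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    chains = sorted(set(atoms.chain_id.tolist()))
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found in {path}; available: {chains}"
        )
    chain = atoms[atoms.chain_id == chain_id]
    chain = chain[struc.filter_amino_acids(chain)]

    seq_chars: list = []
    coords: list = []
    for res in struc.residue_iter(chain):
        ca = res[res.atom_name == "CA"]
        if len(ca) == 0:
            logger.warning(
                "residue %s %d in chain %s has no CA atom; dropped",
                res.res_name[0], int(res.res_id[0]), chain_id,
            )
            continue
        try:
            one = ProteinSequence.convert_letter_3to1(res.res_name[0])
        except KeyError:
            one = "X"
        seq_chars.append(one)
        coords.append(ca.coord[0])
    sequence = "".join(seq_chars)
    coord_arr = (
        np.asarray(coords, dtype=np.float64)
        if coords else np.zeros((0, 3))
    )
    return sequence, coord_arr


def featurize_residues(
    sequence: str,
    table: ResidueFeatureTable = DEFAULT_RESIDUE_TABLE,
) -> np.ndarray:
    """Per-residue 7-property feature matrix (L x 7).

    Non-standard one-letter codes map to a zero row with a warning.
    """
    if len(sequence) == 0:
        raise ValueError("cannot featurize an empty sequence")
    out = np.zeros((len(sequence), 7), dtype=np.float64)
    for i, aa in enumerate(sequence):
        if aa in table:
            out[i] = table[aa]
        else:
            warnings.warn(
                f"non-standard residue code {aa!r} at position {i}; "
                f"using zero features"
            )
    return out


def build_contact_graph(
    sequence: str,
    coords: np.ndarray,
    cutoff: float = 10.0,
    entity_id: str = "",
    table: ResidueFeatureTable = DEFAULT_RESIDUE_TABLE,
) -> MolecularGraph:
    """Residue contact graph: edge (i,j) iff ||Cα_i − Cα_j|| < cutoff (Å)."""
    coords = np.asarray(coords, dtype=np.float64)
    length = len(sequence)
    if length == 0:
        raise ValueError("empty sequence")
    if coords.shape != (length, 3):
        raise ValueError(
            f"coords must be {length} x 3, got {coords.shape}"
        )
    from scipy.spatial.distance import pdist, squareform

    if length > 1:
        dist = squareform(pdist(coords))
        ii, jj = np.where(np.triu(dist < cutoff, k=1))
        edges = np.stack([ii, jj], axis=1)
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
    return MolecularGraph(
        entity_id=entity_id,
        entity_kind="protein",
        node_features=featurize_residues(sequence, table),
        edges=edges,
        coords=coords,
    )


def build_knn_graph(
    coords: np.ndarray, k: int, symmetrize: bool = False
) -> np.ndarray:
    """Directed j→i edges to the k nearest neighbors of each node i.

    Ties are broken by lower node index (stable sort), for platform
    determinism. Returns an array of (source j, target i) rows.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the node count {n}")
    from scipy.spatial.distance import cdist

    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    targets = np.repeat(np.arange(n), k)
    sources = order.ravel()
    edges = np.stack([sources, targets], axis=1).astype(np.int64)
    if symmetrize:
        rev = edges[:, ::-1]
        edges = np.unique(np.concatenate([edges, rev], axis=0), axis=0)
    return edges


# ----------------------------------------------------------------------
# Drug graphs from SMILES
# ----------------------------------------------------------------------

ELEMENT_VOCABULARY = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B")
BOND_ORDER_VOCABULARY = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")


def molecular_graph_from_line_notation(
    smiles: str, entity_id: str = ""
) -> MolecularGraph:
    """Hydrogen-suppressed atom/bond graph from a SMILES string.

    Node features: element one-hot (fixed vocabulary + other slot) ++
    degree ++ formal charge ++ aromaticity flag. Edge features: bond-order
    one-hot.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")

    n_elem = len(ELEMENT_VOCABULARY) + 1  # + "other"
    node_feats = np.zeros((mol.GetNumAtoms(), n_elem + 3), dtype=np.float64)
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        slot = (
            ELEMENT_VOCABULARY.index(sym)
            if sym in ELEMENT_VOCABULARY else n_elem - 1
        )
        node_feats[idx, slot] = 1.0
        node_feats[idx, n_elem] = float(atom.GetDegree())
        node_feats[idx, n_elem + 1] = float(atom.GetFormalCharge())
        node_feats[idx, n_elem + 2] = float(atom.GetIsAromatic())

    edges = []
    edge_feats = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        onehot = np.zeros(len(BOND_ORDER_VOCABULARY), dtype=np.float64)
        name = bond.GetBondType().name
        if name in BOND_ORDER_VOCABULARY:
            onehot[BOND_ORDER_VOCABULARY.index(name)] = 1.0
        edges.append((i, j))
        edge_feats.append(onehot)
    order = np.lexsort(
        (
            [e[1] for e in edges] or [0],
            [e[0] for e in edges] or [0],
        )
    ) if edges else []
    edges_arr = (
        np.asarray(edges, dtype=np.int64)[order]
        if edges else np.zeros((0, 2), dtype=np.int64)
    )
    feats_arr = (
        np.asarray(edge_feats, dtype=np.float64)[order]
        if edge_feats
        else np.zeros((0, len(BOND_ORDER_VOCABULARY)), dtype=np.float64)
    )
    return MolecularGraph(
        entity_id=entity_id,
        entity_kind="drug",
        node_features=node_feats,
        edges=edges_arr,
        edge_features=feats_arr,
    )


# ----------------------------------------------------------------------
# Graph interchange (JSON, versioned)
# ----------------------------------------------------------------------

def write_graph_interchange(
    graph: MolecularGraph, path: Union[str, Path]
) -> None:
    doc = {
        "schema": GRAPH_SCHEMA_VERSION,
        "entity_id": graph.entity_id,
        "entity_kind": graph.entity_kind,
        "node_features": graph.node_features.tolist(),
        "edges": graph.edges.tolist(),
        "edge_features": graph.edge_features.tolist(),
        "coords": None if graph.coords is None else graph.coords.tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_graph_interchange(path: Union[str, Path]) -> MolecularGraph:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != GRAPH_SCHEMA_VERSION:
        raise ValueError(
            f"schema version mismatch: expected {GRAPH_SCHEMA_VERSION}, "
            f"got {doc.get('schema')!r}"
        )
    for key in ("entity_id", "entity_kind", "node_features", "edges"):
        if key not in doc:
            raise ValueError(f"graph interchange file missing {key!r} key")
    edge_features = np.asarray(
        doc.get("edge_features", []), dtype=np.float64
    )
    if edge_features.size == 0:
        edge_features = edge_features.reshape(0, 0)
    coords = doc.get("coords")
    return MolecularGraph(
        entity_id=doc["entity_id"],
        entity_kind=doc["entity_kind"],
        node_features=np.asarray(doc["node_features"], dtype=np.float64),
        edges=np.asarray(doc["edges"], dtype=np.int64).reshape(-1, 2),
        edge_features=edge_features,
        coords=None if coords is None else np.asarray(coords, dtype=np.float64),
    )
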