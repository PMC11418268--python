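"""Drug substructures and their graph encodings.

Two routes produce per-drug substructure sets: BRICS fragmentation of real
molecules (requires the optional chemistry backend) and a synthetic
fragment library of small random graphs.  Either way, each distinct
fragment graph is encoded once with a three-layer graph isomorphism
network and the encodings are collected row-wise into a substructure
table whose rows later act as attention queries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack_rows
from .nn import linear, linear_params


class ChemistryBackendError(RuntimeError):
    """Raised when the chemistry toolkit is unavailable for the SMILES path."""


@dataclass
class MoleculeGraph:
    """A simple undirected graph with per-node feature vectors."""

    node_features: np.ndarray  # (n_nodes, feature_dim)
    edges: list[tuple[int, int]]

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.node_features.ndim != 2:
            raise ValueError("node_features must be 2-D")
        n = self.n_nodes
        seen = set()
        for u, v in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) references invalid node")
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            a[u, v] = 1.0
            a[v, u] = 1.0
        return a

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        adj = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes


@dataclass
class FragmentLibrary:
    """Distinct fragment graphs plus the drug -> fragment-id mapping."""

    fragments: dict[int, MoleculeGraph]
    drug_fragments: dict[str, list[int]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for drug, ids in self.drug_fragments.items():
            for fid in ids:
                if fid not in self.fragments:
                    raise ValueError(f"drug {drug!r} references unknown fragment {fid}")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def feature_dim(self) -> int:
        return next(iter(self.fragments.values())).feature_dim

    def fragment_ids(self) -> list[int]:
        return sorted(self.fragments)

    def to_json(self, path) -> None:
        obj = {
            "schema_version": 1,
            "metadata": self.metadata,
            "fragments": {
                str(fid): {
                    "node_features": g.node_features.tolist(),
                    "edges": [list(e) for e in g.edges],
                }
                for fid, g in sorted(self.fragments.items())
            },
            "drug_fragments": {
                d: sorted(ids) for d, ids in sorted(self.drug_fragments.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=None)

    @classmethod
    def from_json(cls, path) -> "FragmentLibrary":
        with open(path) as fh:
            obj = json.load(fh)
        fragments = {
            int(fid): MoleculeGraph(
                np.asarray(g["node_features"]),
                [tuple(e) for e in g["edges"]],
            )
            for fid, g in obj["fragments"].items()
        }
        return cls(fragments, {d: list(ids) for d, ids in obj["drug_fragments"].items()},
                   metadata=obj.get("metadata", {}))


# ---------------------------------------------------------------------------
# BRICS route (real molecules)


def brics_decompose(smiles: str) -> list[str]:
    """Canonical BRICS fragments of a molecule, deduplicated and sorted.

    A molecule with no BRICS-cleavable bond decomposes to itself.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import BRICS
    except ImportError:
        raise ChemistryBackendError(
            "chemistry toolkit (rdkit) not installed; use the synthetic "
            "fragment library instead"
        ) from None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    frags = set(BRICS.BRICSDecompose(mol))
    if not frags:
        frags = {Chem.MolToSmiles(mol)}
    return sorted(frags)


def mol_to_graph(smiles: str, element_vocab: list[str]) -> MoleculeGraph:
    """Atom-type one-hot (over ``element_vocab``) plus degree, bonds as edges.

    Unknown elements map to a shared out-of-vocabulary slot.
    """
    try:
        from rdkit import Chem
    except ImportError:
        raise ChemistryBackendError("chemistry toolkit (rdkit) not installed") from None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    elem_idx = {e: i for i, e in enumerate(element_vocab)}
    fdim = len(element_vocab) + 2  # one-hot + OOV slot + degree
    feats = np.zeros((mol.GetNumAtoms(), fdim))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        feats[i, elem_idx.get(atom.GetSymbol(), len(element_vocab))] = 1.0
        feats[i, -1] = atom.GetDegree()
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    return MoleculeGraph(feats, edges)


def library_from_smiles(med_to_smiles: dict[str, str]) -> FragmentLibrary:
    """Build a fragment library by BRICS-decomposing each drug's molecule.

    Fragments are deduplicated across drugs by canonical fragment string.
    """
    frag_smiles: dict[str, int] = {}
    drug_fragments: dict[str, list[int]] = {}
    for med, smi in sorted(med_to_smiles.items()):
        ids = []
        for frag in brics_decompose(smi):
            if frag not in frag_smiles:
                frag_smiles[frag] = len(frag_smiles)
            ids.append(frag_smiles[frag])
        drug_fragments[med] = sorted(set(ids))
    # derive the element vocabulary from the atoms of all fragments
    try:
        from rdkit import Chem
    except ImportError:
        raise ChemistryBackendError("chemistry toolkit (rdkit) not installed") from None
    symbols: set[str] = set()
    for frag in frag_smiles:
        mol = Chem.MolFromSmiles(frag)
        if mol is not None:
            symbols.update(a.GetSymbol() for a in mol.GetAtoms())
    elements = sorted(symbols)
    fragments = {
        fid: mol_to_graph(frag, elements)
        for frag, fid in frag_smiles.items()
    }
    return FragmentLibrary(
        fragments, drug_fragments, metadata={"elements": elements, "source": "smiles"}
    )


# ---------------------------------------------------------------------------
# GIN encoder


def gin_params(rng: np.random.Generator, feature_dim: int, dim: int,
               n_layers: int = 3, prefix: str = "gin") -> dict:
    """Per-layer two-linear MLP weights plus a learnable epsilon scalar."""
    p = {}
    d_in = feature_dim
    for k in range(1, n_layers + 1):
        p.update(linear_params(rng, d_in, dim, f"{prefix}.l{k}.m1"))
        p.update(linear_params(rng, dim, dim, f"{prefix}.l{k}.m2"))
        p[f"{prefix}.l{k}.eps"] = Tensor(np.zeros(()), requires_grad=True)
        d_in = dim
    return p


def gin_aggregate(graph: MoleculeGraph, features: Tensor, eps: Tensor) -> Tensor:
    """Neighborhood aggregation ``(1 + eps) * b_v + sum_{u in N(v)} b_u``."""
    if features.shape[0] != graph.n_nodes:
        raise ValueError(
            f"feature rows {features.shape[0]} != nodes {graph.n_nodes}"
        )
    adj = Tensor(graph.adjacency())
    return (1.0 + eps) * features + adj @ features


def gin_layer(graph: MoleculeGraph, features: Tensor, params: dict,
              prefix: str) -> Tensor:
    """One propagation step: aggregate then apply the layer MLP."""
    agg = gin_aggregate(graph, features, params[f"{prefix}.eps"])
    return linear(linear(agg, params, f"{prefix}.m1").relu(), params, f"{prefix}.m2")


def encode_substructure(graph: MoleculeGraph, params: dict, n_layers: int = 3,
                        prefix: str = "gin") -> Tensor:
    """Three propagation steps followed by global mean pooling over atoms."""
    if graph.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    h = Tensor(graph.node_features)
    for k in range(1, n_layers + 1):
        h = gin_layer(graph, h, params, f"{prefix}.l{k}")
    return h.mean(axis=0)


@dataclass
class SubstructureTable:
    """Row-per-fragment encoding matrix with a fragment-id -> row map."""

    matrix: Tensor
    row_index: dict[int, int]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def build_substructure_table(library: FragmentLibrary, params: dict,
                             n_layers: int = 3, prefix: str = "gin") -> SubstructureTable:
    """Encode every distinct fragment once; rows ordered by fragment id."""
    if library.n_fragments == 0:
        raise ValueError("fragment library is empty")
    ids = library.fragment_ids()
    rows = [
        encode_substructure(library.fragments[fid], params, n_layers, prefix)
        for fid in ids
    ]
    return SubstructureTable(stack_rows(rows), {fid: i for i, fid in enumerate(ids)})
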