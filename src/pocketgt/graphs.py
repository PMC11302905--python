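"""Pocket residue graphs and their node/edge input features.

A pocket graph has one node per pocket residue (every residue whose Calpha
lies within 10 A of any pocket vertex), carrying the amino-acid token, the
per-residue SASA and the Calpha coordinates.  Undirected edges connect all
Calpha pairs within 25 A.  Input features are a 21-way one-hot amino-acid
block, a radial-basis embedding of SASA (centers equally spaced on
[0, 350] A^2) and a radial-basis embedding of edge distances (centers on
[3, 25] A).  Only pairwise distances and per-residue scalars enter, so every
feature is invariant under rigid motions of the coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyPocketError, VocabularyError
from .pockets import PocketCandidate
from .structures import ProteinStructure, SasaTable

#: the 20 standard amino acids; index 20 is the unknown token
AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
UNKNOWN_TOKEN = 20
N_AA_TOKENS = 21
_AA_INDEX = {name: i for i, name in enumerate(AA3)}

DEFAULT_SELECT_RADIUS = 10.0
DEFAULT_EDGE_CUTOFF = 25.0


def aa_token(residue_name: str) -> int:
    """Map a 3-letter residue name to its token; non-standard names map to 20."""
    return _AA_INDEX.get(residue_name.upper(), UNKNOWN_TOKEN)


def rbf_centers(lo: float, hi: float, n: int) -> np.ndarray:
    """``n`` equally spaced RBF centers, first at ``lo``, last at ``hi``."""
    if n < 2:
        raise ValueError("need at least 2 RBF centers")
    return np.linspace(lo, hi, n)


def rbf_embed(x, centers: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian radial-basis expansion ``exp(-gamma (x - mu_k)^2)``.

    ``x`` may be a scalar (returns ``[n]``) or a 1-D array (returns
    ``[len(x), n]``).  Components are in (0, 1] and hit 1 exactly when
    ``x`` equals a center; no normalization is applied.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    diff = x[..., None] - centers
    return np.exp(-gamma * diff**2)


@dataclass(frozen=True)
class FeatureConfig:
    """Input feature hyperparameters.

    The RBF dimensionalities equal the model hidden width ``d``.  Widths
    default to ``gamma = 1 / (2 delta^2)`` with ``delta`` the center
    spacing, giving smoothly overlapping basis functions.
    """

    hidden_dim: int = 128
    sasa_range: tuple[float, float] = (0.0, 350.0)
    dist_range: tuple[float, float] = (3.0, 25.0)
    gamma_sasa: float | None = None
    gamma_dist: float | None = None
    use_sasa: bool = True

    def _resolve_gamma(self, given: float | None, rng: tuple[float, float]) -> float:
        if given is not None:
            if given <= 0:
                raise ValueError("gamma must be positive")
            return given
        delta = (rng[1] - rng[0]) / (self.hidden_dim - 1)
        return 1.0 / (2.0 * delta**2)

    @property
    def sasa_centers(self) -> np.ndarray:
        return rbf_centers(*self.sasa_range, self.hidden_dim)

    @property
    def dist_centers(self) -> np.ndarray:
        return rbf_centers(*self.dist_range, self.hidden_dim)

    @property
    def sasa_gamma(self) -> float:
        return self._resolve_gamma(self.gamma_sasa, self.sasa_range)

    @property
    def dist_gamma(self) -> float:
        return self._resolve_gamma(self.gamma_dist, self.dist_range)

    @property
    def node_input_dim(self) -> int:
        return N_AA_TOKENS + (self.hidden_dim if self.use_sasa else 0)


@dataclass(frozen=True)
class PocketGraph:
    """Per-pocket residue graph.

    ``edges`` holds directed index pairs; the set is symmetric (both
    orientations present) with no self-loops, and every pair was within the
    edge cutoff at construction time.
    """

    node_aa: np.ndarray          # [N] int tokens in [0, 20]
    node_sasa: np.ndarray        # [N] float, A^2
    node_coords: np.ndarray      # [N, 3] float, A
    edges: np.ndarray            # [E, 2] int, directed, symmetric closure
    node_residue_keys: tuple     # ((chain_id, residue_index), ...)
    pocket_id: str = ""
    protein_id: str = ""
    label: bool | None = None
    dca: float | None = None
    barycenter: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "node_aa", np.asarray(self.node_aa, dtype=int))
        object.__setattr__(self, "node_sasa", np.asarray(self.node_sasa, dtype=float))
        object.__setattr__(self, "node_coords", np.asarray(self.node_coords, dtype=float))
        object.__setattr__(
            self, "edges", np.asarray(self.edges, dtype=int).reshape(-1, 2)
        )
        if self.node_aa.shape[0] == 0:
            raise EmptyPocketError("a pocket graph needs at least one node")
        if self.node_aa.min(initial=0) < 0 or self.node_aa.max(initial=0) > UNKNOWN_TOKEN:
            raise VocabularyError("amino-acid tokens must lie in [0, 20]")
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return int(self.node_aa.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def edge_distances(self) -> np.ndarray:
        """Euclidean distance per directed edge, ``[E]``."""
        if self.edges.shape[0] == 0:
            return np.empty(0)
        diff = self.node_coords[self.edges[:, 0]] - self.node_coords[self.edges[:, 1]]
        return np.linalg.norm(diff, axis=1)


def select_pocket_residues(
    s: ProteinStructure, p: PocketCandidate, radius: float = DEFAULT_SELECT_RADIUS
) -> list[tuple[str, str]]:
    """Residue keys whose Calpha lies within ``radius`` of ANY pocket vertex.

    Boundary inclusive; returned in structure order without duplicates.
    Raises :class:`EmptyPocketError` when no residue qualifies.
    """
    residues = s.residues
    if not residues:
        raise EmptyPocketError("structure has no Calpha-bearing residues")
    ca = s.ca_coords()
    tree = cKDTree(p.vertices)
    dmin, _ = tree.query(ca)
    keys = [
        (res.chain_id, res.residue_index)
        for res, d in zip(residues, dmin)
        if d <= radius
    ]
    if not keys:
        raise EmptyPocketError(
            f"candidate {p.pocket_id} selects no residues within {radius} A"
        )
    return keys


def build_edges(coords: np.ndarray, cutoff: float = DEFAULT_EDGE_CUTOFF) -> np.ndarray:
    """Directed symmetric edge list for all pairs within ``cutoff`` (inclusive)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return np.empty((0, 2), dtype=int)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if pairs.shape[0] == 0:
        return np.empty((0, 2), dtype=int)
    both = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
    order = np.lexsort((both[:, 1], both[:, 0]))
    return both[order]


def build_graph(
    s: ProteinStructure,
    residue_keys: list[tuple[str, str]],
    sasa: SasaTable,
    cutoff: float = DEFAULT_EDGE_CUTOFF,
    pocket_id: str = "",
    protein_id: str = "",
    label: bool | None = None,
    dca: float | None = None,
    barycenter: np.ndarray | None = None,
) -> PocketGraph:
    """Assemble a :class:`PocketGraph` for the given residue keys.

    Missing SASA entries fall back to 0 A^2 with a warning (non-standard
    residues may be absent from the table).
    """
    if not residue_keys:
        raise EmptyPocketError("residue_keys must be non-empty")
    by_key = {(r.chain_id, r.residue_index): r for r in s.residues}
    tokens, sasa_vals, coords = [], [], []
    for key in residue_keys:
        res = by_key[key]
        tokens.append(aa_token(res.residue_name))
        if key in sasa:
            sasa_vals.append(sasa[key])
        else:
            warnings.warn(f"no SASA entry for residue {key}; using 0")
            sasa_vals.append(0.0)
        coords.append(s.array.coord[res.ca_index])
    coords = np.asarray(coords, dtype=float)
    return PocketGraph(
        node_aa=np.asarray(tokens),
        node_sasa=np.asarray(sasa_vals),
        node_coords=coords,
        edges=build_edges(coords, cutoff),
        node_residue_keys=tuple(residue_keys),
        pocket_id=pocket_id,
        protein_id=protein_id,
        label=label,
        dca=dca,
        barycenter=None if barycenter is None else np.asarray(barycenter, float),
    )


def node_features(g: PocketGraph, cfg: FeatureConfig) -> np.ndarray:
    """Raw node input blocks: one-hot(21) [+ SASA RBF block when enabled].

    The learned amino-acid embedding and, with SASA, the input projection
    live in the model; this emits the blocks they consume.
    """
    onehot = np.zeros((g.n_nodes, N_AA_TOKENS))
    onehot[np.arange(g.n_nodes), g.node_aa] = 1.0
    if not cfg.use_sasa:
        return onehot
    sasa_block = rbf_embed(g.node_sasa, cfg.sasa_centers, cfg.sasa_gamma)
    return np.concatenate([onehot, sasa_block], axis=1)


def edge_features(g: PocketGraph, cfg: FeatureConfig) -> np.ndarray:
    """Distance RBF vector per directed edge, ``[E, d]``."""
    return rbf_embed(g.edge_distances(), cfg.dist_centers, cfg.dist_gamma)


# -- serialization -------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_graphs(graphs: list[PocketGraph], path) -> Path:
    """Write graphs as a compressed ``.npz`` plus a ``.json`` metadata sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    node_offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    edge_offsets = np.cumsum([0] + [g.n_edges for g in graphs])
    arrays = {
        "node_aa": np.concatenate([g.node_aa for g in graphs]) if graphs else np.empty(0, int),
        "node_sasa": np.concatenate([g.node_sasa for g in graphs]) if graphs else np.empty(0),
        "node_coords": np.concatenate([g.node_coords for g in graphs]) if graphs else np.empty((0, 3)),
        "edges": np.concatenate([g.edges for g in graphs]) if graphs else np.empty((0, 2), int),
        "node_offsets": node_offsets,
        "edge_offsets": edge_offsets,
    }
    np.savez_compressed(path, **arrays)
    meta = {
        "format_version": _ARCHIVE_VERSION,
        "graphs": [
            {
                "pocket_id": g.pocket_id,
                "protein_id": g.protein_id,
                "label": g.label,
                "dca": g.dca,
                "barycenter": None if g.barycenter is None else list(map(float, g.barycenter)),
                "residue_keys": [list(k) for k in g.node_residue_keys],
            }
            for g in graphs
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def load_graphs(path) -> list[PocketGraph]:
    """Read a graph archive written by :func:`save_graphs`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    graphs = []
    no, eo = data["node_offsets"], data["edge_offsets"]
    for i, m in enumerate(meta["graphs"]):
        graphs.append(
            PocketGraph(
                node_aa=data["node_aa"][no[i]:no[i + 1]],
                node_sasa=data["node_sasa"][no[i]:no[i + 1]],
                node_coords=data["node_coords"][no[i]:no[i + 1]],
                edges=data["edges"][eo[i]:eo[i + 1]],
                node_residue_keys=tuple(tuple(k) for k in m["residue_keys"]),
                pocket_id=m["pocket_id"],
                protein_id=m["protein_id"],
                label=m["label"],
                dca=m["dca"],
                barycenter=None if m["barycenter"] is None else np.asarray(m["barycenter"]),
            )
        )
    return graphs
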