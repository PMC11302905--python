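"""Pocket-candidate ingestion, barycenters and DCA-based truth labels.

A candidate is a cloud of alpha-sphere centers ("vertices") from a geometric
pocket detector.  Candidates come from an Fpocket output directory
(``pockets/pocket<N>_vert.pqr``), a vertex CSV, or a built-in grid-based
cavity detector used when no external detector output is available.

Labels follow the DCA criterion: a candidate is a true pocket iff the
minimum distance between its vertex barycenter and any bound ligand atom is
strictly less than 4 A.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, FormatError
from .structures import ProteinStructure

#: DCA threshold (A) below which a candidate is a true pocket
DCA_THRESHOLD = 4.0


@dataclass(frozen=True)
class PocketCandidate:
    """A pocket candidate: alpha-sphere vertices plus optional label data."""

    pocket_id: str
    vertices: np.ndarray  # [V, 3]
    dca: float | None = None
    label: bool | None = None
    protein_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValueError("vertices must be a non-empty [V, 3] array")
        object.__setattr__(self, "vertices", v)
        if self.label is not None:
            if self.dca is None:
                raise ValueError("a labeled candidate must carry its DCA value")
            if self.label != (self.dca < DCA_THRESHOLD):
                raise ValueError("label inconsistent with DCA threshold")

    @property
    def barycenter(self) -> np.ndarray:
        """Arithmetic mean of the vertex coordinates."""
        return self.vertices.mean(axis=0)


# -- Fpocket / PQR ingestion ------------------------------------------------

_VERT_RE = re.compile(r"pocket(\d+)_vert\.pqr$")


def _parse_pqr_vertices(path: Path) -> np.ndarray:
    """Extract x,y,z from ATOM/HETATM records of a PQR file.

    Tolerates both whitespace-delimited PQR (fields ``... x y z charge
    radius``) and fixed-column PDB-like layouts; only coordinates are used.
    """
    coords = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        try:
            xyz = [float(parts[-5]), float(parts[-4]), float(parts[-3])]
        except (ValueError, IndexError):
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise FormatError(f"unparseable vertex record in {path}: {line!r}") from exc
        coords.append(xyz)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def read_fpocket_output(directory, protein_id: str | None = None) -> list[PocketCandidate]:
    """Read candidates from an Fpocket output directory.

    ``directory`` must contain a ``pockets/`` subdirectory with files named
    ``pocket<N>_vert.pqr``; candidates are returned in ascending N
    (Fpocket's rank order).  Vertex files without coordinate records are
    skipped with a warning.
    """
    directory = Path(directory)
    pocket_dir = directory / "pockets"
    if not pocket_dir.is_dir():
        raise FormatError(f"{directory} has no 'pockets/' subdirectory")
    entries = []
    for path in pocket_dir.iterdir():
        m = _VERT_RE.search(path.name)
        if m:
            entries.append((int(m.group(1)), path))
    entries.sort()
    candidates = []
    for _, path in entries:
        vertices = _parse_pqr_vertices(path)
        if vertices.shape[0] == 0:
            warnings.warn(f"skipping vertex file without coordinates: {path}")
            continue
        candidates.append(
            PocketCandidate(pocket_id=path.name[: -len("_vert.pqr")], vertices=vertices,
                            protein_id=protein_id)
        )
    return candidates


def write_fpocket_output(candidates: list[PocketCandidate], directory) -> Path:
    """Write candidates in the Fpocket output dialect (``pockets/pocket<N>_vert.pqr``)."""
    directory = Path(directory)
    pocket_dir = directory / "pockets"
    pocket_dir.mkdir(parents=True, exist_ok=True)
    for n, cand in enumerate(candidates, start=1):
        lines = []
        for i, (x, y, z) in enumerate(cand.vertices, start=1):
            lines.append(
                f"ATOM  {i:>5} APOL STP {n:>5}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f} 0.0000 1.0000"
            )
        (pocket_dir / f"pocket{n}_vert.pqr").write_text("\n".join(lines) + "\n")
    return directory


def read_vertex_csv(path, protein_id: str | None = None) -> list[PocketCandidate]:
    """Read candidates from a CSV with header ``pocket_id,x,y,z``."""
    df = pd.read_csv(path)
    required = {"pocket_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} must have columns {sorted(required)}")
    candidates = []
    for pid in df["pocket_id"].drop_duplicates():
        sub = df[df["pocket_id"] == pid]
        candidates.append(
            PocketCandidate(
                pocket_id=str(pid),
                vertices=sub[["x", "y", "z"]].to_numpy(float),
                protein_id=protein_id,
            )
        )
    return candidates


def write_vertex_csv(candidates: list[PocketCandidate], path) -> None:
    rows = [
        {"pocket_id": c.pocket_id, "x": x, "y": y, "z": z}
        for c in candidates
        for x, y, z in c.vertices
    ]
    pd.DataFrame(rows, columns=["pocket_id", "x", "y", "z"]).to_csv(path, index=False)


# -- built-in cavity detector -------------------------------------------------

def fallback_detect(
    s: ProteinStructure,
    grid_spacing: float = 1.0,
    min_cluster: int = 5,
    clearance: float = 3.0,
    burial_radius: float = 6.0,
    burial_count: int = 12,
) -> list[PocketCandidate]:
    """Grid-based cavity detector for use when no Fpocket output exists.

    Grid points inside the structure's bounding box qualify as cavity points
    when they are at least ``clearance`` A away from every heavy atom and
    have at least ``burial_count`` heavy atoms within ``burial_radius`` A.
    Qualifying points are single-linkage clustered at twice the grid
    spacing; clusters of at least ``min_cluster`` points become candidates,
    largest first.  This flags concave interior voids; it is not a
    re-implementation of an alpha-sphere detector.
    """
    coords = s.coords
    if coords.shape[0] == 0:
        raise EmptyStructureError("cannot detect pockets on an empty structure")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    axes = [np.arange(lo[k], hi[k] + 1e-9, grid_spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(coords)
    dmin, _ = tree.query(grid)
    n_near = tree.query_ball_point(grid, burial_radius, return_length=True)
    keep = (dmin >= clearance) & (n_near >= burial_count)
    pts = grid[keep]
    if pts.shape[0] == 0:
        return []
    ptree = cKDTree(pts)
    pairs = ptree.query_pairs(2.0 * grid_spacing + 1e-9, output_type="ndarray")
    n = pts.shape[0]
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)
    clusters = [pts[comp == c] for c in range(n_comp)]
    clusters = [c for c in clusters if c.shape[0] >= min_cluster]
    clusters.sort(key=lambda c: -c.shape[0])
    return [
        PocketCandidate(pocket_id=f"pocket{i + 1}", vertices=c)
        for i, c in enumerate(clusters)
    ]


# -- DCA and labels -----------------------------------------------------------

def _stack_ligand_atoms(ligand_atoms) -> np.ndarray:
    if isinstance(ligand_atoms, np.ndarray):
        arrs = [ligand_atoms]
    else:
        arrs = [np.asarray(a, dtype=float) for a in ligand_atoms]
        if arrs and arrs[0].ndim == 1:  # a single list of 3-vectors
            arrs = [np.stack(arrs)]
    if not arrs or sum(a.shape[0] for a in arrs) == 0:
        raise ValueError("ligand atom set must be non-empty")
    return np.concatenate([a.reshape(-1, 3) for a in arrs], axis=0)


def compute_dca(p: PocketCandidate, ligand_atoms) -> float:
    """Distance from the candidate barycenter to the closest ligand atom.

    ``ligand_atoms`` may be a single ``[M, 3]`` array or a list of arrays
    (one per ligand group); the minimum is taken over all of them.
    """
    atoms = _stack_ligand_atoms(ligand_atoms)
    return float(np.linalg.norm(atoms - p.barycenter, axis=1).min())


def assign_label(p: PocketCandidate, ligand_atoms) -> PocketCandidate:
    """Return a copy of ``p`` with DCA and label set (true iff DCA < 4 A)."""
    dca = compute_dca(p, ligand_atoms)
    return replace(p, dca=dca, label=bool(dca < DCA_THRESHOLD))
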