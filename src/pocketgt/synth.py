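"""Synthetic protein/pocket fixtures with planted labels and a learnable signal.

The generator emulates the structure of a labeled candidate dataset: toy
protein chains (self-avoiding Calpha walks with pseudo side chains), pocket
candidates planted on the surface, ligands placed so the DCA labeling rule
reproduces the intended label exactly, and a class imbalance matching
real candidate sets (default 7% positives).  The learnable signal is the
amino-acid composition of the pocket-lining residues: positive pockets are
lined with a "binding" palette with probability ``signal_strength`` per
residue, negatives and the background with residues drawn from the full
standard palette.  Geometry is protein-like in scale only; folds, rotamers
and ligand chemistry are deliberately fake.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc

from .errors import GenerationError
from .graphs import AA3, PocketGraph, build_graph, select_pocket_residues
from .pockets import (
    PocketCandidate,
    assign_label,
    write_fpocket_output,
    write_vertex_csv,
)
from .structures import ProteinStructure, compute_sasa, strip_for_detection, write_structure

#: residues enriched in planted positive pocket linings
BINDING_PALETTE = ("HIS", "ASP", "GLU", "CYS", "TRP")
#: the full background palette (all 20 standard residues)
BACKGROUND_PALETTE = AA3

_CA_STEP = 3.8     # consecutive Calpha distance, A
_CA_CLEARANCE = 3.5  # minimum non-bonded Calpha separation, A
_SIDECHAIN_NAMES = ("CB", "CG", "CD", "CE")
_SIDECHAIN_ELEMENTS = ("C", "N", "O")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic dataset.

    Defaults emulate the imbalance of real candidate sets (~7% positives)
    with a strong composition signal; 30 proteins x 20 pockets gives ~600
    candidates with pocket linings of realistic size (15-30 residues).
    Candidate lists mirror a geometric detector run on ligand-bound
    structures: every protein carries at least one true site among its
    candidates whenever ``pockets_per_protein * positive_fraction >= 1``,
    with the remaining positives drawn so the overall prevalence stays at
    ``positive_fraction``.
    """

    n_proteins: int = 30
    residues_per_protein: int = 90
    pockets_per_protein: int = 20
    positive_fraction: float = 0.07
    signal_strength: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.residues_per_protein < 20:
            raise ValueError("residues_per_protein must be >= 20")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _walk_ca(n: int, rng: np.random.Generator) -> np.ndarray:
    """Confined self-avoiding walk: 3.8 A steps, >= 3.5 A pairwise clearance.

    Steps are rejected outside a sphere of radius ~3.3 n^(1/3) A so the
    chain collapses into a globule of roughly protein-like density; pockets
    planted on its surface then line 15-30 residues as real pockets do.
    """
    radius = max(9.0, 3.3 * n ** (1.0 / 3.0))
    for _ in range(30):  # whole-chain restarts
        pts = [np.zeros(3)]
        direction = _random_unit(rng)
        ok = True
        for _ in range(n - 1):
            for _attempt in range(300):
                proposal = direction * 0.5 + _random_unit(rng)
                proposal /= np.linalg.norm(proposal)
                nxt = pts[-1] + _CA_STEP * proposal
                if np.linalg.norm(nxt) > radius:
                    direction = _random_unit(rng)
                    continue
                prior = np.asarray(pts[:-1])
                if prior.size == 0 or np.linalg.norm(prior - nxt, axis=1).min() >= _CA_CLEARANCE:
                    pts.append(nxt)
                    direction = proposal
                    break
            else:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise GenerationError(f"could not place a self-avoiding {n}-residue chain")


def _assemble(chains: list[dict]) -> ProteinStructure:
    n = sum(len(c["coords"]) for c in chains)
    arr = struc.AtomArray(n)
    arr.coord = np.concatenate([c["coords"] for c in chains]).astype(np.float32)
    pos = 0
    for c in chains:
        m = len(c["coords"])
        sl = slice(pos, pos + m)
        arr.chain_id[sl] = c["chain_id"]
        arr.res_id[sl] = c["res_id"]
        arr.res_name[sl] = c["res_name"]
        arr.atom_name[sl] = c["atom_name"]
        arr.element[sl] = c["element"]
        arr.hetero[sl] = c["hetero"]
        pos += m
    arr.set_annotation("ins_code", np.full(n, "", dtype="U1"))
    return ProteinStructure(arr)


def make_chain(n_residues: int, rng: np.random.Generator) -> ProteinStructure:
    """A toy protein chain: Calpha walk decorated with 1-4 pseudo side-chain atoms."""
    if n_residues < 2:
        raise ValueError("a chain needs at least 2 residues")
    ca = _walk_ca(n_residues, rng)
    coords, res_id, res_name, atom_name, element = [], [], [], [], []
    names = [BACKGROUND_PALETTE[i] for i in rng.integers(0, len(BACKGROUND_PALETTE), n_residues)]
    for i in range(n_residues):
        coords.append(ca[i])
        res_id.append(i + 1)
        res_name.append(names[i])
        atom_name.append("CA")
        element.append("C")
        for k in range(int(rng.integers(1, 5))):
            coords.append(ca[i] + _random_unit(rng) * rng.uniform(1.2, 2.4))
            res_id.append(i + 1)
            res_name.append(names[i])
            atom_name.append(_SIDECHAIN_NAMES[k])
            element.append(_SIDECHAIN_ELEMENTS[int(rng.integers(0, 3))])
    return _assemble(
        [
            dict(
                coords=np.asarray(coords),
                chain_id="A",
                res_id=np.asarray(res_id),
                res_name=np.asarray(res_name, dtype="U5"),
                atom_name=np.asarray(atom_name, dtype="U6"),
                element=np.asarray(element, dtype="U2"),
                hetero=np.zeros(len(coords), dtype=bool),
            )
        ]
    )


def _append_ligand(s: ProteinStructure, atoms: np.ndarray, ligand_number: int) -> ProteinStructure:
    m = atoms.shape[0]
    lig = struc.AtomArray(m)
    lig.coord = atoms.astype(np.float32)
    lig.chain_id[:] = "L"
    lig.res_id[:] = ligand_number
    lig.res_name[:] = "LIG"
    lig.atom_name[:] = [f"C{i + 1}" for i in range(m)]
    lig.element[:] = "C"
    lig.hetero[:] = True
    lig.set_annotation("ins_code", np.full(m, "", dtype="U1"))
    return ProteinStructure(s.array + lig)


def _surface_locus(s: ProteinStructure, rng: np.random.Generator) -> np.ndarray:
    ca = s.ca_coords()
    center = ca.mean(axis=0)
    anchor = ca[int(rng.integers(0, ca.shape[0]))]
    outward = anchor - center
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else _random_unit(rng)
    return anchor + 4.5 * outward


def _repalette(s: ProteinStructure, vertices: np.ndarray,
               signal_strength: float, rng: np.random.Generator) -> None:
    """Redraw the lining of a positive pocket toward the binding palette, in place."""
    from scipy.spatial import cKDTree

    residues = s.residues
    ca = s.ca_coords()
    dmin, _ = cKDTree(vertices).query(ca)
    for res, d in zip(residues, dmin):
        if d > 10.0:
            continue
        if rng.random() < signal_strength:
            name = BINDING_PALETTE[int(rng.integers(0, len(BINDING_PALETTE)))]
        else:
            name = BACKGROUND_PALETTE[int(rng.integers(0, len(BACKGROUND_PALETTE)))]
        mask = (s.array.chain_id == res.chain_id) & (
            s.array.res_id == int(res.residue_index)
        ) & (~s.array.hetero)
        s.array.res_name[mask] = name


def plant_pocket(
    s: ProteinStructure,
    positive: bool,
    spec: FixtureSpec,
    rng: np.random.Generator,
    pocket_id: str = "pocket1",
    negative_barycenters: list[np.ndarray] | None = None,
    avoid_loci: list[np.ndarray] | None = None,
    avoid_radius: float = 25.0,
) -> tuple[ProteinStructure, PocketCandidate, np.ndarray | None]:
    """Plant one candidate; returns the (possibly extended) structure, the
    candidate, and the ligand atom array for positive plants.

    Positive: a 5-15 atom ligand is placed with the closest atom at a
    uniform 0.5-3.5 A from the vertex barycenter (DCA < 4 guaranteed), and
    the lining is re-paletted toward the binding palette.  Negative: the
    locus is retried until the barycenter stays > 4.5 A from every ligand
    atom already present.  ``negative_barycenters`` lets the caller protect
    earlier negative plants from a new positive's ligand; ``avoid_loci``
    keeps negative loci away from positive pockets so their linings stay
    distinct surface sites.
    """
    protected = negative_barycenters or []
    keep_clear = avoid_loci or []
    for attempt in range(400):
        locus = _surface_locus(s, rng)
        if not positive and keep_clear:
            # relax the separation gradually if geometry is too cramped
            radius = avoid_radius if attempt < 300 else avoid_radius * 0.6
            if min(np.linalg.norm(locus - a) for a in keep_clear) < radius:
                continue
        n_v = int(rng.integers(5, 21))
        radii = 3.0 * rng.random(n_v) ** (1.0 / 3.0)
        vertices = locus + radii[:, None] * np.stack([_random_unit(rng) for _ in range(n_v)])
        barycenter = vertices.mean(axis=0)
        existing = s.ligand_coords()
        if positive:
            dca = rng.uniform(0.5, 3.5)
            direction = _random_unit(rng)
            n_atoms = int(rng.integers(5, 16))
            atoms = [barycenter + dca * direction]
            for _ in range(n_atoms - 1):
                atoms.append(barycenter + (dca + rng.uniform(0.0, 2.0)) * _random_unit(rng))
            atoms = np.asarray(atoms)
            # a new ligand must not turn an earlier negative into a positive
            if any(
                np.linalg.norm(atoms - nb, axis=1).min() <= 4.5 for nb in protected
            ):
                continue
            s = _append_ligand(s, atoms, ligand_number=len(s.ligands) + 1)
            _repalette(s, vertices, spec.signal_strength, rng)
            cand = PocketCandidate(pocket_id=pocket_id, vertices=vertices)
            return s, cand, atoms
        else:
            if existing and min(
                np.linalg.norm(lc - barycenter, axis=1).min() for lc in existing
            ) <= 4.5:
                continue
            # negative linings keep the background palette from chain generation
            cand = PocketCandidate(pocket_id=pocket_id, vertices=vertices)
            return s, cand, None
    raise GenerationError(f"could not satisfy the distance constraints for {pocket_id}")


def _orphan_ligand(s: ProteinStructure, barycenters: list[np.ndarray],
                   rng: np.random.Generator) -> ProteinStructure:
    """Add a ligand far (> 4.5 A) from every candidate barycenter.

    Keeps the labeling precondition (every structure carries a bound
    ligand) on proteins where no positive pocket was drawn.
    """
    for _ in range(200):
        locus = _surface_locus(s, rng) + 8.0 * _random_unit(rng)
        n_atoms = int(rng.integers(5, 16))
        atoms = locus + rng.uniform(0.0, 2.0, (n_atoms, 1)) * np.stack(
            [_random_unit(rng) for _ in range(n_atoms)]
        )
        if all(np.linalg.norm(atoms - b, axis=1).min() > 4.5 for b in barycenters):
            return _append_ligand(s, atoms, ligand_number=len(s.ligands) + 1)
    raise GenerationError("could not place an orphan ligand")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus the lookup tables evaluation needs."""

    spec: FixtureSpec
    structures: dict[str, ProteinStructure]
    candidates: dict[str, list[PocketCandidate]]
    graphs: list[PocketGraph]
    barycenters: dict[tuple[str, str], np.ndarray]
    protein_ligands: dict[str, list[np.ndarray]]
    labels: dict[tuple[str, str], bool]
    root: Path | None = None


def make_dataset(
    spec: FixtureSpec,
    out_dir=None,
    build_graphs: bool = True,
) -> SyntheticDataset:
    """Generate the dataset; optionally write every input dialect to ``out_dir``.

    Written layout per protein: ``<pid>.pdb``, ``<pid>_out/pockets/
    pocket<N>_vert.pqr``, ``<pid>_vertices.csv``; plus ``labels.csv`` and a
    graph archive ``graphs.npz``/``graphs.json`` for the whole dataset.
    ``build_graphs=False`` skips SASA and graph construction (labels only).
    """
    rng = np.random.default_rng(spec.rng_seed)
    structures: dict[str, ProteinStructure] = {}
    candidates: dict[str, list[PocketCandidate]] = {}
    graphs: list[PocketGraph] = []
    barycenters: dict[tuple[str, str], np.ndarray] = {}
    protein_ligands: dict[str, list[np.ndarray]] = {}
    labels: dict[tuple[str, str], bool] = {}

    k, f = spec.pockets_per_protein, spec.positive_fraction
    for p in range(spec.n_proteins):
        pid = f"prot{p:04d}"
        s = make_chain(spec.residues_per_protein, rng)
        if k * f >= 1.0:
            # one guaranteed true site per protein (detector-on-bound-
            # structure regime); extras drawn to keep overall prevalence f
            n_pos = 1 + rng.binomial(k - 1, (k * f - 1.0) / (k - 1))
            wanted = np.zeros(k, dtype=bool)
            wanted[rng.choice(k, size=min(n_pos, k), replace=False)] = True
        else:
            wanted = rng.random(k) < f
        # positives first so negative plants can avoid all ligands
        order = np.argsort(~wanted, kind="stable")
        cands: list[PocketCandidate | None] = [None] * spec.pockets_per_protein
        negative_bcs: list[np.ndarray] = []
        positive_loci: list[np.ndarray] = []
        for slot in order:
            pid_pocket = f"pocket{slot + 1}"
            s, cand, _ = plant_pocket(
                s, bool(wanted[slot]), spec, rng,
                pocket_id=pid_pocket, negative_barycenters=negative_bcs,
                avoid_loci=positive_loci,
            )
            if wanted[slot]:
                positive_loci.append(cand.barycenter)
            else:
                negative_bcs.append(cand.barycenter)
            cands[slot] = cand
        if not s.ligands:
            s = _orphan_ligand(s, [c.barycenter for c in cands], rng)
        ligand_coords = s.ligand_coords()
        labeled = [assign_label(c, ligand_coords) for c in cands]
        structures[pid] = s
        candidates[pid] = labeled
        protein_ligands[pid] = ligand_coords
        for c in labeled:
            barycenters[(pid, c.pocket_id)] = c.barycenter
            labels[(pid, c.pocket_id)] = bool(c.label)
        if build_graphs:
            polymer = strip_for_detection(s)
            sasa = compute_sasa(polymer)
            for c in labeled:
                keys = select_pocket_residues(polymer, c)
                graphs.append(
                    build_graph(
                        polymer, keys, sasa,
                        pocket_id=c.pocket_id, protein_id=pid,
                        label=c.label, dca=c.dca, barycenter=c.barycenter,
                    )
                )

    root = None
    if out_dir is not None:
        root = Path(out_dir)
        root.mkdir(parents=True, exist_ok=True)
        rows = ["protein_id,pocket_id,label,dca"]
        for pid, cands in candidates.items():
            write_structure(structures[pid], root / f"{pid}.pdb")
            write_fpocket_output(cands, root / f"{pid}_out")
            write_vertex_csv(cands, root / f"{pid}_vertices.csv")
            for c in cands:
                rows.append(f"{pid},{c.pocket_id},{int(c.label)},{c.dca:.4f}")
        (root / "labels.csv").write_text("\n".join(rows) + "\n")
        if build_graphs:
            from .graphs import save_graphs

            save_graphs(graphs, root / "graphs.npz")

    return SyntheticDataset(
        spec=spec,
        structures=structures,
        candidates=candidates,
        graphs=graphs,
        barycenters=barycenters,
        protein_ligands=protein_ligands,
        labels=labels,
        root=root,
    )
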