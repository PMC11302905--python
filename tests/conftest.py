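import numpy as np
import pytest

import pocketgt as pg


def pdb_line(record, serial, name, res_name, chain, res_id, x, y, z,
             occupancy=1.0, b=0.0, element=None, altloc=" ", icode=" "):
    """Format one fixed-column PDB record."""
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{res_name:<3} {chain}"
        f"{res_id:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{b:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small in-memory synthetic dataset shared across tests."""
    spec = pg.FixtureSpec(
        n_proteins=6,
        residues_per_protein=40,
        pockets_per_protein=4,
        positive_fraction=0.3,
        signal_strength=0.9,
        rng_seed=1,
    )
    return pg.make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_graphs(tiny_dataset):
    return tiny_dataset.graphs


@pytest.fixture
def three_residue_pdb(tmp_path):
    """A 3-residue chain with one ligand group and two waters."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        pdb_line("ATOM", 3, "C", "ALA", "A", 1, 2.2, 1.2, 0.0),
        pdb_line("ATOM", 4, "N", "GLY", "A", 2, 3.5, 1.2, 0.0, element="N"),
        pdb_line("ATOM", 5, "CA", "GLY", "A", 2, 4.6, 2.1, 0.0),
        pdb_line("ATOM", 6, "C", "GLY", "A", 2, 5.9, 1.4, 0.0),
        pdb_line("ATOM", 7, "N", "SER", "A", 3, 7.0, 2.2, 0.0, element="N"),
        pdb_line("ATOM", 8, "CA", "SER", "A", 3, 8.2, 1.4, 0.0),
        pdb_line("ATOM", 9, "OG", "SER", "A", 3, 9.0, 2.5, 0.5, element="O"),
        pdb_line("HETATM", 10, "C1", "LIG", "B", 1, 4.0, 5.0, 1.0),
        pdb_line("HETATM", 11, "C2", "LIG", "B", 1, 4.8, 5.6, 1.2),
        pdb_line("HETATM", 12, "O", "HOH", "W", 1, 10.0, 10.0, 10.0, element="O"),
        pdb_line("HETATM", 13, "O", "HOH", "W", 2, 11.0, 11.0, 11.0, element="O"),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_rigid_transform(rng, reflect=False):
    """A random rotation (optionally improper) plus translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    if reflect:
        R = R @ np.diag([1.0, 1.0, -1.0])
    t = rng.uniform(-50, 50, 3)
    return R, t


def make_random_graph(rng, n_nodes=8, box=20.0, with_label=None):
    """A random but valid pocket graph for model-level tests."""
    coords = rng.uniform(0, box, (n_nodes, 3))
    return pg.PocketGraph(
        node_aa=rng.integers(0, 21, n_nodes),
        node_sasa=rng.uniform(0, 300, n_nodes),
        node_coords=coords,
        edges=pg.build_edges(coords),
        node_residue_keys=tuple(("A", str(i + 1)) for i in range(n_nodes)),
        pocket_id="p1",
        protein_id="prot",
        label=with_label,
    )
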