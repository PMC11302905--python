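"""Protein structure I/O, polymer/ligand partitioning and per-residue SASA.

Structures are held as :class:`biotite.structure.AtomArray` objects wrapped in
a thin :class:`ProteinStructure` container that exposes the residue list
(Calpha-bearing polymer residues), ligand groups (named hetero residues,
water excluded) and convenience coordinate views.  Solvent-accessible surface
area is computed with the Shrake-Rupley rolling-probe method (probe radius
1.4 A) on heavy polymer atoms only and aggregated per residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyStructureError, FormatError, PocketGTError

#: hetero residue names treated as water and never reported as ligands
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "DIS", "SOL"})

#: elements excluded from the SASA calculation
_HYDROGENS = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``residue_index`` is the author residue number with any insertion code
    appended (e.g. ``"42"`` or ``"42A"``); ``record_kind`` is ``"hetero"``
    for HETATM-derived atoms and ``"polymer"`` otherwise.
    """

    element: str
    name: str
    coords: np.ndarray
    residue_index: str
    residue_name: str
    chain_id: str
    record_kind: str


@dataclass(frozen=True)
class ResidueRef:
    """A polymer residue with exactly one Calpha atom."""

    chain_id: str
    residue_index: str
    residue_name: str
    ca_index: int  # row into the atom array


class SasaTable:
    """Map ``(chain_id, residue_index) -> per-residue SASA`` in A^2."""

    def __init__(self, values: dict[tuple[str, str], float]):
        for key, v in values.items():
            if v < 0:
                raise ValueError(f"negative SASA for residue {key}: {v}")
        self._values = dict(values)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self._values[key]

    def __contains__(self, key) -> bool:
        return key in self._values

    def __len__(self) -> int:
        return len(self._values)

    def get(self, key, default: float = 0.0) -> float:
        return self._values.get(key, default)

    def items(self):
        return self._values.items()

    def values(self):
        return self._values.values()


def _residue_key(res_id: int, ins_code: str) -> str:
    return f"{res_id}{ins_code.strip()}"


class ProteinStructure:
    """A protein structure partitioned into polymer and ligand content.

    Parameters
    ----------
    atom_array:
        Biotite atom array; the ``hetero`` annotation drives the
        polymer/hetero partition.
    """

    def __init__(self, atom_array: struc.AtomArray):
        if not np.all(np.isfinite(atom_array.coord)):
            raise ValueError("atom coordinates must be finite")
        if "ins_code" not in atom_array.get_annotation_categories():
            atom_array.set_annotation(
                "ins_code", np.full(atom_array.array_length(), "", dtype="U1")
            )
        self.array = atom_array

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.array.coord

    @property
    def atoms(self) -> list[Atom]:
        arr = self.array
        return [
            Atom(
                element=str(arr.element[i]),
                name=str(arr.atom_name[i]),
                coords=arr.coord[i].copy(),
                residue_index=_residue_key(int(arr.res_id[i]), str(arr.ins_code[i])),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                record_kind="hetero" if arr.hetero[i] else "polymer",
            )
            for i in range(arr.array_length())
        ]

    @property
    def residues(self) -> list[ResidueRef]:
        """Polymer residues with exactly one Calpha, in file order.

        Residues lacking a Calpha atom are excluded (their atoms remain in
        :attr:`array`); duplicate Calpha records keep the first occurrence.
        """
        arr = self.array
        out: list[ResidueRef] = []
        seen: set[tuple[str, str]] = set()
        ca_mask = (~arr.hetero) & (arr.atom_name == "CA") & (arr.element != "CA")
        for i in np.flatnonzero(ca_mask):
            key = (str(arr.chain_id[i]), _residue_key(int(arr.res_id[i]), str(arr.ins_code[i])))
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ResidueRef(
                    chain_id=key[0],
                    residue_index=key[1],
                    residue_name=str(arr.res_name[i]),
                    ca_index=int(i),
                )
            )
        return out

    @property
    def ligands(self) -> list[tuple[str, np.ndarray]]:
        """Hetero residue groups as ``(name, atom-row indices)``, water excluded."""
        arr = self.array
        groups: dict[tuple[str, str, str], list[int]] = {}
        for i in np.flatnonzero(arr.hetero):
            res_name = str(arr.res_name[i])
            if res_name in WATER_NAMES:
                continue
            key = (str(arr.chain_id[i]), _residue_key(int(arr.res_id[i]), str(arr.ins_code[i])), res_name)
            groups.setdefault(key, []).append(int(i))
        return [(key[2], np.asarray(idx, dtype=int)) for key, idx in groups.items()]

    def ligand_coords(self) -> list[np.ndarray]:
        """Coordinates of each ligand group, one ``[M, 3]`` array per group."""
        return [self.array.coord[idx] for _, idx in self.ligands]

    def ca_coords(self) -> np.ndarray:
        """Calpha coordinates for :attr:`residues` as an ``[N, 3]`` array."""
        idx = [r.ca_index for r in self.residues]
        return self.array.coord[idx] if idx else np.empty((0, 3))

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(self.array.copy())


def read_structure(path, model_index: int = 1) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first in file).  ``model_index`` is 1-based; the default
    is the first model.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=model_index,
            altloc="occupancy",
            extra_fields=["b_factor", "occupancy"],
        )
    except FileNotFoundError:
        raise
    except PocketGTError:
        raise
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if not np.any(~arr.hetero):
        raise EmptyStructureError(f"{path} contains no ATOM records")
    return ProteinStructure(arr)


def strip_for_detection(s: ProteinStructure) -> ProteinStructure:
    """Return a polymer-only copy (waters, ligands and all HETATM removed)."""
    return ProteinStructure(s.array[~s.array.hetero].copy())


def compute_sasa(s: ProteinStructure, point_number: int = 1000) -> SasaTable:
    """Per-residue solvent-accessible surface area (Shrake-Rupley).

    Probe radius 1.4 A, ``point_number`` sphere points per atom (>= 100;
    the default keeps per-residue discretization error within a few
    percent), heavy polymer atoms only; ligands and water are removed
    before the calculation so they do not occlude the protein surface.
    """
    if point_number < 100:
        raise ValueError("point_number must be >= 100")
    arr = s.array
    mask = (~arr.hetero) & ~np.isin(arr.element, list(_HYDROGENS))
    if not np.any(mask):
        raise EmptyStructureError("structure has no heavy polymer atoms")
    poly = arr[mask]
    atom_sasa = struc.sasa(
        poly,
        probe_radius=1.4,
        point_number=point_number,
        vdw_radii="Single",
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    table: dict[tuple[str, str], float] = {}
    for i in range(poly.array_length()):
        key = (str(poly.chain_id[i]), _residue_key(int(poly.res_id[i]), str(poly.ins_code[i])))
        table[key] = table.get(key, 0.0) + float(atom_sasa[i])
    return SasaTable(table)


def write_structure(s: ProteinStructure, path, per_atom_scalar: dict[int, float] | None = None) -> None:
    """Write ``s`` as PDB text, optionally encoding a scalar in the B-factor.

    ``per_atom_scalar`` maps atom-row indices to values; atoms not covered
    get 0.  Values are clipped to the PDB B-factor field range [0, 999.99].
    """
    arr = s.array.copy()
    b = np.zeros(arr.array_length())
    if per_atom_scalar is not None:
        for i, v in per_atom_scalar.items():
            b[int(i)] = v
    b = np.clip(b, 0.0, 999.99)
    arr.set_annotation("b_factor", b)
    if "occupancy" not in arr.get_annotation_categories():
        arr.set_annotation("occupancy", np.ones(arr.array_length()))
    pdb = PDBFile()
    pdb.set_structure(arr)
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc
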