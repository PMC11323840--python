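"""PDB structure input, atom selections and volumetric/tabular output.

Reading goes through gemmi; the in-memory representation is a flat list of
:class:`Atom` records (laboratory-frame coordinates straight from the file,
orthogonal angstrom, asymmetric unit only).  Alternate locations are resolved
on read: per atom site the conformer with the highest occupancy wins, ties
broken by altloc 'A' then alphabetically.

Volumetric maps (:class:`~halomif.grids.BoxGridValues`) can be written as
Gaussian cube, OpenDX or long-format CSV, each with a matching reader so maps
round-trip losslessly to ~1e-7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .grids import BoxGridValues

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "write_pdb",
    "select_backbone_carbonyls",
    "select_ligand_atoms",
    "select_halogen_atoms",
    "protein_heavy_atom_coords",
    "write_volumetric",
    "read_volumetric",
]

logger = logging.getLogger(__name__)

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

HALOGEN_ELEMENTS = {"F", "CL", "BR", "I"}


@dataclass(frozen=True)
class Atom:
    """One atom record (PDB fields, coordinates in angstrom)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetatm: bool = False
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Structure:
    """Ordered atom list for one model of a PDB entry."""

    atoms: list[Atom] = field(default_factory=list)
    model_id: int = 1
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hetatm and a.residue_name in STANDARD_AMINO_ACIDS]

    def hetero_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hetatm]


class EmptyStructureError(ValueError):
    """No atoms survived parsing/filtering."""


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom site: highest occupancy, ties -> 'A',
    then alphabetical altloc."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.insertion_code,
               atom.residue_name, atom.name)
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            order.append(key)
            continue
        # higher occupancy wins; ties prefer 'A', then alphabetical
        cand_rank = (-atom.occupancy, atom.altloc != "A", atom.altloc)
        prev_rank = (-prev.occupancy, prev.altloc != "A", prev.altloc)
        if cand_rank < prev_rank:
            best[key] = atom
    return [best[k] for k in order]


def read_pdb(path, model_select: int = 1, altloc_policy: str = "occupancy") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : str or Path
    model_select : int
        1-based model number (multi-model entries keep only this model).
    altloc_policy : {"occupancy", "all"}
        "occupancy" (default) resolves alternate locations as documented in
        the module docstring; "all" keeps every conformer.

    Raises
    ------
    ValueError
        Unreadable/garbled file, unknown model, or no atoms after filtering.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    model = None
    for i, m in enumerate(st, start=1):
        num = getattr(m, "num", None)
        if num == model_select or (num is None and i == model_select) or i == model_select:
            model = m
            break
    if model is None:
        raise ValueError(f"model {model_select} not present in {path}")

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for at in residue:
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        is_hetatm=het,
                        insertion_code=residue.seqid.icode.strip(),
                    )
                )
    if altloc_policy == "occupancy":
        atoms = _resolve_altlocs(atoms)
    elif altloc_policy != "all":
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    if not atoms:
        raise EmptyStructureError(f"no atoms parsed from {path}")
    return Structure(atoms=atoms, model_id=model_select, name=path.stem)


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure back to PDB fixed-column format (via gemmi)."""
    # group into chain -> residue -> atoms first; gemmi containers copy on
    # add, so the tree is assembled bottom-up
    chain_order: list[str] = []
    res_order: dict[str, list[tuple]] = {}
    res_atoms: dict[tuple, list[Atom]] = {}
    for atom in structure.atoms:
        if atom.chain_id not in res_order:
            chain_order.append(atom.chain_id)
            res_order[atom.chain_id] = []
        rkey = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name)
        if rkey not in res_atoms:
            res_order[atom.chain_id].append(rkey)
            res_atoms[rkey] = []
        res_atoms[rkey].append(atom)

    st = gemmi.Structure()
    st.name = structure.name or "halomif"
    model = gemmi.Model(structure.model_id)
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        for rkey in res_order[chain_id]:
            res = gemmi.Residue()
            res.name = rkey[3]
            res.seqid = gemmi.SeqId(rkey[1], rkey[2] or " ")
            res.het_flag = "H" if res_atoms[rkey][0].is_hetatm else "A"
            for atom in res_atoms[rkey]:
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.position)
                a.occ = atom.occupancy
                a.altloc = atom.altloc or "\x00"
                res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def select_backbone_carbonyls(structure: Structure) -> list[tuple[str, dict[str, Atom]]]:
    """Complete backbone N/CA/C/O quadruples of standard amino acids.

    Returns ``(residue_id, {"N": .., "CA": .., "C": .., "O": ..})`` in file
    order, where ``residue_id`` is ``"<chain>:<resname><number>"``.  Residues
    missing any of the four atoms are skipped with a log message.
    """
    grouped: dict[tuple, dict[str, Atom]] = {}
    order: list[tuple] = []
    names: dict[tuple, str] = {}
    for atom in structure.atoms:
        if atom.is_hetatm or atom.residue_name not in STANDARD_AMINO_ACIDS:
            continue
        key = (atom.chain_id, atom.residue_number, atom.insertion_code)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
            names[key] = atom.residue_name
        if atom.name in ("N", "CA", "C", "O"):
            grouped[key].setdefault(atom.name, atom)

    out = []
    for key in order:
        atoms = grouped[key]
        rid = f"{key[0]}:{names[key]}{key[1]}{key[2]}"
        if all(n in atoms for n in ("N", "CA", "C", "O")):
            out.append((rid, atoms))
        else:
            missing = [n for n in ("N", "CA", "C", "O") if n not in atoms]
            logger.warning("skipping residue %s: missing backbone atoms %s", rid, missing)
    return out


def select_ligand_atoms(structure: Structure, ligand_code: str) -> list[Atom]:
    """HETATM atoms of one ligand by 3-letter code (e.g. ZES, TBS, T44, TCL)."""
    return [a for a in structure.hetero_atoms() if a.residue_name == ligand_code.upper()]


def select_halogen_atoms(atoms: list[Atom], elements=("CL", "BR", "I")) -> list[Atom]:
    """Halogen atoms (by element symbol) from a selection."""
    wanted = {e.upper() for e in elements}
    return [a for a in atoms if a.element.upper() in wanted]


def protein_heavy_atom_coords(structure: Structure) -> np.ndarray:
    """Coordinates of non-hydrogen protein atoms, shape (N, 3)."""
    coords = [a.xyz for a in structure.protein_atoms() if a.element.upper() != "H"]
    if not coords:
        return np.zeros((0, 3))
    return np.stack(coords)


# ---------------------------------------------------------------------------
# volumetric output

def write_volumetric(grid_map: BoxGridValues, path, format: str = "dx") -> None:
    """Write a box grid of strengths as Gaussian cube, OpenDX or CSV.

    ``cube`` follows the Gaussian convention (lengths in bohr, one dummy
    atom); ``dx`` is OpenDX general array format; ``csv`` is long format
    with one ``x,y,z,value`` row per voxel.  All three round-trip through
    :func:`read_volumetric`.
    """
    path = Path(path)
    if format == "cube":
        _write_cube(grid_map, path)
    elif format == "dx":
        _write_dx(grid_map, path)
    elif format == "csv":
        _write_csv(grid_map, path)
    else:
        raise ValueError(f"unsupported volumetric format: {format!r}")


def read_volumetric(path, format: str | None = None) -> BoxGridValues:
    """Read a map written by :func:`write_volumetric` (format from suffix
    unless given)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "cube":
        return _read_cube(path)
    if format == "dx":
        return _read_dx(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unsupported volumetric format: {format!r}")


def _write_cube(m: BoxGridValues, path: Path) -> None:
    b = BOHR_PER_ANGSTROM
    nx, ny, nz = m.dims
    with open(path, "w") as fh:
        fh.write("halomif interaction-field map\n")
        fh.write("strengths in [0,1]; lengths in bohr\n")
        fh.write(f"{1:5d}{m.origin[0]*b:14.8f}{m.origin[1]*b:14.8f}{m.origin[2]*b:14.8f}\n")
        fh.write(f"{nx:5d}{m.spacing*b:14.8f}{0.0:14.8f}{0.0:14.8f}\n")
        fh.write(f"{ny:5d}{0.0:14.8f}{m.spacing*b:14.8f}{0.0:14.8f}\n")
        fh.write(f"{nz:5d}{0.0:14.8f}{0.0:14.8f}{m.spacing*b:14.8f}\n")
        # one dummy atom at the origin (cube requires >= 1 atom record)
        fh.write(f"{1:5d}{0.0:14.8f}{m.origin[0]*b:14.8f}{m.origin[1]*b:14.8f}{m.origin[2]*b:14.8f}\n")
        flat = m.values.reshape(-1)  # z fastest, cube order == C order
        for start in range(0, flat.size, 6):
            fh.write("".join(f"{v:16.8E}" for v in flat[start:start + 6]) + "\n")


def _read_cube(path: Path) -> BoxGridValues:
    with open(path) as fh:
        lines = fh.read().split("\n")
    natoms_line = lines[2].split()
    natoms = int(natoms_line[0])
    origin = np.array([float(x) for x in natoms_line[1:4]]) / BOHR_PER_ANGSTROM
    dims = []
    spacing = None
    for i in range(3):
        parts = lines[3 + i].split()
        dims.append(int(parts[0]))
        step = float(parts[1 + i]) / BOHR_PER_ANGSTROM
        if spacing is None:
            spacing = step
    values = []
    for line in lines[6 + natoms:]:
        values.extend(float(x) for x in line.split())
    arr = np.array(values).reshape(tuple(dims))
    return BoxGridValues(origin=origin, spacing=float(spacing), dims=tuple(dims), values=arr)


def _write_dx(m: BoxGridValues, path: Path) -> None:
    nx, ny, nz = m.dims
    with open(path, "w") as fh:
        fh.write("# halomif interaction-field map (strengths in [0,1], angstrom)\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {m.origin[0]:.9g} {m.origin[1]:.9g} {m.origin[2]:.9g}\n")
        fh.write(f"delta {m.spacing:.9g} 0 0\n")
        fh.write(f"delta 0 {m.spacing:.9g} 0\n")
        fh.write(f"delta 0 0 {m.spacing:.9g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n")
        flat = m.values.reshape(-1)
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.9g}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def _read_dx(path: Path) -> BoxGridValues:
    dims = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        in_data = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1"):
                dims = tuple(int(x) for x in line.split()[-3:])
            elif line.startswith("origin"):
                origin = np.array([float(x) for x in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append([float(x) for x in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
                in_data = True
            elif in_data:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                    continue
                values.extend(float(x) for x in line.split())
    if dims is None or origin is None or not deltas or n_items is None:
        raise ValueError(f"malformed DX file: {path}")
    spacing = float(deltas[0][0])
    arr = np.array(values[:n_items]).reshape(dims)
    return BoxGridValues(origin=origin, spacing=spacing, dims=dims, values=arr)


def _write_csv(m: BoxGridValues, path: Path) -> None:
    coords = m.point_coordinates()
    flat = m.values.reshape(-1)
    with open(path, "w") as fh:
        fh.write("x,y,z,value\n")
        for (x, y, z), v in zip(coords, flat):
            fh.write(f"{x:.9g},{y:.9g},{z:.9g},{v:.9g}\n")


def _read_csv(path: Path) -> BoxGridValues:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    coords, vals = data[:, :3], data[:, 3]
    origin = coords.min(axis=0)
    dims = []
    for axis in range(3):
        dims.append(len(np.unique(np.round(coords[:, axis], 6))))
    dims = tuple(dims)
    spans = coords.max(axis=0) - origin
    steps = [spans[i] / (dims[i] - 1) for i in range(3) if dims[i] > 1]
    spacing = float(steps[0]) if steps else 1.0
    arr = vals.reshape(dims)
    return BoxGridValues(origin=origin, spacing=spacing, dims=dims, values=arr)
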