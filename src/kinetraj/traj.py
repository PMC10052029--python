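"""Topologies, trajectories, atom selections, and plain-text trajectory IO.

The in-memory model is deliberately small: a :class:`Topology` names atoms and
groups them into residues, a :class:`Trajectory` holds per-frame Cartesian
coordinates in Å, and a :class:`Selection` is an ordered list of atom indices
produced by a tiny selection-expression grammar.  Atom indexing is 0-based
internally; residue ids keep their (typically 1-based) PDB numbering and are
the only identifiers surfaced in reports.

Trajectories are exchanged as multi-model PDB files (MODEL/ENDMDL blocks) or
as plain TSV coordinate tables — both plain text, both lossless to the 3
decimals PDB fixed-width records carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_coordinate_table",
    "write_coordinate_table",
    "select",
]

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


class PDBParseError(ValueError):
    """Raised when a multi-model PDB file violates the expected dialect."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str
    is_ligand: bool = False
    insertion_code: str = ""

    @property
    def res_label(self) -> str:
        """Residue id with any insertion code appended, as shown in reports."""
        return f"{self.res_id}{self.insertion_code}"


class Topology:
    """Ordered atom list with a residue index table.

    Invariants checked at construction: every atom belongs to exactly one
    residue, residue ids are non-decreasing within a chain, and every protein
    residue carries at least one alpha carbon.
    """

    def __init__(self, atoms: list[Atom]):
        self.atoms = list(atoms)
        self._build_residue_table()
        self._validate()

    def _build_residue_table(self) -> None:
        self.residues: list[dict] = []
        current_key = None
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.res_id, atom.insertion_code, atom.is_ligand)
            if key != current_key:
                self.residues.append(
                    {
                        "chain_id": atom.chain_id,
                        "res_id": atom.res_id,
                        "insertion_code": atom.insertion_code,
                        "res_name": atom.res_name,
                        "is_ligand": atom.is_ligand,
                        "atom_indices": [],
                    }
                )
                current_key = key
            self.residues[-1]["atom_indices"].append(i)

    def _validate(self) -> None:
        last_by_chain: dict[str, int] = {}
        for res in self.residues:
            chain = res["chain_id"]
            if chain in last_by_chain and res["res_id"] < last_by_chain[chain]:
                raise ValueError(
                    f"residue ids not ordered within chain {chain!r}: "
                    f"{res['res_id']} after {last_by_chain[chain]}"
                )
            last_by_chain[chain] = res["res_id"]
            if not res["is_ligand"]:
                names = {self.atoms[i].name for i in res["atom_indices"]}
                if "CA" not in names:
                    raise ValueError(
                        f"protein residue {res['res_name']}{res['res_id']} "
                        "has no alpha carbon"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_ids(self, protein_only: bool = True) -> list[int]:
        return [
            r["res_id"]
            for r in self.residues
            if not (protein_only and r["is_ligand"])
        ]

    def alpha_carbon_indices(self) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.name == "CA" and not a.is_ligand
        ]

    def residue_of_atom(self, atom_index: int) -> int:
        """Residue id of the atom at ``atom_index``."""
        return self.atoms[atom_index].res_id


class Trajectory:
    """Per-frame Cartesian coordinates (frames × atoms × 3, Å) over a topology."""

    def __init__(
        self,
        coordinates: np.ndarray,
        topology: Topology,
        frame_interval: float | None = None,
    ):
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, atoms, 3); got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        self.coordinates = coords
        self.topology = topology
        self.frame_interval = frame_interval

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coordinates[frame]


@dataclass(frozen=True)
class Selection:
    """Ordered, unique, in-bounds atom indices plus the expression that made them."""

    indices: tuple[int, ...]
    expression: str = ""

    def __post_init__(self):
        idx = self.indices
        if any(i < 0 for i in idx):
            raise ValueError("selection indices must be non-negative")
        if list(idx) != sorted(set(idx)):
            raise ValueError("selection indices must be unique and ascending")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def union(self, other: "Selection") -> "Selection":
        merged = sorted(set(self.indices) | set(other.indices))
        return Selection(tuple(merged), f"({self.expression}) or ({other.expression})")


# --------------------------------------------------------------------------
# selection grammar
#
#   expression := term ("or" term)*
#   term       := factor ("and" factor)*
#   factor     := "not" factor | "(" expression ")" | primitive
#   primitive  := all | protein | ligand | backbone | heavy | calpha
#               | name <NAME> | chain <ID> | resid <range>[,<range>...]
#   range      := N | N-M
# --------------------------------------------------------------------------


def _primitive_mask(topology: Topology, tokens: list[str], pos: int, expression: str):
    n = topology.n_atoms
    tok = tokens[pos].lower()
    atoms = topology.atoms
    if tok == "all":
        return np.ones(n, bool), pos + 1
    if tok == "protein":
        return np.array([not a.is_ligand for a in atoms]), pos + 1
    if tok == "ligand":
        return np.array([a.is_ligand for a in atoms]), pos + 1
    if tok in ("calpha", "ca"):
        return np.array([a.name == "CA" and not a.is_ligand for a in atoms]), pos + 1
    if tok == "backbone":
        return (
            np.array([a.name in _BACKBONE_NAMES and not a.is_ligand for a in atoms]),
            pos + 1,
        )
    if tok == "heavy":
        return np.array([a.element.upper() != "H" for a in atoms]), pos + 1
    if tok == "name":
        if pos + 1 >= len(tokens):
            raise ValueError(f"unparsable selection expression: {expression!r}")
        target = tokens[pos + 1].upper()
        return np.array([a.name.upper() == target for a in atoms]), pos + 2
    if tok == "chain":
        if pos + 1 >= len(tokens):
            raise ValueError(f"unparsable selection expression: {expression!r}")
        target = tokens[pos + 1]
        return np.array([a.chain_id == target for a in atoms]), pos + 2
    if tok == "resid":
        if pos + 1 >= len(tokens):
            raise ValueError(f"unparsable selection expression: {expression!r}")
        wanted: set[int] = set()
        for part in tokens[pos + 1].split(","):
            if "-" in part[1:]:  # allow negative ids, split on interior dash
                cut = part.index("-", 1)
                lo, hi = part[:cut], part[cut + 1 :]
                try:
                    wanted.update(range(int(lo), int(hi) + 1))
                except ValueError:
                    raise ValueError(
                        f"unparsable selection expression: {expression!r}"
                    ) from None
            else:
                try:
                    wanted.add(int(part))
                except ValueError:
                    raise ValueError(
                        f"unparsable selection expression: {expression!r}"
                    ) from None
        return np.array([a.res_id in wanted for a in atoms]), pos + 2
    raise ValueError(f"unparsable selection expression: {expression!r}")


def _parse_factor(topology, tokens, pos, expression):
    if pos >= len(tokens):
        raise ValueError(f"unparsable selection expression: {expression!r}")
    if tokens[pos].lower() == "not":
        mask, pos = _parse_factor(topology, tokens, pos + 1, expression)
        return ~mask, pos
    if tokens[pos] == "(":
        mask, pos = _parse_expression(topology, tokens, pos + 1, expression)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError(f"unparsable selection expression: {expression!r}")
        return mask, pos + 1
    return _primitive_mask(topology, tokens, pos, expression)


def _parse_term(topology, tokens, pos, expression):
    mask, pos = _parse_factor(topology, tokens, pos, expression)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        rhs, pos = _parse_factor(topology, tokens, pos + 1, expression)
        mask = mask & rhs
    return mask, pos


def _parse_expression(topology, tokens, pos, expression):
    mask, pos = _parse_term(topology, tokens, pos, expression)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        rhs, pos = _parse_term(topology, tokens, pos + 1, expression)
        mask = mask | rhs
    return mask, pos


def select(topology: Topology, expression: str) -> Selection:
    """Evaluate a selection expression against a topology.

    The grammar covers the selections the analysis stages need: residue-id
    ranges (``resid 487-494``), chains, atom-name classes (``name CA``,
    ``backbone``, ``heavy``, ``calpha``), the ligand flag, and boolean
    combinations with ``and`` / ``or`` / ``not`` and parentheses.

    An empty result is legal (a warning is emitted) so that range selections
    can be probed against topologies that may not contain them.
    """
    tokens = expression.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise ValueError(f"unparsable selection expression: {expression!r}")
    mask, pos = _parse_expression(topology, tokens, 0, expression)
    if pos != len(tokens):
        raise ValueError(f"unparsable selection expression: {expression!r}")
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(indices, expression)


# --------------------------------------------------------------------------
# multi-model PDB
# --------------------------------------------------------------------------


def _format_atom_line(serial: int, atom: Atom, xyz: np.ndarray) -> str:
    for v in xyz:
        if not (-999.999 <= v <= 9999.999):
            raise ValueError(
                f"coordinate {v:.3f} not representable in PDB %8.3f fixed width"
            )
    record = "HETATM" if atom.is_ligand else "ATOM  "
    name = atom.name
    # PDB convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field} {atom.res_name:<3s} {atom.chain_id:1s}"
        f"{atom.res_id:>4d}{atom.insertion_code or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_multimodel_pdb(topology: Topology, trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL block per frame)."""
    if trajectory.topology is not topology and trajectory.n_atoms != topology.n_atoms:
        raise ValueError("trajectory inconsistent with topology")
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        serial = 0
        prev_chain = None
        for i, atom in enumerate(topology.atoms):
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            serial += 1
            lines.append(_format_atom_line(serial, atom, trajectory.coordinates[f, i]))
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_atom_record(line: str, line_no: int) -> tuple[Atom, np.ndarray]:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_id = int(line[22:26])
        icode = line[26].strip()
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = name[:1]
    except (ValueError, IndexError):
        raise PDBParseError(f"malformed ATOM record at line {line_no}") from None
    atom = Atom(
        name=name,
        element=element,
        res_name=res_name,
        res_id=res_id,
        chain_id=chain_id,
        is_ligand=line.startswith("HETATM"),
        insertion_code=icode,
    )
    return atom, xyz, altloc


def read_multimodel_pdb(path, frame_interval: float | None = None):
    """Read a multi-model PDB into ``(Topology, Trajectory)``.

    MODEL/ENDMDL records delimit frames; a file without MODEL records is a
    single frame.  Atom order must be identical across models — a model with
    a different atom count raises :class:`PDBParseError` naming it.  Only
    altloc 'A' or blank records are kept.
    """
    frames: list[list[np.ndarray]] = []
    atom_lists: list[list[Atom]] = []
    current_coords: list[np.ndarray] | None = None
    current_atoms: list[Atom] | None = None
    saw_model = False

    def _close_model(model_no: int):
        nonlocal current_coords, current_atoms
        if current_coords is None:
            return
        if atom_lists and len(current_atoms) != len(atom_lists[0]):
            raise PDBParseError(
                f"model {model_no} has {len(current_atoms)} atoms; "
                f"expected {len(atom_lists[0])} (model 1)"
            )
        frames.append(current_coords)
        atom_lists.append(current_atoms)
        current_coords, current_atoms = None, None

    model_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("MODEL"):
                saw_model = True
                model_no += 1
                current_coords, current_atoms = [], []
            elif line.startswith("ENDMDL"):
                _close_model(model_no)
            elif line.startswith(("ATOM  ", "HETATM")):
                if current_coords is None:
                    current_coords, current_atoms = [], []
                    if saw_model:
                        model_no += 1
                atom, xyz, altloc = _parse_atom_record(line, line_no)
                if altloc not in ("", "A"):
                    continue
                current_atoms.append(atom)
                current_coords.append(xyz)
    _close_model(model_no if saw_model else 1)
    if not frames:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    topology = Topology(atom_lists[0])
    coords = np.array(frames)
    return topology, Trajectory(coords, topology, frame_interval=frame_interval)


# --------------------------------------------------------------------------
# TSV coordinate tables
# --------------------------------------------------------------------------


def write_coordinate_table(trajectory: Trajectory, path) -> None:
    """Write (frame, atom, x, y, z) rows as TSV."""
    with open(path, "w") as fh:
        fh.write("frame\tatom\tx\ty\tz\n")
        for f in range(trajectory.n_frames):
            for a in range(trajectory.n_atoms):
                x, y, z = trajectory.coordinates[f, a]
                fh.write(f"{f}\t{a}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_coordinate_table(path, topology: Topology, frame_interval=None) -> Trajectory:
    """Read a (frame, atom, x, y, z) TSV back into a Trajectory over ``topology``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    n_frames = int(df["frame"].max()) + 1
    n_atoms = int(df["atom"].max()) + 1
    coords = np.full((n_frames, n_atoms, 3), np.nan)
    coords[df["frame"].to_numpy(), df["atom"].to_numpy()] = df[["x", "y", "z"]].to_numpy()
    if np.isnan(coords).any():
        raise ValueError("coordinate table has missing (frame, atom) entries")
    return Trajectory(coords, topology, frame_interval=frame_interval)


def make_bead_topology(
    n_residues: int,
    chain_id: str = "A",
    ligand: bool = False,
    first_res_id: int = 1,
) -> Topology:
    """One-alpha-carbon-per-residue bead topology, optionally with one ligand bead.

    The coarse representation used by the synthetic systems: each protein
    residue is a single CA pseudo-atom; the optional ligand is a single
    HETATM bead appended after the protein chain.
    """
    atoms = [
        Atom(
            name="CA",
            element="C",
            res_name="ALA",
            res_id=first_res_id + i,
            chain_id=chain_id,
        )
        for i in range(n_residues)
    ]
    if ligand:
        atoms.append(
            Atom(
                name="C1",
                element="C",
                res_name="LIG",
                res_id=first_res_id + n_residues,
                chain_id=chain_id,
                is_ligand=True,
            )
        )
    return Topology(atoms)
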