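"""Reading, sanitizing and writing protein structures.

Structures are held as a flat, ordered list of heavy atoms (:class:`Atom`)
inside a :class:`Structure`.  Atom sets elsewhere in the package are sets of
integer indices into ``Structure.atoms``; this keeps every downstream
operation independent of chain/residue bookkeeping.

PDB and mmCIF parsing and PDB writing go through :mod:`gemmi`.  The one
piece of file-format logic owned by this module is the annotation scheme:
per-atom surface labels are encoded in the B-factor column (0 buried,
1 hydrophobic, 2 pseudohydrophilic, 3 genuine hydrophilic) so that any
structure viewer can color by label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Van der Waals radii (Å) assigned during sanitization, Bondi-style values.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
#: Fallback radius (Å) for elements outside VDW_RADII.
DEFAULT_VDW_RADIUS: float = 1.70

#: The twenty standard amino-acid residue names.
STANDARD_RESIDUES: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_RESIDUES: frozenset[str] = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP3"})

BACKBONE_ATOM_NAMES: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclass
class Atom:
    """A single (heavy) atom with PDB-style identity and geometry."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    altloc: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    vdw_radius: float = float("nan")
    het: bool = False
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.serial} {self.name}: coordinates must be three finite numbers"
            )

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain_id, residue_seq, insertion_code) — identifies the residue."""
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.insertion_code, self.name, self.altloc)


class Structure:
    """An ordered collection of atoms from a single model."""

    def __init__(self, atoms: Iterable[Atom], id: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.id = id

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def check_unique(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom identity {a.key}")
            seen.add(a.key)

    def first_residue_of_chain(self) -> dict[str, tuple[str, int, str]]:
        """Residue id of the first-seen residue per chain (N-terminus)."""
        first: dict[str, tuple[str, int, str]] = {}
        for a in self.atoms:
            first.setdefault(a.chain_id, a.residue_id)
        return first

    def merge(self, other: "Structure", id: str | None = None) -> "Structure":
        """Concatenate two structures, remapping colliding chain ids of *other*."""
        used = self.chains
        remap: dict[str, str] = {}
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
        for cid in sorted({a.chain_id for a in other.atoms}):
            new = cid
            if new in used:
                new = next(c for c in alphabet if c not in used and c not in remap.values())
            remap[cid] = new
        atoms = [replace(a, coords=a.coords.copy()) for a in self.atoms]
        offset = max((a.serial for a in self.atoms), default=0)
        for a in other.atoms:
            atoms.append(
                replace(
                    a,
                    serial=a.serial + offset,
                    chain_id=remap[a.chain_id],
                    coords=a.coords.copy(),
                )
            )
        return Structure(atoms, id=id if id is not None else f"{self.id}+{other.id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return Structure(atoms, id=self.id)


@dataclass(frozen=True)
class SanitizePolicy:
    """What :func:`sanitize` removes and how it resolves ambiguity."""

    remove_waters: bool = True
    remove_hetero: bool = True
    remove_hydrogens: bool = True
    remove_nonstandard: bool = True


def _infer_element(name: str) -> str:
    """Best-effort element from a PDB v3 atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "HDCNOSP":
        return "H" if stripped[0] == "D" else stripped[0]
    return stripped[0]


def _structure_from_gemmi(st: gemmi.Structure, id: str) -> Structure:
    if len(st) == 0:
        raise StructureError(f"{id}: no models in file")
    model = st[0]  # first model only; the method treats each entry as one rigid structure
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            icode = res.seqid.icode.strip()
            for at in res:
                elem = at.element.name if at.element and at.element.name != "X" else ""
                if not elem:
                    elem = _infer_element(at.name)
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=elem.upper(),
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        insertion_code=icode,
                        altloc=at.altloc.replace("\x00", ""),
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        het=het,
                        bfactor=at.b_iso,
                    )
                )
    if not any(not a.het for a in atoms):
        raise StructureError(f"{id}: no ATOM records in first model")
    return Structure(atoms, id=id)


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model only).

    HETATM records are retained but flagged (``Atom.het``); :func:`sanitize`
    removes them.  Elements are taken from the file and inferred from the
    atom name when absent.

    Parameters
    ----------
    path : file path
    format : {"auto", "pdb", "mmcif"}
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such structure file: {path}")
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise StructureError(f"unknown structure format: {format!r}")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on parse failure
        raise IOError(f"could not parse {path} as {format}: {exc}") from exc
    return _structure_from_gemmi(st, id=path.stem)


def assign_radii(s: Structure) -> None:
    """Assign van der Waals radii per element, in place (unknown → 1.70 Å)."""
    for a in s.atoms:
        if a.element not in VDW_RADII:
            warnings.warn(
                f"unknown element {a.element!r} for atom {a.serial} {a.name}; "
                f"using vdW radius {DEFAULT_VDW_RADIUS} Å"
            )
        a.vdw_radius = VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS)


def sanitize(s: Structure, policy: SanitizePolicy = SanitizePolicy()) -> Structure:
    """Reduce a parsed structure to a single clean conformer.

    Keeps the first model (already enforced at read time); for alternate
    locations keeps the highest-occupancy copy (ties broken by lexicographic
    altloc); removes waters, hetero atoms, hydrogens and non-standard
    residues per *policy*; assigns vdW radii.
    """
    kept: list[Atom] = []
    for a in s.atoms:
        if policy.remove_waters and a.residue_name in WATER_RESIDUES:
            continue
        if policy.remove_hetero and a.het and a.residue_name not in WATER_RESIDUES:
            continue
        if policy.remove_hydrogens and (a.element in ("H", "D") or (not a.element and _infer_element(a.name) == "H")):
            continue
        if policy.remove_nonstandard and not a.het and a.residue_name not in STANDARD_RESIDUES:
            logger.warning("removing non-standard residue %s %s", a.residue_name, a.residue_id)
            continue
        kept.append(replace(a, coords=a.coords.copy()))

    # altloc resolution: highest occupancy wins, ties to the lexicographically
    # first altloc; the surviving atom has its altloc cleared.
    by_site: dict[tuple, list[Atom]] = {}
    for a in kept:
        site = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        by_site.setdefault(site, []).append(a)
    resolved: list[Atom] = []
    chosen: dict[tuple, Atom] = {}
    for site, group in by_site.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        chosen[site] = best
    for a in kept:
        site = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        if chosen[site] is a:
            a.altloc = ""
            resolved.append(a)

    if not resolved:
        raise StructureError(f"{s.id}: structure empty after sanitization")
    out = Structure(resolved, id=s.id)
    out.check_unique()
    assign_radii(out)
    return out


def write_structure(s: Structure, path: str | Path, bfactors: Sequence[float] | None = None) -> None:
    """Write a :class:`Structure` as a PDB file (single model).

    ``bfactors`` overrides the per-atom B-factor column when given.
    """
    st = gemmi.Structure()
    st.name = s.id or "hydroshell"
    model = gemmi.Model(1)
    # gemmi's add_residue/add_chain copy their argument, so residues must be
    # fully populated before insertion: group atoms first, then build.
    chain_order: list[str] = []
    grouped: dict[str, list[tuple[tuple, list[int]]]] = {}
    for i, a in enumerate(s.atoms):
        if a.chain_id not in grouped:
            grouped[a.chain_id] = []
            chain_order.append(a.chain_id)
        residues = grouped[a.chain_id]
        if not residues or residues[-1][0] != a.residue_id:
            residues.append((a.residue_id, []))
        residues[-1][1].append(i)
    for cid in chain_order:
        chain = gemmi.Chain(cid or "A")
        for _rid, indices in grouped[cid]:
            first = s.atoms[indices[0]]
            res = gemmi.Residue()
            res.name = first.residue_name
            res.seqid = gemmi.SeqId(first.residue_seq, first.insertion_code or " ")
            res.het_flag = "H" if first.het else "A"
            for i in indices:
                a = s.atoms[i]
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element or _infer_element(a.name))
                at.pos = gemmi.Position(*a.coords)
                at.occ = float(a.occupancy)
                at.b_iso = float(bfactors[i] if bfactors is not None else a.bfactor)
                at.serial = int(a.serial)
                if a.altloc:
                    at.altloc = a.altloc
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def write_annotated_structure(s: Structure, labels: Mapping[int, object], path: str | Path) -> None:
    """Write a PDB file with per-atom surface labels encoded in the B-factor column.

    *labels* maps atom index → label (anything with an integer value in 0..3:
    0 buried, 1 hydrophobic, 2 pseudohydrophilic, 3 genuine hydrophilic).
    Re-reading the file recovers the codes exactly.
    """
    bfactors = []
    for i in range(len(s)):
        if i not in labels:
            raise StructureError(f"atom index {i} has no label")
        lab = labels[i]
        code = int(getattr(lab, "value", lab))
        if code not in (0, 1, 2, 3):
            raise StructureError(f"label code {code} outside the 0..3 encoding")
        bfactors.append(float(code))
    write_structure(s, path, bfactors=bfactors)


def read_label_codes(path: str | Path) -> list[int]:
    """Decode the B-factor label column written by :func:`write_annotated_structure`."""
    s = read_structure(path)
    return [int(round(a.bfactor)) for a in s.atoms]


def export_visualization(regions, s: Structure, path: str | Path, object_name: str = "structure") -> None:
    """Write a PyMOL command script (.pml) selecting and coloring each region.

    One named selection per region (by atom serial), mutually disjoint;
    region rank 1 gets the first color of the palette.
    """
    palette = ["orange", "marine", "forest", "purple", "yellow", "salmon", "teal", "olive"]
    serial_by_index = {i: a.serial for i, a in enumerate(s.atoms)}
    lines = [
        "# hydroshell low-entropy hydration-shell regions",
        f"# structure: {s.id}",
        f"# regions: {len(list(regions))}",
    ]
    seen: set[int] = set()
    for region in regions:
        for i in region.atoms:
            if i not in serial_by_index:
                raise StructureError(f"region rank {region.rank} references atom index {i} not in structure")
            if i in seen:
                raise StructureError(f"atom index {i} appears in more than one region")
            seen.add(i)
        serials = sorted(serial_by_index[i] for i in region.atoms)
        sel = "+".join(str(x) for x in serials)
        name = f"low_entropy_region_{region.rank}"
        color = palette[(region.rank - 1) % len(palette)]
        lines.append(f"select {name}, {object_name} and id {sel}")
        lines.append(f"color {color}, {name}")
    lines.append("deselect")
    Path(path).write_text("\n".join(lines) + "\n")
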