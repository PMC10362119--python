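"""Classification of surface atoms: hydrophobic, genuine or pseudohydrophilic.

The central idea: a polar (N/O) surface atom only contributes hydrophilicity
to the hydration shell if it can actually hydrogen-bond with water.  Three
screening rules demote polar surface atoms to *pseudohydrophilic*:

R1  the atom is saturated by an intramolecular hydrogen bond;
R2  it is a backbone carbonyl O or amide N of a residue whose protruding
    hydrophobic side chain shields the backbone from water (Ile, Val, Leu,
    Phe, Tyr, Trp, Cys, Met, Lys, Arg, His, Pro, Ala — plus Gly, whose
    hydrophilicity is very weak);
R3  it is the single polar tip of a long hydrophobic side chain
    (Trp NE1, Tyr OH, Lys NZ).

A fourth, post-hoc rule absorbs isolated genuine hydrophilic atoms whose
entire surface neighborhood is already low-entropy (R4): water around them
is fixed in the surrounding ordered network anyway.

Hydrophobic + pseudohydrophilic surface atoms together carry the
low-entropy hydration shell; the region module clusters them into patches.

Hydrogen-bond detection is heavy-atom only (donor–acceptor distance
<= 3.5 Å, no angle term) because hydrogens are stripped from most X-ray
inputs.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, StructureError
from .surface import SurfaceGraph, SurfaceModel, surface_atoms

if TYPE_CHECKING:  # pragma: no cover
    from .structure_io import Atom

DEFAULT_HBOND_CUTOFF = 3.5  # Å, heavy-atom donor–acceptor distance

#: Residues whose hydrophobic side chains shield their own backbone O/N (R2).
#: GLY is included for its very weak hydrophilicity; the set is overridable.
SHIELDED_RESIDUES: frozenset[str] = frozenset(
    "ILE VAL LEU PHE TYR TRP CYS MET LYS ARG HIS PRO ALA GLY".split()
)

#: Side-chain polar tips of long hydrophobic side chains (R3),
#: as (residue_name, atom_name).
SIDECHAIN_PSEUDO_ATOMS: frozenset[tuple[str, str]] = frozenset(
    {("TRP", "NE1"), ("TYR", "OH"), ("LYS", "NZ")}
)

#: Hydroxyl oxygens that can act as hydrogen-bond donors.
HYDROXYL_DONORS: frozenset[tuple[str, str]] = frozenset(
    {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}
)

POLAR_ELEMENTS = frozenset({"N", "O"})

# rule-trace tags
BASE = "BASE"
R1_HBOND = "R1_HBOND"
R2_BACKBONE_SHIELD = "R2_BACKBONE_SHIELD"
R3_SIDECHAIN = "R3_SIDECHAIN"
R4_ABSORBED = "R4_ABSORBED"


class Label(enum.IntEnum):
    """Per-atom surface class; the integer value is the B-factor encoding."""

    BURIED = 0
    HYDROPHOBIC = 1
    PSEUDOHYDROPHILIC = 2
    GENUINE_HYDROPHILIC = 3


#: Labels whose hydration shell is low-entropy.
LOW_ENTROPY_LABELS = frozenset({Label.HYDROPHOBIC, Label.PSEUDOHYDROPHILIC})


@dataclass(frozen=True)
class AtomLabel:
    value: Label
    rule_trace: tuple[str, ...] = ()

    @property
    def is_low_entropy(self) -> bool:
        return self.value in LOW_ENTROPY_LABELS


@dataclass(frozen=True)
class HBond:
    """A heavy-atom intramolecular hydrogen bond (indices into the structure)."""

    donor_heavy: int
    acceptor: int
    distance: float
    donor_on_surface: bool = True
    acceptor_on_surface: bool = True


def base_polarity(a: "Atom") -> str:
    """POLAR for N/O, NONPOLAR for C/S; unknown elements default to NONPOLAR.

    Nitrogen and oxygen carry enough partial charge to hydrogen-bond with
    water; side-chain carbon and sulfur do not.  Hydrogens follow their
    bonded heavy atom and are stripped upstream, so a lone H is nonpolar
    here (with a warning).
    """
    el = a.element.upper()
    if el in POLAR_ELEMENTS:
        return "POLAR"
    if el in ("C", "S"):
        return "NONPOLAR"
    warnings.warn(f"atom {a.serial} {a.name}: element {a.element!r} not classified; treating as NONPOLAR")
    return "NONPOLAR"


def _is_plausible_donor(a: "Atom") -> bool:
    if a.element == "N":
        return True
    return (a.residue_name, a.name) in HYDROXYL_DONORS


def detect_intramolecular_hbonds(
    s: Structure,
    surf: Iterable[int] | None = None,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> list[HBond]:
    """Geometric heavy-atom hydrogen bonds between polar atoms of *s*.

    A pair of N/O atoms counts when (a) their distance is within the cutoff,
    (b) at least one is a plausible donor (any N, or a Ser/Thr/Tyr hydroxyl
    O), (c) they belong to different residues, and (d) they are not the
    covalently bonded peptide C=O(i)···N(i+1) pair.  Bonds are detected
    between all polar atoms, buried or not, and each record notes whether
    its partners lie in *surf* (all atoms assumed on-surface when *surf* is
    None).  Ordering is deterministic (by atom index).
    """
    if hbond_cutoff <= 0:
        raise ValueError("hbond_cutoff must be > 0")
    surf_set = None if surf is None else frozenset(int(i) for i in surf)
    polar = [i for i, a in enumerate(s.atoms) if a.element in POLAR_ELEMENTS]
    if not polar:
        return []
    coords = s.coords[polar]
    tree = cKDTree(coords)
    bonds: list[HBond] = []
    for pi, pj in sorted(tree.query_pairs(r=hbond_cutoff)):
        i, j = polar[pi], polar[pj]
        a, b = s[i], s[j]
        if a.residue_id == b.residue_id:
            continue
        if _is_peptide_bond_pair(a, b):
            continue
        a_donor, b_donor = _is_plausible_donor(a), _is_plausible_donor(b)
        if not (a_donor or b_donor):
            continue
        # orient: the (unique) plausible donor first; two donors → lower index
        if a_donor:
            d, acc = i, j
        else:
            d, acc = j, i
        dist = float(np.linalg.norm(s[i].coords - s[j].coords))
        bonds.append(
            HBond(
                donor_heavy=d,
                acceptor=acc,
                distance=dist,
                donor_on_surface=surf_set is None or d in surf_set,
                acceptor_on_surface=surf_set is None or acc in surf_set,
            )
        )
    bonds.sort(key=lambda h: (h.donor_heavy, h.acceptor))
    return bonds


def _is_peptide_bond_pair(a: "Atom", b: "Atom") -> bool:
    """True for the covalent C=O(i)···N(i+1) backbone pair."""
    for o, n in ((a, b), (b, a)):
        if (
            o.name == "O"
            and n.name == "N"
            and o.chain_id == n.chain_id
            and n.residue_seq - o.residue_seq == 1
        ):
            return True
    return False


def screen_pseudohydrophilic(
    s: Structure,
    m: SurfaceModel,
    hbonds: Iterable[HBond],
    shielded_residues: frozenset[str] = SHIELDED_RESIDUES,
) -> dict[int, AtomLabel]:
    """Apply the base polarity split and screening rules R1–R3 to every atom.

    Non-surface atoms are BURIED.  Nonpolar surface atoms are HYDROPHOBIC.
    Polar surface atoms start GENUINE_HYDROPHILIC and are demoted to
    PSEUDOHYDROPHILIC when any of R1 (intramolecular H-bond), R2 (backbone
    O/N of a shielded residue) or R3 (Trp NE1 / Tyr OH / Lys NZ) fires; the
    rule trace records every rule that fired.

    Terminal backbone atoms (each chain's first N, and OXT) stay genuine
    under R2: charged termini are strongly hydrated.
    """
    if len(m.per_atom_sasa) != len(s):
        raise StructureError("surface model does not match the structure (atom count differs)")
    surf = surface_atoms(m, m.surface_threshold)
    in_hbond: set[int] = set()
    for h in hbonds:
        in_hbond.add(h.donor_heavy)
        in_hbond.add(h.acceptor)
    n_termini = set(s.first_residue_of_chain().values())

    labels: dict[int, AtomLabel] = {}
    for i, a in enumerate(s.atoms):
        if i not in surf:
            labels[i] = AtomLabel(Label.BURIED)
            continue
        if base_polarity(a) == "NONPOLAR":
            labels[i] = AtomLabel(Label.HYDROPHOBIC, (BASE,))
            continue
        trace = [BASE]
        if i in in_hbond:
            trace.append(R1_HBOND)
        if (
            a.name in ("N", "O")
            and a.residue_name in shielded_residues
            and not (a.name == "N" and a.residue_id in n_termini)
        ):
            trace.append(R2_BACKBONE_SHIELD)
        if (a.residue_name, a.name) in SIDECHAIN_PSEUDO_ATOMS:
            trace.append(R3_SIDECHAIN)
        if len(trace) > 1:
            labels[i] = AtomLabel(Label.PSEUDOHYDROPHILIC, tuple(trace))
        else:
            labels[i] = AtomLabel(Label.GENUINE_HYDROPHILIC, (BASE,))
    return labels


def absorb_isolated_hydrophilic(
    labels: Mapping[int, AtomLabel], g: SurfaceGraph
) -> dict[int, AtomLabel]:
    """Absorb genuine hydrophilic atoms fully surrounded by low-entropy shell (R4).

    Iterates to a fixed point: a GENUINE_HYDROPHILIC atom with at least one
    graph neighbor, all of whose neighbors are HYDROPHOBIC or
    PSEUDOHYDROPHILIC, becomes PSEUDOHYDROPHILIC (trace R4).  The
    low-entropy set only grows, so the iteration terminates.
    """
    out = dict(labels)
    changed = True
    while changed:
        changed = False
        for i in list(g.nodes):
            lab = out.get(i)
            if lab is None or lab.value is not Label.GENUINE_HYDROPHILIC:
                continue
            nbrs = list(g.neighbors(i))
            if nbrs and all(out[j].value in LOW_ENTROPY_LABELS for j in nbrs):
                out[i] = AtomLabel(Label.PSEUDOHYDROPHILIC, lab.rule_trace + (R4_ABSORBED,))
                changed = True
    return out


def label_atoms(
    s: Structure,
    m: SurfaceModel,
    g: SurfaceGraph | None = None,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    shielded_residues: frozenset[str] = SHIELDED_RESIDUES,
    absorb_isolated: bool = True,
) -> dict[int, AtomLabel]:
    """Convenience pipeline: H-bond detection, screening, optional absorption."""
    surf = surface_atoms(m, m.surface_threshold)
    hbonds = detect_intramolecular_hbonds(s, surf, hbond_cutoff)
    labels = screen_pseudohydrophilic(s, m, hbonds, shielded_residues)
    if absorb_isolated and g is not None:
        labels = absorb_isolated_hydrophilic(labels, g)
    return labels


def labels_from_codes(codes: Iterable[int]) -> dict[int, AtomLabel]:
    """Rebuild a label map from B-factor codes (trace information is lost)."""
    return {i: AtomLabel(Label(int(c))) for i, c in enumerate(codes)}
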