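"""Synthetic structures with known geometry and ground truth.

Every generator is deterministic given its parameters (and seed, where one
exists), so tests and the acceptance script can build identical inputs in
any environment without downloading real structures.

Peptide fixtures are built from ideal internal coordinates (N–CA 1.46 Å,
CA–C 1.52 Å, C–N 1.33 Å, ideal bond angles, chosen φ/ψ) with side chains
placed in a single default rotamer — good enough geometry for surface,
hydrogen-bond and labeling rules, with no pretense of physical realism.

Pseudo-atom fixtures (spheres of C/O atoms on a Fibonacci lattice) exercise
surface clustering and interface statistics with exactly known ground-truth
labels and regions: carbon is nonpolar, oxygen is polar, and every
pseudo-atom is its own residue so none of the residue-specific screening
rules fire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .labeling import AtomLabel, Label
from .structure_io import Atom, Structure, VDW_RADII

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# backbone ideal internal coordinates (Å, degrees)
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

# Side-chain template entries: atom name, element,
# (three parent atom names), bond length, bond angle, torsion (degrees).
# Parents are earlier atoms of the same residue; torsions are fixed default
# rotamers (mostly anti).  Geometry is idealized, not energy-minimized.
_SC = {
    "GLY": [],
    "ALA": [],  # CB placed separately for all non-GLY residues
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.42, 110.5, -60.0)],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.43, 109.5, -60.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, 60.0),
    ],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.81, 114.0, 180.0)],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, -60.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.53, 110.5, 180.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.53, 110.5, 60.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.51, 113.8, 180.0),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("SD", "S", ("CA", "CB", "CG"), 1.81, 112.7, 180.0),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, 180.0),
    ],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.49, 104.0, 30.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.50, 105.0, -35.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.4, 0.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.4, 180.0),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, 0.0),
        ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.4, 180.0),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.4, 0.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.4, 180.0),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.8, 0.0),
        ("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.4, 180.0),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.53, 111.0, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.53, 111.0, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.0, 180.0),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.5, 180.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.7, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.7, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.49, 113.8, 180.0),
        ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.7, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.35, 131.0, -90.0),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.37, 127.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.6, -90.0),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.8, 180.0),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
}
_SC["TYR"] = _SC["PHE"] + [("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0)]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position D given parents A-B-C, |CD|, ∠BCD and torsion ABCD."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("collinear parent atoms in internal-coordinate placement")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray, bond: float = 1.53) -> np.ndarray:
    """Tetrahedral CB from the backbone frame (fixed chirality)."""
    b1 = (n - ca) / np.linalg.norm(n - ca)
    b2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = b1 + b2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    # component weights give ~110.5 deg N-CA-CB and C-CA-CB angles
    direction = -0.619 * bisector + 0.786 * perp
    direction /= np.linalg.norm(direction)
    return ca + bond * direction


def _resolve_sequence(sequence: str) -> list[str]:
    seq = sequence.strip()
    if not seq:
        raise ValueError("empty sequence")
    if all(len(tok) == 3 for tok in seq.split()) and " " in seq:
        names = [tok.upper() for tok in seq.split()]
    else:
        names = []
        for ch in seq:
            if ch.upper() not in ONE_TO_THREE:
                raise ValueError(f"unknown residue code {ch!r}")
            names.append(ONE_TO_THREE[ch.upper()])
    for name in names:
        if name not in _SC:
            raise ValueError(f"unsupported residue {name}")
    return names


def make_peptide(sequence: str, phi: float = -57.0, psi: float = -47.0, chain_id: str = "A") -> Structure:
    """Ideal-geometry peptide with uniform (φ, ψ) and default-rotamer side chains.

    *sequence* is a one-letter string ("AAAAA") or space-separated
    three-letter codes ("ALA LEU SER").
    """
    names = _resolve_sequence(sequence)
    if len(names) < 2:
        raise ValueError("need at least 2 residues")
    residues: list[dict[str, tuple[str, np.ndarray]]] = []
    # first residue backbone seeded explicitly in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords: dict[tuple[int, str], np.ndarray] = {(0, "N"): n0, (0, "CA"): ca0, (0, "C"): c0}
    for i in range(1, len(names)):
        coords[(i, "N")] = place_atom(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")], BOND_C_N, ANGLE_CA_C_N, psi
        )
        coords[(i, "CA")] = place_atom(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")], BOND_N_CA, ANGLE_C_N_CA, OMEGA
        )
        coords[(i, "C")] = place_atom(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")], BOND_CA_C, ANGLE_N_CA_C, phi
        )
    # carbonyl O: anti to the next N (torsion psi + 180 about CA-C)
    for i in range(len(names)):
        coords[(i, "O")] = place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
    # side chains
    for i, rname in enumerate(names):
        if rname != "GLY":
            coords[(i, "CB")] = _place_cb(coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")])
        for aname, _el, parents, bond, angle, torsion in _SC[rname]:
            pa, pb, pc = (coords[(i, p)] for p in parents)
            coords[(i, aname)] = place_atom(pa, pb, pc, bond, angle, torsion)

    atoms: list[Atom] = []
    serial = 1
    for i, rname in enumerate(names):
        order = ["N", "CA", "C", "O"]
        if rname != "GLY":
            order.append("CB")
        order += [e[0] for e in _SC[rname]]
        for aname in order:
            el = "N" if aname == "N" else ("O" if aname == "O" else "C")
            for entry in _SC[rname]:
                if entry[0] == aname:
                    el = entry[1]
            atoms.append(
                Atom(
                    serial=serial,
                    name=aname,
                    element=el,
                    residue_name=rname,
                    chain_id=chain_id,
                    residue_seq=i + 1,
                    coords=coords[(i, aname)],
                    vdw_radius=VDW_RADII[el],
                )
            )
            serial += 1
    return Structure(atoms, id=f"peptide_{len(names)}")


def make_helix(sequence: str, phi: float = -57.0, psi: float = -47.0) -> Structure:
    """Ideal α-helix (default φ = −57°, ψ = −47°); needs >= 5 residues."""
    names = _resolve_sequence(sequence)
    if len(names) < 5:
        raise ValueError("a helix fixture needs at least 5 residues")
    s = make_peptide(sequence, phi=phi, psi=psi)
    s.id = f"helix_{len(names)}"
    return s


def make_extended_peptide(sequence: str, phi: float = -135.0, psi: float = 135.0) -> Structure:
    """Extended (β-strand-like) peptide: side chains exposed, no helical H-bonds."""
    s = make_peptide(sequence, phi=phi, psi=psi)
    s.id = f"extended_{len(s)}"
    return s


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic Fibonacci lattice of *n* points on a sphere."""
    k = np.arange(n, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * k
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def pseudo_structure(
    coords: np.ndarray,
    elements: list[str],
    chain_id: str = "A",
    id: str = "pseudo",
    serial_offset: int = 0,
) -> Structure:
    """One pseudo-atom per residue: labeling rules reduce to element polarity."""
    atoms = []
    for i, (xyz, el) in enumerate(zip(np.asarray(coords, dtype=float), elements)):
        name = f"{el}1"
        atoms.append(
            Atom(
                serial=serial_offset + i + 1,
                name=name,
                element=el,
                residue_name="UNK",
                chain_id=chain_id,
                residue_seq=i + 1,
                coords=xyz,
                vdw_radius=VDW_RADII[el],
            )
        )
    return Structure(atoms, id=id)


def make_two_cap_ball(
    n_atoms: int = 100,
    cap_fraction: float = 0.3,
    radius: float = 10.0,
) -> tuple[Structure, dict[int, AtomLabel], tuple[frozenset[int], frozenset[int]]]:
    """Sphere of pseudo-atoms: two antipodal nonpolar caps, polar belt between.

    *cap_fraction* is each cap's share of the sphere area (< 0.5 so a belt
    remains).  The belt must be wider than the adjacency cutoff for the cap
    regions to stay separate; with the defaults the straight-line gap
    between caps is 2·radius·(1 − 2·cap_fraction) = 8 Å.

    Returns the structure, the ground-truth labels (caps HYDROPHOBIC, belt
    GENUINE_HYDROPHILIC) and the two ground-truth cap regions.
    """
    if n_atoms < 30:
        raise ValueError("n_atoms must be >= 30")
    if cap_fraction >= 0.5:
        raise ValueError("cap_fraction must be < 0.5 (caps would touch)")
    if cap_fraction <= 0:
        raise ValueError("cap_fraction must be > 0")
    pts = fibonacci_sphere(n_atoms, radius)
    z_thresh = radius * (1.0 - 2.0 * cap_fraction)  # spherical cap area fraction
    top, bottom = [], []
    elements = []
    for i, p in enumerate(pts):
        if p[2] >= z_thresh:
            top.append(i)
            elements.append("C")
        elif p[2] <= -z_thresh:
            bottom.append(i)
            elements.append("C")
        else:
            elements.append("O")
    s = pseudo_structure(pts, elements, id="two_cap_ball")
    truth_labels = {
        i: AtomLabel(Label.HYDROPHOBIC if el == "C" else Label.GENUINE_HYDROPHILIC)
        for i, el in enumerate(elements)
    }
    return s, truth_labels, (frozenset(top), frozenset(bottom))


def _patch_ball(
    n_atoms: int,
    radius: float,
    patch_axis: np.ndarray,
    patch_half_angle: float,
    sprinkle_fraction: float,
    rng: np.random.Generator,
    jitter: float,
) -> tuple[np.ndarray, list[str], frozenset[int]]:
    pts = fibonacci_sphere(n_atoms, radius)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    axis = patch_axis / np.linalg.norm(patch_axis)
    cosang = (pts @ axis) / np.linalg.norm(pts, axis=1)
    in_patch = cosang >= math.cos(patch_half_angle)
    elements = []
    patch_idx = []
    for i in range(n_atoms):
        if in_patch[i]:
            elements.append("C")
            patch_idx.append(i)
        elif sprinkle_fraction > 0 and rng.random() < sprinkle_fraction:
            elements.append("C")
        else:
            elements.append("O")
    return pts, elements, frozenset(patch_idx)


def make_toy_complex(
    patch_radius: float = 6.0,
    separation: float = 4.0,
    seed: int = 0,
    n_atoms: int = 160,
    radius: float = 10.0,
    sprinkle_fraction: float = 0.12,
    contact_cutoff: float = 5.0,
) -> tuple[Structure, Structure, Structure, tuple[frozenset[int], frozenset[int]]]:
    """Two pseudo-atom balls with hydrophobic patches bound face to face.

    Each ball is mostly polar with one hydrophobic surface patch of arc
    radius *patch_radius* (Å along the surface) plus a sparse hydrophobic
    sprinkle elsewhere; the balls are placed patch-to-patch with the given
    surface *separation*.  Returns (A, B, bound complex, ground-truth
    interface) where the interface is the pair of cross-structure atom sets
    within *contact_cutoff* Å (indices into A and B respectively).
    """
    if separation < 3.0:
        raise ValueError("separation must be >= 3 Å (balls would overlap)")
    rng = np.random.default_rng(seed)
    half_angle = patch_radius / radius
    pts_a, el_a, _ = _patch_ball(n_atoms, radius, np.array([1.0, 0.0, 0.0]), half_angle, sprinkle_fraction, rng, jitter=0.15)
    pts_b, el_b, _ = _patch_ball(n_atoms, radius, np.array([-1.0, 0.0, 0.0]), half_angle, sprinkle_fraction, rng, jitter=0.15)
    center_b = np.array([2.0 * radius + separation, 0.0, 0.0])
    pts_b = pts_b + center_b
    a = pseudo_structure(pts_a, el_a, chain_id="A", id=f"toy_A_{seed}")
    b = pseudo_structure(pts_b, el_b, chain_id="B", id=f"toy_B_{seed}")
    complex_ab = a.merge(b, id=f"toy_complex_{seed}")
    # ground-truth interface by brute cross-distance
    diff = pts_a[:, None, :] - pts_b[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iface_a = frozenset(int(i) for i in np.nonzero((d <= contact_cutoff).any(axis=1))[0])
    iface_b = frozenset(int(j) for j in np.nonzero((d <= contact_cutoff).any(axis=0))[0])
    return a, b, complex_ab, (iface_a, iface_b)


def _rotation_aligning(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector v onto unit vector u (Rodrigues)."""
    c = float(np.dot(v, u))
    axis = np.cross(v, u)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis orthogonal to v
        ortho = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            ortho = np.array([0.0, 1.0, 0.0])
        axis = np.cross(v, ortho)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    axis = axis / n
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    s = n
    return np.eye(3) + s * K + (1 - c) * K @ K


def make_residue_panel() -> Structure:
    """Hand-built panel of well-separated residues exercising each rule.

    Stations 25 Å apart hold single-residue fragments of LEU, SER, TYR,
    LYS and GLY (every atom solvent-exposed), plus an ASP/ASN pair placed
    so that ASP OD1 ··· ASN ND2 is a 3.0 Å hydrogen bond and no other
    cross-fragment polar pair comes within bonding distance.
    """
    frags = []
    for idx, code in enumerate(["L", "S", "Y", "K", "G", "D"]):
        f = make_peptide(code + code)  # dipeptide; assertions use residue 2's backbone? no: residue 1
        frags.append(f)
    # Single residues are cleaner: build 2-residue peptides and keep residue 1,
    # so residue 1 keeps a C-terminal-free backbone O while its N is terminal.
    structures = []
    for f in frags:
        structures.append([a for a in f.atoms if a.residue_seq == 1])

    atoms: list[Atom] = []
    serial = 1
    station = 0.0
    od1 = None
    for resi, frag_atoms in enumerate(structures, start=1):
        offset = np.array([station, 0.0, 0.0])
        for a in frag_atoms:
            new = Atom(
                serial=serial,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                chain_id="A",
                residue_seq=resi,
                coords=a.coords + offset,
                vdw_radius=a.vdw_radius,
            )
            atoms.append(new)
            if a.residue_name == "ASP" and a.name == "OD1":
                od1 = new
            serial += 1
        station += 25.0

    # ASN fragment: orient it so the fragment extends away from ASP along
    # the OD1 outward direction, then translate so ND2 sits 3.0 Å from OD1.
    asn_atoms = [a for a in make_peptide("NN").atoms if a.residue_seq == 1]
    asp_coords = np.array([a.coords for a in atoms if a.residue_name == "ASP"])
    u = od1.coords - asp_coords.mean(axis=0)
    u = u / np.linalg.norm(u)
    target_nd2 = od1.coords + 3.0 * u
    nd2_now = next(a for a in asn_atoms if a.name == "ND2")
    centroid = np.mean([a.coords for a in asn_atoms], axis=0)
    v = centroid - nd2_now.coords
    v = v / np.linalg.norm(v)
    rot = _rotation_aligning(v, u)
    pivot = nd2_now.coords.copy()
    for a in asn_atoms:
        a.coords = rot @ (a.coords - pivot) + pivot
    shift = target_nd2 - nd2_now.coords
    for a in asn_atoms:
        atoms.append(
            Atom(
                serial=serial,
                name=a.name,
                element=a.element,
                residue_name="ASN",
                chain_id="A",
                residue_seq=7,
                coords=a.coords + shift,
                vdw_radius=a.vdw_radius,
            )
        )
        serial += 1
    return Structure(atoms, id="residue_panel")
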