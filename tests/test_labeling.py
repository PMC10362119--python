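"""Polarity, hydrogen-bond detection and the pseudohydrophilic screening rules."""

import numpy as np
import pytest

from hydroshell import (
    Label,
    absorb_isolated_hydrophilic,
    base_polarity,
    compute_sasa,
    detect_intramolecular_hbonds,
    label_atoms,
    map_structure,
    screen_pseudohydrophilic,
    surface_atoms,
    surface_neighbor_graph,
)
from hydroshell.fixtures import make_extended_peptide, make_helix, make_peptide, make_residue_panel, pseudo_structure
from hydroshell.labeling import (
    AtomLabel,
    BASE,
    R1_HBOND,
    R2_BACKBONE_SHIELD,
    R3_SIDECHAIN,
    R4_ABSORBED,
)
from hydroshell.structure_io import Atom


def _atom(name, element, residue="ALA", serial=1):
    return Atom(serial=serial, name=name, element=element, residue_name=residue,
                chain_id="A", residue_seq=1, coords=np.zeros(3))


@pytest.mark.parametrize(
    "name,element,residue,expected",
    [
        ("OG", "O", "SER", "POLAR"),
        ("CD1", "C", "LEU", "NONPOLAR"),
        ("SD", "S", "MET", "NONPOLAR"),
        ("NZ", "N", "LYS", "POLAR"),
    ],
)
def test_base_polarity(name, element, residue, expected):
    assert base_polarity(_atom(name, element, residue)) == expected


def test_base_polarity_unknown_element_warns_nonpolar():
    with pytest.warns(UserWarning):
        assert base_polarity(_atom("FE", "FE", "HEM")) == "NONPOLAR"


def _two_sidechain_atoms(distance):
    """ASN ND2 (donor) and ASP OD1 (acceptor) of different residues."""
    atoms = [
        Atom(serial=1, name="ND2", element="N", residue_name="ASN", chain_id="A",
             residue_seq=1, coords=np.zeros(3)),
        Atom(serial=2, name="OD1", element="O", residue_name="ASP", chain_id="A",
             residue_seq=5, coords=np.array([distance, 0.0, 0.0])),
    ]
    from hydroshell.structure_io import Structure
    return Structure(atoms, id="pair")


def test_hbond_within_cutoff_detected():
    bonds = detect_intramolecular_hbonds(_two_sidechain_atoms(2.9))
    assert len(bonds) == 1
    assert bonds[0].donor_heavy == 0 and bonds[0].acceptor == 1
    assert bonds[0].distance == pytest.approx(2.9)


def test_hbond_beyond_cutoff_ignored():
    assert detect_intramolecular_hbonds(_two_sidechain_atoms(3.8)) == []


def test_no_hbond_without_plausible_donor():
    """Two carbonyl-type oxygens cannot bond: neither is a donor."""
    from hydroshell.structure_io import Structure
    atoms = [
        Atom(serial=1, name="OD1", element="O", residue_name="ASP", chain_id="A",
             residue_seq=1, coords=np.zeros(3)),
        Atom(serial=2, name="OE1", element="O", residue_name="GLU", chain_id="A",
             residue_seq=5, coords=np.array([2.9, 0.0, 0.0])),
    ]
    assert detect_intramolecular_hbonds(Structure(atoms, id="x")) == []


def test_helix_backbone_hbond_ladder():
    """Ideal α-helix: O(i)···N(i+4) detected for every interior pair, at 2.7-3.2 Å."""
    h = make_helix("AAAAAAAAAA")
    # independent geometry check, bypassing the detector
    pos = {(a.residue_seq, a.name): a.coords for a in h.atoms}
    expected_pairs = set()
    for i in range(1, 7):
        d = np.linalg.norm(pos[(i, "O")] - pos[(i + 4, "N")])
        assert 2.7 <= d <= 3.2
        expected_pairs.add((i, i + 4))
    bonds = detect_intramolecular_hbonds(h)
    found = set()
    for b in bonds:
        don, acc = h[b.donor_heavy], h[b.acceptor]
        if don.name == "N" and acc.name == "O":
            found.add((acc.residue_seq, don.residue_seq))
    assert expected_pairs <= found


def test_peptide_bond_pair_excluded():
    """The covalent C=O(i)···N(i+1) pair never counts as a hydrogen bond."""
    p = make_peptide("AA")
    bonds = detect_intramolecular_hbonds(p)
    for b in bonds:
        pair = {(p[b.donor_heavy].name, p[b.donor_heavy].residue_seq),
                (p[b.acceptor].name, p[b.acceptor].residue_seq)}
        assert pair != {("O", 1), ("N", 2)}


PANEL_EXPECTATIONS = [
    # (residue_name, atom_name, expected label, required trace tags)
    ("LEU", "O", Label.PSEUDOHYDROPHILIC, {R2_BACKBONE_SHIELD}),
    ("LEU", "CD1", Label.HYDROPHOBIC, {BASE}),
    ("SER", "OG", Label.GENUINE_HYDROPHILIC, {BASE}),
    ("TYR", "OH", Label.PSEUDOHYDROPHILIC, {R3_SIDECHAIN}),
    ("LYS", "NZ", Label.PSEUDOHYDROPHILIC, {R3_SIDECHAIN}),
    ("GLY", "O", Label.PSEUDOHYDROPHILIC, {R2_BACKBONE_SHIELD}),
    ("ASP", "OD1", Label.PSEUDOHYDROPHILIC, {R1_HBOND}),
    ("ASN", "ND2", Label.PSEUDOHYDROPHILIC, {R1_HBOND}),
]


def test_screening_rules_on_residue_panel():
    panel = make_residue_panel()
    m = compute_sasa(panel)
    surf = surface_atoms(m)
    bonds = detect_intramolecular_hbonds(panel, surf)
    labels = screen_pseudohydrophilic(panel, m, bonds)
    by_id = {(a.residue_name, a.name): labels[i] for i, a in enumerate(panel.atoms)}
    for residue, name, expected, tags in PANEL_EXPECTATIONS:
        lab = by_id[(residue, name)]
        assert lab.value is expected, f"{residue} {name}: {lab}"
        assert tags <= set(lab.rule_trace), f"{residue} {name}: trace {lab.rule_trace}"


def test_screening_is_deterministic(residue_panel):
    m = compute_sasa(residue_panel)
    bonds = detect_intramolecular_hbonds(residue_panel)
    l1 = screen_pseudohydrophilic(residue_panel, m, bonds)
    l2 = screen_pseudohydrophilic(residue_panel, m, bonds)
    assert l1 == l2


def test_labels_partition_atoms(residue_panel):
    res = map_structure(residue_panel)
    surf = res.surface_model.surface_atoms
    for i in range(len(residue_panel)):
        lab = res.labels[i]
        if i in surf:
            assert lab.value is not Label.BURIED
        else:
            assert lab.value is Label.BURIED


def test_hbond_monotonicity():
    """Adding an H-bond only converts genuine → pseudohydrophilic, never back."""
    panel = make_residue_panel()
    m = compute_sasa(panel)
    bonds = detect_intramolecular_hbonds(panel)
    without = screen_pseudohydrophilic(panel, m, [])
    with_bonds = screen_pseudohydrophilic(panel, m, bonds)
    for i in range(len(panel)):
        if without[i].value is Label.PSEUDOHYDROPHILIC:
            assert with_bonds[i].value is Label.PSEUDOHYDROPHILIC
        if without[i].value in (Label.BURIED, Label.HYDROPHOBIC):
            assert with_bonds[i].value is without[i].value


def test_all_leucine_surface_has_no_genuine_interior_atoms():
    s = make_extended_peptide("LLLLLLLL")
    res = map_structure(s)
    for i, a in enumerate(s.atoms):
        if a.residue_seq in (1, 8):  # termini excluded from the claim
            continue
        assert res.labels[i].value is not Label.GENUINE_HYDROPHILIC, (a.residue_seq, a.name)


def _chain_structure(elements, spacing=3.0):
    coords = [[i * spacing, 0.0, 0.0] for i in range(len(elements))]
    return pseudo_structure(coords, elements)


def _graph_and_labels(elements, values):
    s = _chain_structure(elements)
    g = surface_neighbor_graph(s, set(range(len(elements))), 5.0)
    labels = {i: AtomLabel(v, (BASE,)) for i, v in enumerate(values)}
    return g, labels


def test_absorption_of_surrounded_genuine_atom():
    g, labels = _graph_and_labels(
        ["C", "C", "O", "C", "C"],
        [Label.HYDROPHOBIC] * 2 + [Label.GENUINE_HYDROPHILIC] + [Label.HYDROPHOBIC] * 2,
    )
    out = absorb_isolated_hydrophilic(labels, g)
    assert out[2].value is Label.PSEUDOHYDROPHILIC
    assert R4_ABSORBED in out[2].rule_trace


def test_no_absorption_with_genuine_neighbor():
    g, labels = _graph_and_labels(
        ["C", "O", "O", "C", "C"],
        [Label.HYDROPHOBIC, Label.GENUINE_HYDROPHILIC, Label.GENUINE_HYDROPHILIC,
         Label.HYDROPHOBIC, Label.HYDROPHOBIC],
    )
    out = absorb_isolated_hydrophilic(labels, g)
    assert out[1].value is Label.GENUINE_HYDROPHILIC
    assert out[2].value is Label.GENUINE_HYDROPHILIC


def test_no_absorption_without_neighbors():
    s = pseudo_structure([[0, 0, 0], [50, 0, 0]], ["O", "C"])
    g = surface_neighbor_graph(s, {0, 1}, 5.0)
    labels = {0: AtomLabel(Label.GENUINE_HYDROPHILIC, (BASE,)), 1: AtomLabel(Label.HYDROPHOBIC, (BASE,))}
    out = absorb_isolated_hydrophilic(labels, g)
    assert out[0].value is Label.GENUINE_HYDROPHILIC


def test_absorption_iterates_to_fixed_point():
    """A genuine chain next to a hydrophobic wall is swallowed atom by atom."""
    g, labels = _graph_and_labels(
        ["C", "C", "O", "O", "C", "C"],
        [Label.HYDROPHOBIC] * 2 + [Label.GENUINE_HYDROPHILIC] * 2 + [Label.HYDROPHOBIC] * 2,
    )
    # with 5 Å cutoff on a 3 Å chain, atoms see two neighbors each side
    out = absorb_isolated_hydrophilic(labels, g)
    again = absorb_isolated_hydrophilic(out, g)
    assert out == again  # idempotent fixed point


def test_pipeline_idempotent_on_own_output(ball_pipeline):
    res = ball_pipeline
    relabeled = absorb_isolated_hydrophilic(res.labels, res.graph)
    assert relabeled == res.labels
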