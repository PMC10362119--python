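"""Interface definition, ratio statistic, prediction scoring, pose scoring, energetics."""

import numpy as np
import pytest

from hydroshell import (
    Label,
    ThermodynamicParams,
    compute_sasa,
    define_interface,
    evaluate_prediction,
    hydration_free_energy,
    hydrophilic_area_ratio,
    map_structure,
    predict_binding_site,
    score_pose,
)
from hydroshell.fixtures import fibonacci_sphere, make_toy_complex, pseudo_structure
from hydroshell.labeling import AtomLabel
from hydroshell.regions import LowEntropyRegion


def test_distant_chains_have_empty_interface():
    a = pseudo_structure(fibonacci_sphere(40, 8.0), ["C"] * 40, chain_id="A")
    b = pseudo_structure(fibonacci_sphere(40, 8.0) + [80, 0, 0], ["C"] * 40, chain_id="B")
    iface = define_interface(a.merge(b), {"A"}, {"B"})
    assert not iface.interface_atoms_a and not iface.interface_atoms_b


def test_cross_pair_within_cutoff_flagged():
    a = pseudo_structure([[0, 0, 0]], ["C"], chain_id="A")
    b = pseudo_structure([[4.0, 0, 0]], ["C"], chain_id="B")
    cab = a.merge(b)
    iface = define_interface(cab, {"A"}, {"B"}, contact_cutoff=5.0)
    assert iface.interface_atoms_a == {0}
    assert iface.interface_atoms_b == {1}


def test_interface_matches_brute_force_on_toy_complex():
    a, b, cab, (ia, ib) = make_toy_complex(seed=4)
    iface = define_interface(cab, {"A"}, {"B"}, contact_cutoff=5.0)
    # complex atom indexing: A atoms first, then B
    na = len(a)
    assert iface.interface_atoms_a == ia
    assert {i - na for i in iface.interface_atoms_b} == ib
    # brute force over all cross pairs
    expect_a = {
        i
        for i in range(na)
        for j in range(len(b))
        if np.linalg.norm(a.coords[i] - b.coords[j]) <= 5.0
    }
    assert iface.interface_atoms_a == expect_a


def test_invalid_chain_groups_rejected():
    a = pseudo_structure([[0, 0, 0]], ["C"], chain_id="A")
    b = pseudo_structure([[4, 0, 0]], ["C"], chain_id="B")
    cab = a.merge(b)
    with pytest.raises(ValueError):
        define_interface(cab, {"A"}, {"A"})
    with pytest.raises(ValueError):
        define_interface(cab, {"A"}, {"Z"})


def test_all_hydrophobic_interface_has_zero_ratio_in():
    pts = fibonacci_sphere(80, 10.0)
    # hydrophobic face at +x (the "interface") plus a few hydrophobic atoms
    # elsewhere so the outside ratio stays defined
    elements = ["C" if p[0] > 5 or i % 7 == 0 else "O" for i, p in enumerate(pts)]
    s = pseudo_structure(pts, elements)
    res = map_structure(s, absorb_isolated=False)
    iface = [i for i, p in enumerate(pts) if p[0] > 5]
    stat = hydrophilic_area_ratio(res.surface_model, res.labels, iface)
    assert stat.ratio_in == 0.0
    assert stat.ratio_out > 0.0


def test_symmetric_labels_give_equal_ratios():
    """Mirror-symmetric labels with the interface = one hemisphere → equal ratios."""
    pts = np.array([[x, y, z] for x in (-6.0, 6.0) for y in (-6.0, 6.0) for z in (-6.0, 6.0)])
    elements = ["C", "O"] * 4
    s = pseudo_structure(pts, elements)
    m = compute_sasa(s)
    labels = {i: AtomLabel(Label.HYDROPHOBIC if el == "C" else Label.GENUINE_HYDROPHILIC)
              for i, el in enumerate(elements)}
    half = [i for i, p in enumerate(pts) if p[0] < 0]
    stat = hydrophilic_area_ratio(m, labels, half)
    assert stat.ratio_in == pytest.approx(stat.ratio_out, rel=1e-6)


def test_ratio_direction_on_designed_complex(toy_complex_sweep):
    for row in toy_complex_sweep:
        assert row["ratio_in"] < row["ratio_out"], row


def _region(atoms, rank=1):
    return LowEntropyRegion(frozenset(atoms), float(len(atoms)), rank, frozenset())


def test_evaluate_prediction_arithmetic():
    iface = set(range(10))
    perfect = evaluate_prediction(_region(iface), iface)
    assert perfect == {"recall": 1.0, "precision": 1.0, "hit": True}
    disjoint = evaluate_prediction(_region(range(20, 30)), iface)
    assert disjoint == {"recall": 0.0, "precision": 0.0, "hit": False}
    padded = evaluate_prediction(_region(set(range(10)) | set(range(20, 30))), iface)
    assert padded["recall"] == 1.0
    assert padded["precision"] == 0.5
    with pytest.raises(ValueError):
        evaluate_prediction(_region({1}), set())


def test_predict_binding_site_returns_top_ranked():
    regs = [_region({1}, 1), _region({2}, 2), _region({3}, 3)]
    assert [r.rank for r in predict_binding_site(regs, k=1)] == [1]
    assert [r.rank for r in predict_binding_site(regs, k=3)] == [1, 2, 3]
    with pytest.warns(UserWarning):
        assert predict_binding_site([], k=1) == []


def test_separated_pose_scores_zero():
    a, b, _, _ = make_toy_complex(seed=2)
    ra = map_structure(a)
    rb = map_structure(b)
    score = score_pose(
        a, ra.labels, b, rb.labels,
        rotation=np.eye(3), translation=np.array([200.0, 0.0, 0.0]),
        surface_a=ra.surface_model, surface_b=rb.surface_model,
    )
    assert score.total_contact_area == pytest.approx(0.0, abs=1e-6)
    assert score.low_entropy_overlap_area == 0.0
    assert score.clash_count == 0


def test_self_dock_identity_clashes():
    a, _, _, _ = make_toy_complex(seed=2)
    ra = map_structure(a)
    score = score_pose(a, ra.labels, a, ra.labels,
                       surface_a=ra.surface_model, surface_b=ra.surface_model)
    assert score.clash_count > 0


def test_improper_transform_rejected():
    a, b, _, _ = make_toy_complex(seed=2)
    ra = map_structure(a)
    rb = map_structure(b)
    mirror = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        score_pose(a, ra.labels, b, rb.labels, rotation=mirror,
                   surface_a=ra.surface_model, surface_b=rb.surface_model)


def test_matched_pose_beats_rotated_decoy():
    a, b, _, _ = make_toy_complex(seed=6)
    ra = map_structure(a)
    rb = map_structure(b)
    matched = score_pose(a, ra.labels, b, rb.labels,
                         surface_a=ra.surface_model, surface_b=rb.surface_model)
    center = b.coords.mean(axis=0)
    R = np.diag([-1.0, -1.0, 1.0])  # 180° about z: patch turns away from A
    decoy = score_pose(a, ra.labels, b, rb.labels, rotation=R, translation=center - R @ center,
                       surface_a=ra.surface_model, surface_b=rb.surface_model)
    assert matched.low_entropy_overlap_area > decoy.low_entropy_overlap_area
    assert 0.0 <= matched.low_entropy_overlap_area <= matched.total_contact_area


def test_hydration_free_energy_reference_values():
    out = hydration_free_energy(1)
    assert out["delta_S_per_mol"] == pytest.approx(29.0)
    assert out["T_delta_S_per_mol"] == pytest.approx(8961.0)
    assert out["total"] == pytest.approx(8961.0)


def test_hydration_free_energy_linearity():
    assert hydration_free_energy(0)["total"] == 0.0
    assert hydration_free_energy(2)["total"] == pytest.approx(2 * 8961.0)
    out10 = hydration_free_energy(10)
    assert out10["total"] == pytest.approx(10 * out10["T_delta_S_per_mol"])
    with pytest.raises(ValueError):
        hydration_free_energy(-1)


def test_thermodynamic_params_validation():
    with pytest.raises(ValueError):
        ThermodynamicParams(S_solid=70, S_liquid=41)
    with pytest.raises(ValueError):
        ThermodynamicParams(T=-1)
    custom = ThermodynamicParams(S_solid=40, S_liquid=60, T=300)
    assert hydration_free_energy(1, custom)["T_delta_S_per_mol"] == pytest.approx(6000.0)
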