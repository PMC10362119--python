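"""Shared fixtures: synthetic structures and cached pipeline sweeps."""

import numpy as np
import pytest

from hydroshell import compute_sasa, map_structure
from hydroshell.fixtures import (
    make_helix,
    make_residue_panel,
    make_toy_complex,
    make_two_cap_ball,
    pseudo_structure,
)

TOY_SEEDS = list(range(20))


@pytest.fixture(scope="session")
def helix10():
    return make_helix("AAAAAAAAAA")


@pytest.fixture(scope="session")
def residue_panel():
    return make_residue_panel()


@pytest.fixture(scope="session")
def two_cap_ball():
    return make_two_cap_ball(n_atoms=100, cap_fraction=0.3)


@pytest.fixture(scope="session")
def ball_pipeline(two_cap_ball):
    s, truth_labels, truth_regions = two_cap_ball
    return map_structure(s)


@pytest.fixture(scope="session")
def toy_complex_sweep():
    """Per-seed interface statistics and prediction quality on toy complexes."""
    from hydroshell import evaluate_prediction, hydrophilic_area_ratio, predict_binding_site

    rows = []
    for seed in TOY_SEEDS:
        a, b, cab, (iface_a, iface_b) = make_toy_complex(seed=seed)
        res = map_structure(a)
        stat = hydrophilic_area_ratio(res.surface_model, res.labels, iface_a)
        pred = predict_binding_site(res.regions, k=1)
        ev = evaluate_prediction(pred[0], iface_a)
        rows.append(
            {
                "seed": seed,
                "ratio_in": stat.ratio_in,
                "ratio_out": stat.ratio_out,
                "recall": ev["recall"],
                "precision": ev["precision"],
                "hit": ev["hit"],
            }
        )
    return rows


def single_atom_structure(element="C"):
    return pseudo_structure(np.zeros((1, 3)), [element], id="single")
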