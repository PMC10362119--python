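"""Clustering low-entropy surface atoms into connected regions.

A low-entropy region is a connected component of the surface neighbor
graph restricted to hydrophobic + pseudohydrophilic atoms.  Its area is
the sum of member per-atom SASA.  Regions are ranked by decreasing area
(rank 1 = largest; ties broken by the lower minimum atom serial), and the
"large" regions — the binding-site candidates — are the top-k above a
minimum area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .labeling import AtomLabel, LOW_ENTROPY_LABELS, Label
from .structure_io import Structure, StructureError
from .surface import SurfaceGraph, SurfaceModel

DEFAULT_TOP_K = 3  # proteins are typically displayed with their three largest regions
DEFAULT_MIN_AREA = 200.0  # Å²


@dataclass(frozen=True)
class LowEntropyRegion:
    """A connected low-entropy surface patch."""

    atoms: frozenset[int]
    area: float
    rank: int
    residues: frozenset[tuple[str, int, str]]

    def __len__(self) -> int:
        return len(self.atoms)


def map_low_entropy_regions(
    s: Structure,
    labels: Mapping[int, AtomLabel],
    g: SurfaceGraph,
    m: SurfaceModel,
) -> list[LowEntropyRegion]:
    """Connected components of the low-entropy subgraph, ranked by area.

    Raises on a label/graph mismatch (graph nodes without labels).
    """
    missing = [i for i in g.nodes if i not in labels]
    if missing:
        raise StructureError(f"{len(missing)} graph atoms have no label (first: {missing[0]})")
    low = [i for i in g.nodes if labels[i].value in LOW_ENTROPY_LABELS]
    sub = g.subgraph(low)
    serial = {i: s[i].serial for i in low}
    comps = []
    for comp in nx.connected_components(sub):
        atoms = frozenset(comp)
        area = float(sum(m.per_atom_sasa[i] for i in atoms))
        comps.append((area, min(serial[i] for i in atoms), atoms))
    comps.sort(key=lambda t: (-t[0], t[1]))
    regions = []
    for rank, (area, _min_serial, atoms) in enumerate(comps, start=1):
        residues = frozenset(s[i].residue_id for i in atoms)
        regions.append(LowEntropyRegion(atoms=atoms, area=area, rank=rank, residues=residues))
    return regions


def largest_regions(
    regions: Sequence[LowEntropyRegion],
    k: int = DEFAULT_TOP_K,
    min_area: float = DEFAULT_MIN_AREA,
) -> list[LowEntropyRegion]:
    """Top-*k* regions with area >= *min_area*, in rank order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [r for r in sorted(regions, key=lambda r: r.rank) if r.area >= min_area][:k]


def region_summary(regions: Iterable[LowEntropyRegion], m: SurfaceModel) -> pd.DataFrame:
    """Per-region table: rank, atom/residue counts, area and surface fraction."""
    total = float(sum(m.per_atom_sasa[i] for i in m.surface_atoms))
    rows = [
        {
            "rank": r.rank,
            "n_atoms": len(r.atoms),
            "n_residues": len(r.residues),
            "area": r.area,
            "surface_fraction": (r.area / total) if total > 0 else 0.0,
        }
        for r in sorted(regions, key=lambda r: r.rank)
    ]
    return pd.DataFrame(rows, columns=["rank", "n_atoms", "n_residues", "area", "surface_fraction"])
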