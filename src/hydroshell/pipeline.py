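"""End-to-end driver: structure → SASA → labels → low-entropy regions.

This is the composition the CLI and batch users run; each stage remains
individually accessible through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import labeling, regions, surface
from .labeling import AtomLabel
from .regions import LowEntropyRegion
from .structure_io import Structure
from .surface import SurfaceGraph, SurfaceModel


@dataclass
class HydrationShellMap:
    """Everything computed for one structure, plus the config that produced it."""

    structure: Structure
    surface_model: SurfaceModel
    graph: SurfaceGraph
    labels: dict[int, AtomLabel]
    regions: list[LowEntropyRegion]
    config: dict = field(default_factory=dict)


def map_structure(
    s: Structure,
    probe_radius: float = surface.DEFAULT_PROBE_RADIUS,
    n_points: int = surface.DEFAULT_N_POINTS,
    surface_threshold: float = surface.DEFAULT_SURFACE_THRESHOLD,
    adjacency_cutoff: float = surface.DEFAULT_ADJACENCY_CUTOFF,
    hbond_cutoff: float = labeling.DEFAULT_HBOND_CUTOFF,
    shielded_residues: frozenset[str] = labeling.SHIELDED_RESIDUES,
    absorb_isolated: bool = True,
) -> HydrationShellMap:
    """Run the full low-entropy hydration-shell mapping pipeline on *s*.

    *s* must be sanitized (vdW radii assigned).  Returns the surface model,
    surface graph, per-atom labels and the ranked low-entropy regions.
    """
    m = surface.compute_sasa(s, probe_radius=probe_radius, n_points=n_points, surface_threshold=surface_threshold)
    surf = surface.surface_atoms(m, surface_threshold)
    g = surface.surface_neighbor_graph(s, surf, adjacency_cutoff)
    labels = labeling.label_atoms(
        s,
        m,
        g,
        hbond_cutoff=hbond_cutoff,
        shielded_residues=shielded_residues,
        absorb_isolated=absorb_isolated,
    )
    regs = regions.map_low_entropy_regions(s, labels, g, m)
    config = {
        "probe_radius": probe_radius,
        "n_points": n_points,
        "surface_threshold": surface_threshold,
        "adjacency_cutoff": adjacency_cutoff,
        "hbond_cutoff": hbond_cutoff,
        "shielded_residues": sorted(shielded_residues),
        "absorb_isolated": absorb_isolated,
    }
    return HydrationShellMap(structure=s, surface_model=m, graph=g, labels=labels, regions=regs, config=config)
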