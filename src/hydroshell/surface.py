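"""Solvent-accessible surface area and the surface-atom neighbor graph.

SASA is computed with the Shrake–Rupley method: each atom's van der Waals
sphere is inflated by the probe radius and sampled with a fixed,
deterministic golden-section spiral point set; a sample point is accessible
iff it lies outside every other atom's inflated sphere.  Per-atom SASA is
the accessible fraction times the inflated-sphere area.  No random numbers
are involved, so results are bit-stable across runs and atom orderings.

"Surface atoms" are atoms with at least ``surface_threshold`` Å² of SASA
(default 1 Å², which excludes numerically grazed buried atoms).  Patch
clustering operates on the surface neighbor graph, whose edges connect
surface atoms whose centers are within ``adjacency_cutoff`` Å (default 5 Å,
roughly one water diameter plus a bond length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, StructureError

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_SURFACE_THRESHOLD = 1.0  # Å²
DEFAULT_ADJACENCY_CUTOFF = 5.0  # Å

#: Type alias: the surface neighbor graph is a networkx Graph whose nodes
#: are atom indices into the originating Structure.
SurfaceGraph = nx.Graph


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of *n* unit vectors."""
    if n < 92:
        raise ValueError(f"n_points must be >= 92, got {n}")
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SurfaceModel:
    """Per-atom SASA plus the parameters that produced it."""

    per_atom_sasa: np.ndarray
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD

    @property
    def total_sasa(self) -> float:
        return float(self.per_atom_sasa.sum())

    @property
    def surface_atoms(self) -> frozenset[int]:
        return surface_atoms(self, self.surface_threshold)

    def config(self) -> dict:
        return {
            "probe_radius": self.probe_radius,
            "n_points": self.n_points,
            "surface_threshold": self.surface_threshold,
        }


def compute_sasa(
    s: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> SurfaceModel:
    """Shrake–Rupley per-atom solvent-accessible surface area.

    Parameters
    ----------
    s : sanitized structure with vdW radii assigned
    probe_radius : probe sphere radius in Å (1.4 = water)
    n_points : sample points per atom (>= 92); more points, finer quadrature

    Returns
    -------
    SurfaceModel with ``per_atom_sasa`` in Å², indexed like ``s.atoms``.
    """
    n = len(s)
    if n == 0:
        raise StructureError("cannot compute SASA of an empty structure")
    coords = s.coords
    radii = s.radii
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise StructureError("all atoms need a positive vdW radius (run sanitize/assign_radii)")
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    # any pair of atoms at (numerically) identical coordinates is an input error
    close = tree.query_pairs(r=1e-3)
    if close:
        i, j = sorted(close)[0]
        raise StructureError(f"atoms {s[i].serial} and {s[j].serial} have identical coordinates")

    expanded = radii + probe_radius
    max_reach = float(expanded.max())
    sasa = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        neighbors = tree.query_ball_point(coords[i], r_i + max_reach)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            r_j = expanded[j]
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > r_j * r_j
            if not accessible.any():
                break
        sasa[i] = accessible.mean() * 4.0 * np.pi * r_i * r_i
    return SurfaceModel(
        per_atom_sasa=sasa,
        probe_radius=probe_radius,
        n_points=n_points,
        surface_threshold=surface_threshold,
    )


def surface_atoms(m: SurfaceModel, surface_threshold: float = DEFAULT_SURFACE_THRESHOLD) -> frozenset[int]:
    """Atoms with per-atom SASA >= *surface_threshold* (Å²)."""
    if surface_threshold < 0:
        raise ValueError(f"surface_threshold must be >= 0, got {surface_threshold}")
    return frozenset(int(i) for i in np.nonzero(m.per_atom_sasa >= surface_threshold)[0])


def surface_neighbor_graph(
    s: Structure,
    surf: frozenset[int] | set[int],
    adjacency_cutoff: float = DEFAULT_ADJACENCY_CUTOFF,
) -> SurfaceGraph:
    """Graph on surface atoms with an edge for every center pair within the cutoff.

    Nodes are atom indices into ``s``; the cutoff is recorded as the graph
    attribute ``adjacency_cutoff``.
    """
    if adjacency_cutoff <= 0:
        raise ValueError(f"adjacency_cutoff must be > 0, got {adjacency_cutoff}")
    surf = sorted(int(i) for i in surf)
    if surf and (surf[0] < 0 or surf[-1] >= len(s)):
        raise StructureError("surface set references atoms outside the structure")
    g = nx.Graph(adjacency_cutoff=adjacency_cutoff)
    g.add_nodes_from(surf)
    if surf:
        coords = s.coords[surf]
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(r=adjacency_cutoff):
            g.add_edge(surf[a], surf[b])
    return g
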