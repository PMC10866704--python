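"""Structural metrics of an assembled network.

These quantify the architectural features that differentiate bundled
from unbundled matrices: fibre lengths (individual fibrils and
bundler-connected chains), fibre–fibre junction angles, spatial
heterogeneity of the mass distribution, and crosslink-graph
connectivity (mean degree, largest component, y-percolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    ANCHOR_NEG_Y,
    ANCHOR_POS_Y,
    KIND_BUNDLER,
    NetworkState,
    arc_to_segment,
    wrap_position,
)


@dataclass
class StructureReport:
    """Summary of network architecture."""

    fibre_lengths: list
    chain_lengths: list
    junction_angles_deg: list
    heterogeneity_cv: float
    mean_degree: float
    largest_component_fraction: float
    y_percolation: bool

    def to_dict(self) -> dict:
        return {
            "n_fibrils": len(self.fibre_lengths),
            "fibre_length_mean_um": float(np.mean(self.fibre_lengths))
            if self.fibre_lengths else math.nan,
            "chain_length_mean_um": float(np.mean(self.chain_lengths))
            if self.chain_lengths else math.nan,
            "junction_angle_mean_deg":
                float(np.mean(self.junction_angles_deg))
                if self.junction_angles_deg else math.nan,
            "heterogeneity_cv": self.heterogeneity_cv,
            "mean_degree": self.mean_degree,
            "largest_component_fraction": self.largest_component_fraction,
            "y_percolation": self.y_percolation,
        }


def fibre_lengths(state: NetworkState):
    """Contour length per fibril and per bundler-connected chain.

    Chains are connected components of the fibril graph restricted to
    permanent bundler edges; a lone fibril is a chain of one.  Returns
    ``(per_fibril, per_chain)`` lists in µm.
    """
    dom = state.domain
    per_fibril = [f.contour_length(dom) for f in state.fibrils]
    g = nx.Graph()
    g.add_nodes_from(f.id for f in state.fibrils)
    for c in state.connectors:
        if c.kind == KIND_BUNDLER:
            g.add_edge(c.fibril_a, c.fibril_b)
    by_id = {f.id: L for f, L in zip(state.fibrils, per_fibril)}
    per_chain = [sum(by_id[fid] for fid in comp)
                 for comp in nx.connected_components(g)]
    return per_fibril, per_chain


def _tangent_at(state, fibril, s):
    idx, _w = arc_to_segment(fibril, s, state.domain)
    v = fibril.segment_vectors(state.domain)[idx]
    return v / np.linalg.norm(v)


def junction_angles(state: NetworkState, kind: str | None = None):
    """Angle (degrees, folded to [0, 90]) between the local fibril tangents
    at the two attachment points of each bound connector.

    ``kind`` restricts to ``"crosslinker"`` or ``"bundler"`` connectors.
    """
    angles = []
    for c in state.connectors:
        if not c.bound:
            continue
        if kind is not None and c.kind != kind:
            continue
        ta = _tangent_at(state, state.fibril_by_id(c.fibril_a), c.s_a)
        tb = _tangent_at(state, state.fibril_by_id(c.fibril_b), c.s_b)
        cosang = abs(float(np.clip(ta @ tb, -1.0, 1.0)))
        angles.append(math.degrees(math.acos(cosang)))
    return angles


def heterogeneity(state: NetworkState, cell_size: float = 1.0) -> float:
    """Coefficient of variation of per-cell fibril mass.

    The domain is divided into cubic cells of edge ``cell_size``; each
    segment's length is assigned to the cell holding its midpoint (mass is
    proportional to length, so the CV is independent of fibril radius).
    """
    dom = state.domain
    nx_ = max(1, int(round(dom.Lx / cell_size)))
    ny_ = max(1, int(round(dom.Ly / cell_size)))
    nz_ = max(1, int(round(dom.Lz / cell_size)))
    for n_, L in ((nx_, dom.Lx), (ny_, dom.Ly), (nz_, dom.Lz)):
        if abs(n_ * cell_size - L) > 1e-6 * max(1.0, L):
            raise ValueError("cell size must divide the domain edges")
    ncells = nx_ * ny_ * nz_
    if ncells < 8:
        raise ValueError("fewer than 8 cells: choose a smaller cell size")
    mass = np.zeros(ncells)
    for f in state.fibrils:
        p = f.positions[:-1]
        v = f.segment_vectors(dom)
        mids = wrap_position(p + 0.5 * v, dom)
        lens = np.linalg.norm(v, axis=1)
        ix = np.clip((mids[:, 0] / cell_size).astype(int), 0, nx_ - 1)
        iy = np.clip((mids[:, 1] / cell_size).astype(int), 0, ny_ - 1)
        iz = np.clip((mids[:, 2] / cell_size).astype(int), 0, nz_ - 1)
        np.add.at(mass, (ix * ny_ + iy) * nz_ + iz, lens)
    mean = mass.mean()
    if mean == 0:
        return 0.0
    return float(mass.std() / mean)


def connectivity(state: NetworkState):
    """Crosslink-graph statistics: ``(mean degree, largest-component
    fraction, y-percolation)``.

    Fibrils are nodes; each bound connector (crosslinker or bundler)
    contributes an edge (parallel connectors collapse).  y-percolation is
    true when a single connected component contains fibrils anchored to
    both y-walls.
    """
    g = nx.Graph()
    g.add_nodes_from(f.id for f in state.fibrils)
    for c in state.connectors:
        if c.bound:
            g.add_edge(c.fibril_a, c.fibril_b)
    n = g.number_of_nodes()
    if n == 0:
        return 0.0, 0.0, False
    mean_degree = 2.0 * g.number_of_edges() / n
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    lo = {f.id for f in state.fibrils if np.any(f.anchored == ANCHOR_NEG_Y)}
    hi = {f.id for f in state.fibrils if np.any(f.anchored == ANCHOR_POS_Y)}
    percolates = any(comp & lo and comp & hi for comp in comps)
    return mean_degree, len(largest) / n, percolates


def structure_report(state: NetworkState,
                     cell_size: float = 1.0) -> StructureReport:
    """Convenience bundle of all structural metrics."""
    per_fibril, per_chain = fibre_lengths(state)
    deg, frac, perc = connectivity(state)
    return StructureReport(
        fibre_lengths=per_fibril,
        chain_lengths=per_chain,
        junction_angles_deg=junction_angles(state),
        heterogeneity_cv=heterogeneity(state, cell_size),
        mean_degree=deg,
        largest_component_fraction=frac,
        y_percolation=perc,
    )
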