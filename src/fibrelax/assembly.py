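"""Geometric construction of the three matrix architectures.

Assembly mimics collagen self-organization as a sequence of geometric
steps rather than kinetic simulation: seed fibrils nucleate as single
cylindrical segments at random positions, elongate by adding segments
(never depolymerizing) up to a target length (3 or 5 µm), and are then
interconnected.  Three architectures are supported:

* ``fibrillar`` — individual fibrils joined only by transient crosslinkers;
* ``tight_bundle`` — fibrils grouped into parallel, axially staggered
  bundles by permanent bundlers, plus crosslinkers within/between bundles;
* ``loose_bundle`` — fibrils of length ``L_B`` chained end-to-end by
  permanent bundlers with a fixed junction angle θ (azimuthally random).

The fibril count is the smallest number whose fully elongated mass
reaches the target concentration (3.65 mg/ml by default, via the
specific volume of collagen, 0.73 ml/g).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ANCHOR_NEG_Y,
    ANCHOR_POS_Y,
    Connector,
    Domain,
    Fibril,
    KIND_BUNDLER,
    KIND_CROSSLINKER,
    NetworkState,
    SPECIFIC_VOLUME_COLLAGEN,
    SimParams,
    concentration,
    fibril_mass_concentration,
    minimum_image,
    wrap_position,
)

log = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    """Parameters of the matrix construction.

    ``L_f`` is the fibril target length for fibrillar/tight-bundle
    matrices; loose-bundle constituents use the bundle length ``L_B``.
    ``theta_deg`` is the end-to-end bundling angle of loose bundles,
    ``chain_length`` the number of constituent fibrils per loose chain,
    ``bundle_size``/``stagger`` shape tight bundles.
    """

    matrix_type: str = "fibrillar"
    concentration: float = 3.65        # mg/ml
    L_f: float = 3.0                   # µm
    L_B: float = 3.0                   # µm
    theta_deg: float = 10.0
    bundle_size: int = 4
    stagger: float = 1.0               # µm
    chain_length: int = 4
    radius: float = 0.05               # µm
    l0: float = 0.5                    # µm
    elong_noise_deg: float = 5.0
    anchor_tol: float = 0.25           # µm
    v_sp: float = SPECIFIC_VOLUME_COLLAGEN
    max_fibrils: int = 100_000

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not (0.0 <= self.theta_deg < 90.0):
            raise ValueError("theta_deg must lie in [0, 90)")
        for name in ("L_f", "L_B", "radius", "l0", "stagger", "anchor_tol"):
            if getattr(self, name) <= 0 and name not in ("stagger", "anchor_tol"):
                raise ValueError(f"{name} must be positive")
        if self.bundle_size < 1 or self.chain_length < 1:
            raise ValueError("bundle_size and chain_length must be >= 1")

    @property
    def target_length(self) -> float:
        """Constituent fibril length for this architecture."""
        return self.L_B if self.matrix_type == "loose_bundle" else self.L_f


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _perp_unit(v: np.ndarray, rng) -> np.ndarray:
    """A uniformly random unit vector perpendicular to ``v``."""
    v = _unit(v)
    while True:
        w = rng.normal(size=3)
        w -= (w @ v) * v
        n = np.linalg.norm(w)
        if n > 1e-9:
            return w / n


def _rotate_towards(v: np.ndarray, angle: float, rng) -> np.ndarray:
    """Rotate unit vector ``v`` by ``angle`` about a random ⟂ axis."""
    if angle == 0.0:
        return _unit(v)
    u = _perp_unit(v, rng)
    return math.cos(angle) * _unit(v) + math.sin(angle) * u


def n_fibrils_for_concentration(config: AssemblyConfig, domain: Domain) -> int:
    """Smallest fibril count whose fully elongated mass reaches the target."""
    if config.concentration == 0:
        return 0
    per = fibril_mass_concentration(
        config.radius, config.target_length, domain, config.v_sp)
    n = int(math.ceil(config.concentration / per - 1e-9))
    if n > config.max_fibrils:
        raise ValueError(
            f"target concentration needs {n} fibrils "
            f"(cap {config.max_fibrils})")
    return n


def _segments_per_fibril(config: AssemblyConfig) -> int:
    n = config.target_length / config.l0
    if abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"target length {config.target_length} is not a multiple of "
            f"l0={config.l0}")
    return int(round(n))


def nucleate(config: AssemblyConfig, domain: Domain,
             rng: np.random.Generator) -> NetworkState:
    """Seed fibrils: one cylindrical segment each, random position/orientation.

    Fibrils are laid fully inside ``[0, L_y]`` along y; x/z positions are
    wrapped by periodicity.
    """
    n = n_fibrils_for_concentration(config, domain)
    fibrils = []
    for fid in range(n):
        u = _random_unit(rng)
        lo = max(0.0, -config.l0 * u[1])
        hi = min(domain.Ly, domain.Ly - config.l0 * u[1])
        y0 = rng.uniform(lo, hi)
        p0 = np.array([rng.uniform(0, domain.Lx), y0,
                       rng.uniform(0, domain.Lz)])
        p1 = p0 + config.l0 * u
        fibrils.append(Fibril(id=fid,
                              positions=wrap_position(np.array([p0, p1]),
                                                      domain),
                              radius=config.radius, l0=config.l0))
    state = NetworkState(domain=domain, fibrils=fibrils, connectors=[],
                         matrix_type=config.matrix_type,
                         meta={"n_fibrils": n})
    return state


def elongate(state: NetworkState, config: AssemblyConfig,
             rng: np.random.Generator) -> NetworkState:
    """Grow each fibril to the target contour length by appending segments.

    Each new segment follows the previous direction perturbed by Gaussian
    angular noise; growth that would cross a y-wall is reflected inward.
    Fibrils never shorten.
    """
    nseg = _segments_per_fibril(config)
    sigma = math.radians(config.elong_noise_deg)
    dom = state.domain
    for f in state.fibrils:
        if f.n_segments >= nseg:
            continue
        pos = [p.copy() for p in f.unwrapped_positions(dom)]
        while len(pos) - 1 < nseg:
            d = _unit(pos[-1] - pos[-2])
            if sigma > 0:
                d = _rotate_towards(d, rng.normal(0.0, sigma), rng)
            # reflect the growth direction off a y-wall so every segment
            # keeps its full rest length (clipping would shorten contour)
            if pos[-1][1] + config.l0 * d[1] < 0:
                d[1] = abs(d[1])
            elif pos[-1][1] + config.l0 * d[1] > dom.Ly:
                d[1] = -abs(d[1])
            pos.append(pos[-1] + config.l0 * d)
        f.positions = wrap_position(np.array(pos), dom)
        f.anchored = np.zeros(len(pos), dtype=np.int8)
    return state


def _chain_offset_in_y(rel: np.ndarray, Ly: float, rng, tries_left: int):
    """y-offset placing a relative bead chain inside [0, Ly], or None."""
    ymin = rel[:, 1].min()
    ymax = rel[:, 1].max()
    if ymax - ymin > Ly:
        return None
    return rng.uniform(-ymin, Ly - ymax)


def build_tight_bundles(state: NetworkState, config: AssemblyConfig,
                        rng: np.random.Generator) -> NetworkState:
    """Group fibrils into parallel, axially staggered tight bundles.

    Members are rebuilt as straight fibrils sharing a bundle axis, offset
    laterally by ≈2·r_f and axially by the stagger; permanent bundlers tie
    consecutive members at regular arc intervals along their overlap.
    """
    if state.matrix_type != "tight_bundle":
        raise ValueError("state is not a tight_bundle matrix")
    m = config.bundle_size
    if m > len(state.fibrils):
        raise ValueError("bundle size exceeds available fibrils")
    if m == 1:
        return state
    dom = state.domain
    nseg = _segments_per_fibril(config)
    L = nseg * config.l0
    g = config.stagger
    # lateral ring radius giving neighbour spacing ~2 r_f
    R = config.radius if m == 2 else config.radius / math.sin(math.pi / m)
    ids = [f.id for f in state.fibrils]
    for start in range(0, len(ids) - m + 1, m):
        members = state.fibrils[start:start + m]
        for _try in range(200):
            u = _random_unit(rng)
            e1 = _perp_unit(u, rng)
            e2 = np.cross(u, e1)
            phase = rng.uniform(0, 2 * math.pi)
            offsets = [
                R * (math.cos(phase + 2 * math.pi * j / m) * e1
                     + math.sin(phase + 2 * math.pi * j / m) * e2)
                for j in range(m)
            ]
            rel = np.concatenate([
                offsets[j] + (j * g) * u
                + np.outer(np.arange(nseg + 1) * config.l0, u)
                for j in range(m)
            ])
            y0 = _chain_offset_in_y(rel, dom.Ly, rng, 200 - _try)
            if y0 is not None:
                break
        else:
            raise ValueError("could not fit tight bundle inside the domain")
        origin = np.array([rng.uniform(0, dom.Lx), y0,
                           rng.uniform(0, dom.Lz)])
        nb = nseg + 1
        for j, f in enumerate(members):
            f.positions = wrap_position(rel[j * nb:(j + 1) * nb] + origin, dom)
            f.anchored = np.zeros(nb, dtype=np.int8)
        # permanent bundlers between consecutive members along the overlap
        for j in range(m - 1):
            a_lo = (j + 1) * g
            a_hi = j * g + L
            a = a_lo
            while a <= a_hi + 1e-9:
                s_j = min(max(a - j * g, 0.0), L)
                s_k = min(max(a - (j + 1) * g, 0.0), L)
                rest = float(np.linalg.norm(offsets[j] - offsets[j + 1]))
                state.connectors.append(Connector(
                    kind=KIND_BUNDLER,
                    fibril_a=members[j].id, s_a=s_j,
                    fibril_b=members[j + 1].id, s_b=s_k,
                    rest_length=rest))
                a += config.l0
    return state


def build_loose_bundles(state: NetworkState, config: AssemblyConfig,
                        rng: np.random.Generator) -> NetworkState:
    """Chain fibrils end-to-end with a fixed junction angle θ.

    Consecutive constituent fibrils share an endpoint (permanent bundler,
    rest length 0); the initial tangent of each next fibril is the final
    tangent of the previous one rotated by exactly θ about a random
    perpendicular axis.
    """
    if state.matrix_type != "loose_bundle":
        raise ValueError("state is not a loose_bundle matrix")
    theta = math.radians(config.theta_deg)
    dom = state.domain
    nseg = _segments_per_fibril(config)
    n = len(state.fibrils)
    c = config.chain_length
    for start in range(0, n, c):
        members = state.fibrils[start:start + c]
        for _try in range(500):
            d = _random_unit(rng)
            dirs = [d]
            for _ in range(len(members) - 1):
                dirs.append(_rotate_towards(dirs[-1], theta, rng))
            pts = [np.zeros(3)]
            for dj in dirs:
                for _s in range(nseg):
                    pts.append(pts[-1] + config.l0 * dj)
            rel = np.array(pts)
            y0 = _chain_offset_in_y(rel, dom.Ly, rng, 500 - _try)
            if y0 is not None:
                break
        else:
            raise ValueError("could not fit loose-bundle chain inside domain")
        origin = np.array([rng.uniform(0, dom.Lx), y0,
                           rng.uniform(0, dom.Lz)])
        for j, f in enumerate(members):
            beads = rel[j * nseg: (j + 1) * nseg + 1] + origin
            f.positions = wrap_position(beads, dom)
            f.anchored = np.zeros(nseg + 1, dtype=np.int8)
        L = nseg * config.l0
        for j in range(len(members) - 1):
            state.connectors.append(Connector(
                kind=KIND_BUNDLER,
                fibril_a=members[j].id, s_a=L,
                fibril_b=members[j + 1].id, s_b=0.0,
                rest_length=0.0))
    return state


def place_crosslinkers(state: NetworkState, params: SimParams,
                       rng: np.random.Generator) -> NetworkState:
    """Scatter transient crosslinkers between nearby fibril points.

    Candidate attachment points are sampled uniformly along arc length at
    ``params.crosslinker_density`` per µm (Poisson count per fibril).  Each
    candidate binds to a partner fibril drawn uniformly among all *other*
    fibrils whose nearest point lies within the capture radius, attaching
    at that nearest point with rest length equal to the separation (a
    strict nearest-fibril rule would almost never connect distinct tight
    bundles, whose members are each other's closest neighbours).  The
    inter-fibril angle never influences acceptance.
    """
    dom = state.domain
    # flat segment tables
    starts, vecs, fibs = [], [], []
    for f in state.fibrils:
        p = f.positions
        v = f.segment_vectors(dom)
        starts.append(p[:-1])
        vecs.append(v)
        fibs.append(np.full(v.shape[0], f.id))
    if not starts:
        return state
    starts = np.concatenate(starts)
    vecs = np.concatenate(vecs)
    fibs = np.concatenate(fibs)
    vv = np.einsum("ij,ij->i", vecs, vecs)
    vv[vv < 1e-24] = 1e-24
    seg_offset = {}
    off = 0
    for f in state.fibrils:
        seg_offset[f.id] = off
        off += f.n_segments
    id_max = max(f.id for f in state.fibrils)
    from .core import point_on_fibril
    n_placed = 0
    for f in state.fibrils:
        L = f.contour_length(dom)
        count = rng.poisson(params.crosslinker_density * L)
        if count == 0:
            continue
        ss = np.sort(rng.uniform(0.0, L, size=count))
        for s in ss:
            p = wrap_position(point_on_fibril(f, float(s), dom), dom)
            d0 = minimum_image(p, starts, dom)
            # t minimises |d0 + t v|  =>  t = -(d0·v)/(v·v), clipped to [0,1]
            t = np.clip(-np.einsum("ij,ij->i", d0, vecs) / vv, 0.0, 1.0)
            diff = d0 + t[:, None] * vecs
            dist2 = np.einsum("ij,ij->i", diff, diff)
            dist2[fibs == f.id] = np.inf
            # nearest point per candidate fibril, then uniform fibril choice
            fib_min = np.full(id_max + 1, np.inf)
            np.minimum.at(fib_min, fibs, dist2)
            in_range = np.nonzero(
                fib_min <= params.capture_radius**2)[0]
            if len(in_range) == 0:
                continue
            chosen = int(in_range[rng.integers(len(in_range))])
            cand = np.nonzero(fibs == chosen)[0]
            k = int(cand[np.argmin(dist2[cand])])
            dist = math.sqrt(dist2[k])
            other = state.fibril_by_id(chosen)
            seg_local = k - seg_offset[other.id]
            seglen = other.segment_lengths(dom)
            s_other = float(seglen[:seg_local].sum()
                            + t[k] * seglen[seg_local])
            state.connectors.append(Connector(
                kind=KIND_CROSSLINKER,
                fibril_a=f.id, s_a=float(s),
                fibril_b=other.id, s_b=s_other,
                rest_length=dist))
            n_placed += 1
    if n_placed == 0:
        log.warning("no crosslinkers placed (sparse network?)")
    state.meta["n_crosslinkers"] = n_placed
    return state


def anchor_boundaries(state: NetworkState, tol: float = 0.25) -> NetworkState:
    """Permanently bind beads within ``tol`` of the y-walls to those walls."""
    dom = state.domain
    n_lo = n_hi = 0
    for f in state.fibrils:
        flags = np.zeros(f.n_beads, dtype=np.int8)
        flags[f.positions[:, 1] <= tol] = ANCHOR_NEG_Y
        flags[f.positions[:, 1] >= dom.Ly - tol] = ANCHOR_POS_Y
        f.anchored = flags
        n_lo += int((flags == ANCHOR_NEG_Y).sum())
        n_hi += int((flags == ANCHOR_POS_Y).sum())
    state.meta["n_anchors"] = {"neg_y": n_lo, "pos_y": n_hi}
    if n_lo == 0 or n_hi == 0:
        log.warning("boundary without anchors: state marked non-loadable")
    return state


def assemble(config: AssemblyConfig, domain: Domain, params: SimParams,
             seed) -> NetworkState:
    """Full pipeline: nucleate → elongate → bundle → crosslink → anchor."""
    rng = np.random.default_rng(seed)
    state = nucleate(config, domain, rng)
    state = elongate(state, config, rng)
    if config.matrix_type == "tight_bundle":
        state = build_tight_bundles(state, config, rng)
    elif config.matrix_type == "loose_bundle":
        state = build_loose_bundles(state, config, rng)
    state = place_crosslinkers(state, params, rng)
    state = anchor_boundaries(state, config.anchor_tol)
    state.meta.update({
        "seed": int(seed) if np.isscalar(seed) else str(seed),
        "config": {k: (v if not isinstance(v, float) or math.isfinite(v)
                       else str(v))
                   for k, v in vars(config).items()},
        "concentration_mg_ml": concentration(state, config.v_sp),
    })
    log.info(
        "assembled %s: %d fibrils, %d connectors, %.3f mg/ml",
        config.matrix_type, len(state.fibrils), len(state.connectors),
        state.meta["concentration_mg_ml"])
    return state
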