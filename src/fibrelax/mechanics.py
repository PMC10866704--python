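"""Force field, overdamped Langevin dynamics, and Bell's-law bond kinetics.

The deterministic force field has three harmonic terms:

* segment stretching  ``E = 1/2 κ_s (l − l0)²``
* angular bending at interior beads  ``E = 1/2 κ_b φ²``
* connector springs  ``E = 1/2 κ_c (d − l_c)²`` (bound connectors only)

Bead motion follows the overdamped (inertialess) Langevin equation
integrated with an explicit Euler scheme:
``Δr = (F/ζ)Δt + √(2 k_BT Δt/ζ) ξ``, ξ standard normal per axis.

Crosslinkers unbind at the force-dependent Bell rate
``k = k₀ exp(F λ / k_BT)`` and may rebind to the nearest fibril point
within the capture radius; bundlers are permanent.

The module exposes both a convenient :class:`~fibrelax.core.NetworkState`
level API and a packed-array fast path (:class:`PackedState`) used for
long trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (
    KIND_CROSSLINKER,
    NetworkState,
    SimParams,
    arc_to_segment,
)


@dataclass
class PackedState:
    """Flat array view of a :class:`NetworkState` consumed by the kernels."""

    pos: np.ndarray
    anchored: np.ndarray
    base_x: np.ndarray
    fib_of_bead: np.ndarray
    bead_start: np.ndarray  # (n_fibrils+1,) offsets into pos
    seg_i: np.ndarray
    seg_j: np.ndarray
    seg_l0: np.ndarray
    seg_fib: np.ndarray
    trip: np.ndarray
    c_kind: np.ndarray
    c_bound: np.ndarray
    c_b1: np.ndarray
    c_w1: np.ndarray
    c_b2: np.ndarray
    c_w2: np.ndarray
    c_rest: np.ndarray
    c_fib1: np.ndarray
    c_fib2: np.ndarray
    Lx: float
    Ly: float
    Lz: float
    perx: bool
    perz: bool
    fibril_ids: list

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]


def pack_state(state: NetworkState) -> PackedState:
    """Flatten fibrils and connectors into contiguous kernel arrays.

    Connector arc coordinates are converted once to (segment, weight)
    pairs; from then on attachments ride with the material (Lagrangian).
    """
    dom = state.domain
    nf = len(state.fibrils)
    bead_start = np.zeros(nf + 1, dtype=np.int64)
    for q, f in enumerate(state.fibrils):
        bead_start[q + 1] = bead_start[q] + f.n_beads
    n = int(bead_start[-1])
    pos = np.empty((n, 3))
    anchored = np.zeros(n, dtype=np.int8)
    fib_of_bead = np.empty(n, dtype=np.int64)
    segs_i, segs_j, segs_l0, segs_fib = [], [], [], []
    trips = []
    fid_to_q = {}
    for q, f in enumerate(state.fibrils):
        o = int(bead_start[q])
        pos[o:o + f.n_beads] = f.positions
        anchored[o:o + f.n_beads] = f.anchored
        fib_of_bead[o:o + f.n_beads] = q
        fid_to_q[f.id] = q
        for s in range(f.n_segments):
            segs_i.append(o + s)
            segs_j.append(o + s + 1)
            segs_l0.append(f.l0)
            segs_fib.append(q)
        for b in range(1, f.n_beads - 1):
            trips.append((o + b - 1, o + b, o + b + 1))
    nc = len(state.connectors)
    c_kind = np.zeros(nc, dtype=np.uint8)
    c_bound = np.zeros(nc, dtype=np.uint8)
    c_b1 = np.zeros(nc, dtype=np.int64)
    c_w1 = np.zeros(nc)
    c_b2 = np.zeros(nc, dtype=np.int64)
    c_w2 = np.zeros(nc)
    c_rest = np.zeros(nc)
    c_fib1 = np.zeros(nc, dtype=np.int64)
    c_fib2 = np.zeros(nc, dtype=np.int64)
    for k, c in enumerate(state.connectors):
        c_kind[k] = 0 if c.kind == KIND_CROSSLINKER else 1
        c_bound[k] = 1 if c.bound else 0
        qa = fid_to_q[c.fibril_a]
        qb = fid_to_q[c.fibril_b]
        fa = state.fibrils[qa]
        fb = state.fibrils[qb]
        sa, wa = arc_to_segment(fa, c.s_a, dom)
        sb, wb = arc_to_segment(fb, c.s_b, dom)
        c_b1[k] = bead_start[qa] + sa
        c_w1[k] = wa
        c_b2[k] = bead_start[qb] + sb
        c_w2[k] = wb
        c_rest[k] = c.rest_length
        c_fib1[k] = qa
        c_fib2[k] = qb
    base_x = pos[:, 0].copy()
    return PackedState(
        pos=pos, anchored=anchored, base_x=base_x,
        fib_of_bead=fib_of_bead, bead_start=bead_start,
        seg_i=np.asarray(segs_i, dtype=np.int64),
        seg_j=np.asarray(segs_j, dtype=np.int64),
        seg_l0=np.asarray(segs_l0, dtype=float),
        seg_fib=np.asarray(segs_fib, dtype=np.int64),
        trip=(np.asarray(trips, dtype=np.int64).reshape(-1, 3)
              if trips else np.zeros((0, 3), dtype=np.int64)),
        c_kind=c_kind, c_bound=c_bound,
        c_b1=c_b1, c_w1=c_w1, c_b2=c_b2, c_w2=c_w2, c_rest=c_rest,
        c_fib1=c_fib1, c_fib2=c_fib2,
        Lx=dom.Lx, Ly=dom.Ly, Lz=dom.Lz,
        perx=dom.periodic_x, perz=dom.periodic_z,
        fibril_ids=[f.id for f in state.fibrils],
    )


def unpack_state(ps: PackedState, state: NetworkState) -> NetworkState:
    """Write packed positions and connector status back into ``state``."""
    for q, f in enumerate(state.fibrils):
        o = int(ps.bead_start[q])
        f.positions[:] = ps.pos[o:o + f.n_beads]
    for k, c in enumerate(state.connectors):
        c.bound = bool(ps.c_bound[k])
        q2 = int(ps.c_fib2[k])
        f2 = state.fibrils[q2]
        c.fibril_b = f2.id
        local = int(ps.c_b2[k] - ps.bead_start[q2])
        c.s_b = float(min(
            (local + ps.c_w2[k]) * f2.l0, f2.n_segments * f2.l0))
        c.rest_length = float(ps.c_rest[k])
    return state


# --------------------------------------------------------------- forces

def compute_forces(ps: PackedState, params: SimParams):
    """Per-bead force array (pN) and per-connector signed tensions (pN)."""
    F = np.zeros((ps.n_beads, 3))
    tension = np.zeros(ps.c_kind.shape[0])
    _kernels.compute_forces(
        ps.pos, ps.anchored, ps.seg_i, ps.seg_j, ps.seg_l0, ps.trip,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2, ps.c_rest,
        params.kappa_s, params.kappa_b, params.kappa_c,
        ps.Lx, ps.Lz, ps.perx, ps.perz, F, tension)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite force encountered")
    return F, tension


def total_energy(ps: PackedState, params: SimParams) -> float:
    """Total elastic energy (pN·µm) of the configuration."""
    return float(_kernels.total_energy(
        ps.pos, ps.seg_i, ps.seg_j, ps.seg_l0, ps.trip,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2, ps.c_rest,
        params.kappa_s, params.kappa_b, params.kappa_c,
        ps.Lx, ps.Lz, ps.perx, ps.perz))


def _component_forces(state, params, *, kappa_s=0.0, kappa_b=0.0, kappa_c=0.0):
    ps = state if isinstance(state, PackedState) else pack_state(state)
    F = np.zeros((ps.n_beads, 3))
    tension = np.zeros(ps.c_kind.shape[0])
    _kernels.compute_forces(
        ps.pos, ps.anchored, ps.seg_i, ps.seg_j, ps.seg_l0, ps.trip,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2, ps.c_rest,
        kappa_s, kappa_b, kappa_c, ps.Lx, ps.Lz, ps.perx, ps.perz,
        F, tension)
    return F, tension


def stretching_forces(state, params: SimParams):
    """Axial segment spring forces only (per-bead array)."""
    ps = state if isinstance(state, PackedState) else pack_state(state)
    if np.any(np.linalg.norm(
            ps.pos[ps.seg_j] - ps.pos[ps.seg_i], axis=1) < 1e-12):
        raise ValueError("zero-length segment: corrupt state")
    return _component_forces(state, params, kappa_s=params.kappa_s)[0]


def bending_forces(state, params: SimParams):
    """Angular spring forces restoring fibril collinearity."""
    return _component_forces(state, params, kappa_b=params.kappa_b)[0]


def connector_forces(state, params: SimParams):
    """Connector spring forces and signed tensions ``(F, tension)``."""
    return _component_forces(state, params, kappa_c=params.kappa_c)


# --------------------------------------------------------------- dynamics

def thermal_displacement(
    params: SimParams, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Gaussian thermal step, shape ``(n, 3)``, s.d. √(2 k_BT Δt/ζ) per axis."""
    sd = params.thermal_step_sd
    if sd == 0.0:
        return np.zeros((n, 3))
    return rng.normal(0.0, sd, size=(n, 3))


def euler_step(state, params: SimParams, rng: np.random.Generator,
               gamma: float = 0.0):
    """Advance the system one time step.

    Free beads move by ``(F/ζ)Δt`` plus the thermal displacement and are
    re-wrapped along x/z; −y anchors are fixed; +y anchors sit at the shear
    position ``base_x + gamma·L_y``.  Returns the (mutated) input.
    """
    ps = state if isinstance(state, PackedState) else pack_state(state)
    times = np.zeros(2)
    stress = np.zeros(2)
    nbound = np.zeros(2, dtype=np.int64)
    ns = _kernels.run_sim(
        ps.pos, ps.anchored, ps.base_x,
        ps.seg_i, ps.seg_j, ps.seg_l0, ps.seg_fib, ps.trip,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2,
        ps.c_rest, ps.c_fib1, ps.c_fib2,
        params.kappa_s, params.kappa_b, params.kappa_c,
        params.zeta, params.kBT, params.effective_kBT_mech, params.dt,
        params.k0, params.bell_lambda, params.capture_radius,
        0, 0.0, 0,  # kinetics disabled within a bare Euler step
        1, 0, 0, 0, gamma, ps.Ly,
        ps.Lx, ps.Lz, ps.perx, ps.perz,
        1, 0, -1.0, times, stress, nbound, rng)
    if ns < 0:
        raise FloatingPointError("non-finite force: aborting (state dumped)")
    if not isinstance(state, PackedState):
        unpack_state(ps, state)
    return state


def bell_rate(tension: float, params: SimParams) -> float:
    """Bell's-law unbinding rate ``k0·exp(|F|·λ/k_BT)`` (1/s)."""
    if params.k0 == 0:
        return 0.0
    if params.kBT <= 0:
        return params.k0 if tension == 0 else math.inf
    expo = min(abs(tension) * params.bell_lambda / params.kBT, 50.0)
    return params.k0 * math.exp(expo)


def _kinetics(state, params, rng, do_unbind, do_rebind):
    ps = state if isinstance(state, PackedState) else pack_state(state)
    _, tension = compute_forces(ps, params)
    _kernels.kinetics_step(
        ps.pos, ps.seg_i, ps.seg_j, ps.seg_fib,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2,
        ps.c_rest, ps.c_fib1, ps.c_fib2, tension,
        params.k0, params.bell_lambda, params.kBT,
        1 if params.rebinding_enabled else 0, params.rebind_rate,
        params.capture_radius, params.dt,
        ps.Lx, ps.Lz, ps.perx, ps.perz,
        do_unbind, do_rebind, rng)
    if not isinstance(state, PackedState):
        unpack_state(ps, state)
    return state


def bell_unbinding_step(state, params: SimParams, rng: np.random.Generator):
    """Stochastically unbind loaded crosslinkers over one Δt (Bell's law)."""
    return _kinetics(state, params, rng, 1, 0)


def rebinding_step(state, params: SimParams, rng: np.random.Generator):
    """Rebind unbound crosslinkers within capture range over one Δt."""
    return _kinetics(state, params, rng, 0, 1)
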