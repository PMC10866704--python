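"""Core geometry, unit conventions, and shared state containers.

Unit system: lengths in µm, time in s, force in pN, energy in pN·µm.
With these units a stress of 1 pN/µm² equals exactly 1 Pa, so boundary
stresses are reported in Pa with no conversion factor.

The simulation box spans ``[0, L)`` on each axis.  Periodic images exist
only along x and z; the two boundaries normal to y are physical walls to
which fibrils are anchored (−y wall at ``y = 0``, +y wall at ``y = L_y``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

KIND_CROSSLINKER = "crosslinker"
KIND_BUNDLER = "bundler"

#: Boltzmann energy at 310 K in pN·µm.
KBT_310K = 4.28e-3

#: Specific volume of collagen, ml/g.
SPECIFIC_VOLUME_COLLAGEN = 0.73


@dataclass
class Domain:
    """Rectangular simulation box, periodic along x and z only."""

    Lx: float = 20.0
    Ly: float = 20.0
    Lz: float = 5.0
    periodic_x: bool = True
    periodic_z: bool = True

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError("domain edge lengths must be positive")

    @property
    def volume(self) -> float:
        """Box volume in µm³."""
        return self.Lx * self.Ly * self.Lz


def wrap_position(p: np.ndarray, domain: Domain) -> np.ndarray:
    """Fold the x and z coordinates of ``p`` into ``[0, L)``; y is untouched.

    Accepts a single 3-vector or an ``(n, 3)`` array.
    """
    q = np.array(p, dtype=float, copy=True)
    if domain.periodic_x:
        q[..., 0] %= domain.Lx
        # float mod of a tiny negative can round up to exactly L
        q[..., 0] = np.where(q[..., 0] >= domain.Lx, 0.0, q[..., 0])
    if domain.periodic_z:
        q[..., 2] %= domain.Lz
        q[..., 2] = np.where(q[..., 2] >= domain.Lz, 0.0, q[..., 2])
    return q


def minimum_image(a: np.ndarray, b: np.ndarray, domain: Domain) -> np.ndarray:
    """Displacement ``b - a`` with x/z components mapped to ``(-L/2, L/2]``.

    The y component is returned raw (y is never periodic).
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = np.array(d, copy=True)
    if domain.periodic_x:
        d[..., 0] -= domain.Lx * np.ceil(d[..., 0] / domain.Lx - 0.5)
    if domain.periodic_z:
        d[..., 2] -= domain.Lz * np.ceil(d[..., 2] / domain.Lz - 0.5)
    return d


# anchored-flag encoding shared with the packed representation
ANCHOR_NONE = 0
ANCHOR_NEG_Y = 1
ANCHOR_POS_Y = 2


@dataclass
class Fibril:
    """A collagen fibril discretized as a chain of beads joined by segments.

    ``positions`` has shape ``(n_beads, 3)``.  ``anchored`` holds one flag
    per bead (0 free, 1 bound to the −y wall, 2 bound to the +y wall).
    Consecutive beads sit one segment rest length ``l0`` apart at assembly
    time (target lengths must be whole multiples of ``l0``).
    """

    id: int
    positions: np.ndarray
    radius: float = 0.05
    l0: float = 0.5
    anchored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.positions.shape[0] < 2:
            raise ValueError("a fibril needs at least 2 beads (one segment)")
        if self.radius <= 0 or self.l0 <= 0:
            raise ValueError("radius and l0 must be positive")
        if self.anchored is None:
            self.anchored = np.zeros(self.positions.shape[0], dtype=np.int8)
        else:
            self.anchored = np.asarray(self.anchored, dtype=np.int8)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_segments(self) -> int:
        return self.n_beads - 1

    def segment_vectors(self, domain: Optional[Domain] = None) -> np.ndarray:
        """Bead-to-bead vectors, minimum-image if a domain is given."""
        if domain is None:
            return np.diff(self.positions, axis=0)
        return minimum_image(self.positions[:-1], self.positions[1:], domain)

    def segment_lengths(self, domain: Optional[Domain] = None) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(domain), axis=1)

    def contour_length(self, domain: Optional[Domain] = None) -> float:
        return float(self.segment_lengths(domain).sum())

    def unwrapped_positions(self, domain: Optional[Domain] = None) -> np.ndarray:
        """Contiguous bead chain rebuilt from minimum-image increments."""
        if domain is None:
            return self.positions
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        out[1:] = self.positions[0] + np.cumsum(
            self.segment_vectors(domain), axis=0
        )
        return out


def point_on_fibril(
    f: Fibril, s: float, domain: Optional[Domain] = None
) -> np.ndarray:
    """Point at arc-length coordinate ``s`` along the bead chain.

    ``s = 0`` is the first bead, ``s = contour length`` the last; linear
    interpolation inside each segment.  Out-of-range ``s`` is rejected.
    """
    pos = f.unwrapped_positions(domain)
    seglen = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    total = seglen.sum()
    if not (-1e-9 <= s <= total + 1e-9):
        raise ValueError(f"arc coordinate s={s} outside [0, {total}]")
    s = min(max(s, 0.0), total)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = int(np.searchsorted(cum, s, side="right") - 1)
    idx = min(idx, len(seglen) - 1)
    w = (s - cum[idx]) / seglen[idx] if seglen[idx] > 0 else 0.0
    return pos[idx] + w * (pos[idx + 1] - pos[idx])


def arc_to_segment(f: Fibril, s: float, domain: Optional[Domain] = None):
    """Map arc coordinate ``s`` to ``(local segment index, weight in [0,1])``.

    The arc coordinate is a *material* (rest-length) coordinate: segments
    are ``l0`` long regardless of their instantaneous strain, so an
    attachment keeps riding the same material point while the network
    deforms.  ``domain`` is accepted for signature symmetry but unused.
    """
    total = f.n_segments * f.l0
    if not (-1e-9 <= s <= total + 1e-9):
        raise ValueError(f"arc coordinate s={s} outside [0, {total}]")
    s = min(max(s, 0.0), total)
    idx = min(int(s / f.l0), f.n_segments - 1)
    w = s / f.l0 - idx
    return idx, float(min(max(w, 0.0), 1.0))


@dataclass
class Connector:
    """Crosslinker or bundler joining two attachment points on distinct fibrils.

    Attachments are (fibril id, arc-length coordinate) pairs.  Bundlers are
    permanent; crosslinkers can unbind (``bound=False`` ⇒ no force) and,
    if rebinding is enabled, re-attach elsewhere.
    """

    kind: str
    fibril_a: int
    s_a: float
    fibril_b: int
    s_b: float
    rest_length: float
    bound: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (KIND_CROSSLINKER, KIND_BUNDLER):
            raise ValueError(f"unknown connector kind {self.kind!r}")
        if self.fibril_a == self.fibril_b:
            raise ValueError("connector attachments must reference distinct fibrils")
        if self.rest_length < 0:
            raise ValueError("rest length must be non-negative")


@dataclass
class SimParams:
    """Mechanics, kinetics, thermal and integration constants.

    Parameters
    ----------
    kappa_s : segment stretching stiffness, pN/µm.
    kappa_b : bending stiffness, pN·µm per rad².
    kappa_c : connector spring stiffness, pN/µm.
    k0 : unloaded crosslinker unbinding rate, 1/s.
    bell_lambda : Bell mechanical sensitivity length, µm.
    kBT : thermal energy, pN·µm; sets the Bell force scale kBT/λ
        (0 = athermal bond kinetics).
    kBT_mech : thermal energy driving bead Langevin noise; ``None`` means
        "same as kBT".  The coarse bead-spring discretization is orders of
        magnitude softer than a real collagen fibril, so fully thermal bead
        motion exaggerates entropic creep; rheology protocols therefore
        default to athermal bead dynamics (kBT_mech = 0) while Bell
        kinetics keep the molecular thermal energy.
    zeta : drag coefficient per bead, pN·s/µm.
    dt : integration time step, s; must satisfy the stability bound
        dt ≤ 0.25·zeta/max(kappa_s, kappa_c).
    capture_radius : maximum attachment distance for connector placement, µm.
    crosslinker_density : mean crosslink attachment candidates per µm of fibril.
    rebinding_enabled / rebind_rate : transient-bond rebinding (1/s).
    kinetics_stride : bind/unbind kinetics are evaluated every this many
        Euler steps during long runs (kinetic timestep = stride·dt).
    """

    kappa_s: float = 20.0
    kappa_b: float = 2.0
    kappa_c: float = 5.0
    k0: float = 0.1
    bell_lambda: float = 0.01
    kBT: float = KBT_310K
    kBT_mech: Optional[float] = None
    zeta: float = 0.01
    dt: float = 1e-4
    capture_radius: float = 1.5
    crosslinker_density: float = 4.0
    rebinding_enabled: bool = True
    rebind_rate: float = 1.0
    kinetics_stride: int = 50

    def __post_init__(self) -> None:
        for name in ("kappa_s", "kappa_b", "kappa_c", "bell_lambda", "zeta",
                     "dt", "capture_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k0", "kBT", "rebind_rate", "crosslinker_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kBT_mech is not None and self.kBT_mech < 0:
            raise ValueError("kBT_mech must be non-negative")
        if self.kinetics_stride < 1:
            raise ValueError("kinetics_stride must be >= 1")
        kmax = max(self.kappa_s, self.kappa_c)
        bound = 0.25 * self.zeta / kmax
        if self.dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} violates the stability bound "
                f"dt <= 0.1*zeta/kappa_max = {bound:g}"
            )

    @property
    def effective_kBT_mech(self) -> float:
        """Thermal energy driving bead noise (defaults to ``kBT``)."""
        return self.kBT if self.kBT_mech is None else self.kBT_mech

    @property
    def thermal_step_sd(self) -> float:
        """Per-axis s.d. of the thermal displacement per step, µm."""
        return math.sqrt(2.0 * self.effective_kBT_mech * self.dt / self.zeta)


MATRIX_TYPES = ("fibrillar", "tight_bundle", "loose_bundle")


@dataclass
class NetworkState:
    """An assembled matrix: fibrils, connectors, anchors, and its domain."""

    domain: Domain
    fibrils: list
    connectors: list
    matrix_type: str = "fibrillar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix_type not in MATRIX_TYPES:
            raise ValueError(f"unknown matrix type {self.matrix_type!r}")

    def fibril_by_id(self, fid: int) -> Fibril:
        return self._index()[fid]

    def _index(self) -> dict:
        idx = getattr(self, "_fid_index", None)
        if idx is None or len(idx) != len(self.fibrils):
            idx = {f.id: f for f in self.fibrils}
            self._fid_index = idx
        return idx

    def validate(self) -> None:
        """Check connector attachments against fibril contour lengths."""
        idx = self._index()
        for c in self.connectors:
            for fid, s in ((c.fibril_a, c.s_a), (c.fibril_b, c.s_b)):
                if fid not in idx:
                    raise ValueError(f"connector references missing fibril {fid}")
                L = idx[fid].contour_length(self.domain)
                if not (-1e-6 <= s <= L + 1e-6):
                    raise ValueError(
                        f"arc coordinate {s} outside fibril {fid} (length {L})"
                    )

    @property
    def loadable(self) -> bool:
        """True when both y-walls hold at least one anchored bead."""
        has_lo = has_hi = False
        for f in self.fibrils:
            if np.any(f.anchored == ANCHOR_NEG_Y):
                has_lo = True
            if np.any(f.anchored == ANCHOR_POS_Y):
                has_hi = True
        return has_lo and has_hi

    # ---------------------------------------------------------------- I/O

    def save(self, prefix) -> None:
        """Write ``<prefix>.json`` (metadata + connectors) and
        ``<prefix>.beads.csv`` (columnar bead table)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "fibrelax-state-v1",
            "domain": {
                "Lx": self.domain.Lx, "Ly": self.domain.Ly, "Lz": self.domain.Lz,
                "periodic_x": self.domain.periodic_x,
                "periodic_z": self.domain.periodic_z,
            },
            "matrix_type": self.matrix_type,
            "meta": self.meta,
            "fibrils": [
                {"id": f.id, "radius": f.radius, "l0": f.l0}
                for f in self.fibrils
            ],
            "connectors": [
                {
                    "kind": c.kind,
                    "fibril_a": c.fibril_a, "s_a": c.s_a,
                    "fibril_b": c.fibril_b, "s_b": c.s_b,
                    "rest_length": c.rest_length, "bound": c.bound,
                }
                for c in self.connectors
            ],
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        rows = []
        for f in self.fibrils:
            for b in range(f.n_beads):
                rows.append(
                    (f.id, b, f.positions[b, 0], f.positions[b, 1],
                     f.positions[b, 2], int(f.anchored[b]))
                )
        df = pd.DataFrame(
            rows, columns=["fibril_id", "bead", "x", "y", "z", "anchored"]
        )
        df.to_csv(
            str(prefix) + ".beads.csv", index=False, float_format="%.17g"
        )


def load_state(prefix) -> NetworkState:
    """Round-trip loader for :meth:`NetworkState.save` output."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    dom = Domain(**meta["domain"])
    beads = pd.read_csv(str(prefix) + ".beads.csv")
    fibrils = []
    for rec in meta["fibrils"]:
        sub = beads[beads["fibril_id"] == rec["id"]].sort_values("bead")
        fibrils.append(
            Fibril(
                id=rec["id"],
                positions=sub[["x", "y", "z"]].to_numpy(),
                radius=rec["radius"],
                l0=rec["l0"],
                anchored=sub["anchored"].to_numpy(),
            )
        )
    connectors = [Connector(**rec) for rec in meta["connectors"]]
    return NetworkState(
        domain=dom,
        fibrils=fibrils,
        connectors=connectors,
        matrix_type=meta["matrix_type"],
        meta=meta["meta"],
    )


def concentration(
    state: NetworkState, v_sp: float = SPECIFIC_VOLUME_COLLAGEN
) -> float:
    """Effective collagen concentration of the state, mg/ml.

    Each fibril contributes a cylinder volume π·r²·L; dividing by the
    specific volume of collagen (default 0.73 ml/g) converts occupied
    volume to mass, and dividing by the box volume gives a concentration.
    The µm³→ml conversion cancels in the volume ratio.
    """
    vol = 0.0
    for f in state.fibrils:
        vol += math.pi * f.radius**2 * f.contour_length(state.domain)
    g_per_ml = (vol / state.domain.volume) / v_sp
    return 1000.0 * g_per_ml


def fibril_mass_concentration(
    radius: float, length: float, domain: Domain,
    v_sp: float = SPECIFIC_VOLUME_COLLAGEN,
) -> float:
    """Concentration contribution (mg/ml) of a single fibril of given size."""
    vol = math.pi * radius**2 * length
    return 1000.0 * (vol / domain.volume) / v_sp
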