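"""Shear stress-relaxation protocol and relaxation metrics.

The in-silico rheology experiment mirrors a parallel-plate relaxation
test: the +y wall (with every fibril bead anchored to it) translates
along x until the engineering shear strain γ = Δx/L_y reaches its target
(20% by default), then holds while the boundary stress

    σ(t) = −(Σ F_x on +y anchors) / (L_x · L_z)     [pN/µm² = Pa]

is recorded.  Stress is normalized to its value at the start of the hold
and summarized by τ½, the time at which the normalized stress first
crosses 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .core import ANCHOR_POS_Y, Domain, SimParams
from .mechanics import PackedState, compute_forces, pack_state, unpack_state


@dataclass
class Protocol:
    """Shear-and-hold schedule.

    gamma : target engineering shear strain (0.20 = the 20% protocol).
    equilibration : zero-strain settling before loading, s (lets the
        geometrically assembled network and its bond population reach a
        steady state so the hold phase measures load-driven relaxation,
        not the annealing of the as-built geometry).
    ramp / hold : durations in seconds; the default 5 s ramp is
        quasi-static with respect to the network's mechanical modes
        (~ζ·n²/κ), so the hold starts near the relaxed elastic stress.
    sample_dt : stress sampling interval, s.
    stop_below : optional early-stop threshold on normalized held stress
        (e.g. 0.45 ends the run shortly after the τ½ crossing); None runs
        the full hold.
    """

    gamma: float = 0.20
    equilibration: float = 2.0
    ramp: float = 5.0
    hold: float = 60.0
    sample_dt: float = 0.05
    stop_below: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.ramp <= 0 or self.hold <= 0 or self.sample_dt <= 0:
            raise ValueError("durations must be positive")
        if self.equilibration < 0:
            raise ValueError("equilibration must be >= 0")


@dataclass
class RelaxationCurve:
    """Hold-phase stress record; ``times`` are measured from hold start."""

    times: np.ndarray
    stress: np.ndarray
    valid: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def normalized(self) -> np.ndarray:
        if not self.valid:
            raise ValueError("invalid curve (non-positive initial stress)")
        return self.stress / self.stress[0]


def boundary_stress(state, params: SimParams) -> float:
    """Instantaneous boundary shear stress of a state, Pa."""
    ps = state if isinstance(state, PackedState) else pack_state(state)
    F, _ = compute_forces(ps, params)
    fx = F[ps.anchored == ANCHOR_POS_Y, 0].sum()
    return float(-fx / (ps.Lx * ps.Lz))


def _run(ps: PackedState, params: SimParams, protocol: Protocol,
         rng: np.random.Generator, n_steps: int, eq_steps: int,
         ramp_steps: int, sample_every: int, hold_sample: int,
         stop_below: float, step0: int = 0):
    cap = n_steps // sample_every + 2
    times = np.zeros(cap)
    stress = np.zeros(cap)
    nbound = np.zeros(cap, dtype=np.int64)
    ns = _kernels.run_sim(
        ps.pos, ps.anchored, ps.base_x,
        ps.seg_i, ps.seg_j, ps.seg_l0, ps.seg_fib, ps.trip,
        ps.c_kind, ps.c_bound, ps.c_b1, ps.c_w1, ps.c_b2, ps.c_w2,
        ps.c_rest, ps.c_fib1, ps.c_fib2,
        params.kappa_s, params.kappa_b, params.kappa_c,
        params.zeta, params.kBT, params.effective_kBT_mech, params.dt,
        params.k0, params.bell_lambda, params.capture_radius,
        1 if params.rebinding_enabled else 0, params.rebind_rate,
        params.kinetics_stride,
        n_steps, step0, eq_steps, ramp_steps, protocol.gamma, ps.Ly,
        ps.Lx, ps.Lz, ps.perx, ps.perz,
        sample_every, hold_sample, stop_below,
        times, stress, nbound, rng)
    if ns < 0:
        raise FloatingPointError("non-finite force during dynamics")
    return times[:ns], stress[:ns], nbound[:ns]


def _schedule(protocol: Protocol, params: SimParams):
    sample_every = max(1, int(round(protocol.sample_dt / params.dt)))

    def _steps(duration, at_least_one=True):
        n = int(round(duration / params.dt))
        n = int(math.ceil(n / sample_every))
        if at_least_one:
            n = max(1, n)
        return sample_every * n

    return (sample_every, _steps(protocol.equilibration, False),
            _steps(protocol.ramp), _steps(protocol.hold))


def apply_shear(state, protocol: Protocol, params: SimParams,
                rng: np.random.Generator):
    """Ramp the +y wall to the target strain while dynamics run.

    Returns the sheared (mutated) state; rejects non-loadable states.
    """
    is_packed = isinstance(state, PackedState)
    if not is_packed and not state.loadable:
        raise ValueError("state is not loadable: missing y-boundary anchors")
    ps = state if is_packed else pack_state(state)
    sample_every, eq_steps, ramp_steps, _ = _schedule(protocol, params)
    _run(ps, params, protocol, rng, eq_steps + ramp_steps, eq_steps,
         ramp_steps, sample_every,
         (eq_steps + ramp_steps) // sample_every, -1.0)
    if not is_packed:
        unpack_state(ps, state)
    return state


def run_relaxation(state, protocol: Protocol, params: SimParams,
                   rng: np.random.Generator) -> RelaxationCurve:
    """Ramp to the target strain, hold, and record the relaxation curve."""
    is_packed = isinstance(state, PackedState)
    if not is_packed and not state.loadable:
        raise ValueError("state is not loadable: missing y-boundary anchors")
    ps = state if is_packed else pack_state(state)
    sample_every, eq_steps, ramp_steps, hold_steps = _schedule(
        protocol, params)
    # normalization reference: first sampling window fully inside the hold
    hold_sample = (eq_steps + ramp_steps) // sample_every + 1
    stop = protocol.stop_below if protocol.stop_below else -1.0
    times, stress, nbound = _run(
        ps, params, protocol, rng, eq_steps + ramp_steps + hold_steps,
        eq_steps, ramp_steps, sample_every, hold_sample, stop)
    if not is_packed:
        unpack_state(ps, state)
    t_hold = times[hold_sample:] - times[hold_sample]
    s_hold = stress[hold_sample:]
    valid = bool(len(s_hold) > 0 and s_hold[0] > 0)
    return RelaxationCurve(
        times=t_hold, stress=s_hold, valid=valid,
        meta={
            "gamma": protocol.gamma, "ramp_s": protocol.ramp,
            "sample_dt": protocol.sample_dt,
            "ramp_times": times[:hold_sample],
            "ramp_stress": stress[:hold_sample],
            "n_bound": nbound[hold_sample:],
            "early_stopped": bool(len(t_hold) * protocol.sample_dt
                                  < protocol.hold - protocol.sample_dt),
        })


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < 3:
        return y
    return (pd.Series(y)
            .rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def tau_half(curve: RelaxationCurve, smooth_window: int = 5):
    """Time from hold start at which normalized stress first crosses 1/2.

    A light centered moving average (default 5 samples) suppresses thermal
    noise before crossing detection; the crossing is located by linear
    interpolation between the bracketing samples.  Returns ``None`` when
    the curve never reaches 1/2 (censored) or is invalid.
    """
    if not curve.valid:
        return None
    y = _smooth(curve.normalized, smooth_window)
    t = curve.times
    below = np.nonzero(y < 0.5)[0]
    below = below[below > 0] if len(below) and below[0] == 0 else below
    if len(below) == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (y0 - 0.5) / (y0 - y1)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def normalized_at(curve: RelaxationCurve, t: float,
                  smooth_window: int = 5) -> float:
    """Smoothed normalized stress interpolated at time ``t`` (from hold start)."""
    y = _smooth(curve.normalized, smooth_window)
    return float(np.interp(t, curve.times, y))


def sweep(base_config, domain: Domain, params: SimParams, protocol: Protocol,
          param_name: str, values: Sequence, replicates: int = 4,
          seeds: Optional[Sequence[int]] = None, master_seed: int = 0,
          smooth_window: int = 5):
    """Independent assembly + relaxation per (value, replicate).

    ``param_name`` is one of ``L_B``, ``theta_deg``, ``matrix_type``.
    Returns ``(summary, detail)`` DataFrames; censored replicates are
    counted separately and a row with all replicates censored is flagged.
    """
    from .assembly import assemble
    from .config import derive_seeds

    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if param_name not in ("L_B", "theta_deg", "matrix_type"):
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    if seeds is None:
        labels = [f"{param_name}={v}/rep{r}"
                  for v in values for r in range(replicates)]
        seed_map = derive_seeds(master_seed, labels)
        seeds_for = {lbl: seed_map[lbl] for lbl in labels}
    rows = []
    for v in values:
        for r in range(replicates):
            if seeds is None:
                seed = seeds_for[f"{param_name}={v}/rep{r}"]
            else:
                seed = seeds[r]
            cfg = replace(base_config, **{param_name: v})
            state = assemble(cfg, domain, params, seed)
            rng = np.random.default_rng(seed + 1)
            curve = run_relaxation(state, protocol, params, rng)
            th = tau_half(curve, smooth_window) if curve.valid else None
            rows.append({
                "parameter": param_name, "value": v, "replicate": r,
                "seed": int(seed), "tau_half_s": th,
                "censored": th is None, "valid_curve": curve.valid,
            })
    detail = pd.DataFrame(rows)
    summary_rows = []
    for v in values:
        sub = detail[detail["value"] == v]
        ok = sub[~sub["censored"]]["tau_half_s"].astype(float)
        summary_rows.append({
            "parameter": param_name, "value": v,
            "mean_tau_half_s": ok.mean() if len(ok) else math.nan,
            "sd_tau_half_s": ok.std(ddof=1) if len(ok) > 1 else
            (0.0 if len(ok) == 1 else math.nan),
            "n": int(len(ok)),
            "n_censored": int(sub["censored"].sum()),
            "flagged_all_censored": bool(sub["censored"].all()),
        })
    summary = pd.DataFrame(summary_rows)
    summary.attrs["config"] = vars(base_config).copy()
    summary.attrs["protocol"] = vars(protocol).copy()
    return summary, detail
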