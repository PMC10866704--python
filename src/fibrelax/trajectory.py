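"""Trajectory recording: periodic bead-table frames plus a JSON manifest.

The shear protocol is executed in chunks of one frame interval; after
each chunk a columnar CSV of bead coordinates is written and a manifest
entry records time, applied strain, boundary stress and the
bound-crosslinker count.  Chunked execution reproduces an unchunked run
bit-for-bit (the kernel schedule is offset-aware and the random stream
is shared).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NetworkState, SimParams
from .mechanics import pack_state, unpack_state
from .rheometry import Protocol, _run, _schedule


def _write_frame(ps, state: NetworkState, path: Path) -> None:
    unpack_state(ps, state)
    rows = []
    for f in state.fibrils:
        for b in range(f.n_beads):
            rows.append((f.id, b, f.positions[b, 0], f.positions[b, 1],
                         f.positions[b, 2], int(f.anchored[b])))
    pd.DataFrame(
        rows, columns=["fibril_id", "bead", "x", "y", "z", "anchored"]
    ).to_csv(path, index=False, float_format="%.17g")


def record_relaxation(state: NetworkState, protocol: Protocol,
                      params: SimParams, rng: np.random.Generator,
                      frame_interval: float, out_dir) -> dict:
    """Run equilibration + ramp + hold, writing a frame every
    ``frame_interval`` seconds (rounded to whole sampling windows).

    Returns the manifest dict (also written to ``out_dir/manifest.json``);
    frames land in ``out_dir/frame_<index>.csv``.  The input state holds
    the final configuration afterwards.
    """
    if not state.loadable:
        raise ValueError("state is not loadable: missing y-boundary anchors")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ps = pack_state(state)
    sample_every, eq_steps, ramp_steps, hold_steps = _schedule(
        protocol, params)
    total = eq_steps + ramp_steps + hold_steps
    chunk = max(sample_every,
                sample_every * int(round(frame_interval
                                         / (sample_every * params.dt))))
    entries = []
    step = 0
    idx = 0
    while step < total:
        n = min(chunk, total - step)
        times, stress, nbound = _run(
            ps, params, protocol, rng, n, eq_steps, ramp_steps,
            sample_every, -1, -1.0, step0=step)
        step += n
        t = step * params.dt
        if step <= eq_steps:
            gamma = 0.0
        elif step >= eq_steps + ramp_steps:
            gamma = protocol.gamma
        else:
            gamma = protocol.gamma * (step - eq_steps) / ramp_steps
        frame = f"frame_{idx:05d}.csv"
        _write_frame(ps, state, out_dir / frame)
        entries.append({
            "frame": frame,
            "time_s": t,
            "strain": gamma,
            "stress_Pa": float(stress[-1]) if len(stress) else None,
            "n_bound": int(nbound[-1]) if len(nbound) else None,
        })
        idx += 1
    manifest = {
        "format": "fibrelax-trajectory-v1",
        "protocol": {
            "gamma": protocol.gamma,
            "equilibration_s": protocol.equilibration,
            "ramp_s": protocol.ramp,
            "hold_s": protocol.hold,
            "sample_dt_s": protocol.sample_dt,
        },
        "frame_interval_s": chunk * params.dt,
        "frames": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
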