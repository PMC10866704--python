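# fibrelax

Agent-based simulation of type-1 collagen matrices for studying how
network architecture controls **stress relaxation** — the hallmark of
matrix viscoelasticity.  Collagen networks in tissue are held together by
weak, transient bonds; chemical modification (for example by advanced
glycation end-products, AGEs) bundles fibrils, shortens effective fibres
and makes the network more heterogeneous, and such matrices relax stress
faster under a held deformation.  `fibrelax` provides the pieces needed
to study that chain of causation in silico, plus the bench-side analytics
used to quantify viscoelasticity in the laboratory.

The package is aimed at mechanobiology and biophysics researchers who
want a small, fully scriptable fiber-network model rather than a
black-box finite-element tool.

## Model in brief

* Fibrils are bead–spring chains (stretching stiffness κ_s, angular
  bending stiffness κ_b) assembled by nucleation and elongation to 3 µm
  (or 5 µm) in a 20 × 20 × 5 µm box, periodic in x and z, at an effective
  collagen concentration of 3.65 mg/ml (specific volume 0.73 ml/g).
* Three architectures: a **fibrillar** matrix (crosslinkers only), a
  **long, tight-bundle** matrix (permanent bundlers tie parallel,
  staggered fibrils), and a **short, loose-bundle** matrix (bundlers
  chain fibrils end-to-end at a junction angle θ).
* Transient crosslinkers unbind following **Bell's law**,
  k = k₀·exp(Fλ/k_BT), and may rebind nearby; bundlers are permanent.
* Beads obey overdamped Langevin dynamics with explicit Euler
  integration; fibrils are anchored to the two walls normal to y.
* The rheology protocol applies 20% shear strain via the +y wall, holds
  it, records the boundary stress σ(t) (pN/µm² ≡ Pa), and summarizes the
  normalized curve by **τ½**, the time to relax to half the initial
  stress.
* `structure_metrics` quantifies fibre lengths, junction angles, spatial
  heterogeneity (CV of per-cell mass) and crosslink-graph connectivity;
  `mechlab` implements Hertz indentation fitting, hysteresis area, loss
  tangent and circularity with synthetic ground-truth generators.

See `docs/methods.md` for the full model description, parameter table
and limitations.

## Worked example

Assemble a desk-scale loose-bundle matrix (θ = 10°, 3 µm fibrils), run
the shear-and-hold protocol, and report structure and relaxation:

```python
import numpy as np
from fibrelax import (AssemblyConfig, Domain, Protocol, SimParams,
                      assemble, junction_angles, run_relaxation,
                      structure_report, tau_half)

domain = Domain(12.0, 12.0, 3.0)                  # desk-scale box, µm
config = AssemblyConfig(matrix_type="loose_bundle", theta_deg=10.0,
                        chain_length=3, anchor_tol=1.5)
params = SimParams(kBT_mech=0.0)                  # athermal bead dynamics
state = assemble(config, domain, params, seed=42)

rep = structure_report(state, cell_size=1.0)
bundler_angles = junction_angles(state, kind="bundler")
print(f"fibrils: {len(rep.fibre_lengths)}, "
      f"mean chain length: {np.mean(rep.chain_lengths):.1f} um, "
      f"bundler junction angle: {np.mean(bundler_angles):.1f} deg")
print(f"heterogeneity CV: {rep.heterogeneity_cv:.2f}, "
      f"mean degree: {rep.mean_degree:.1f}, "
      f"y-percolating: {rep.y_percolation}")

curve = run_relaxation(state, Protocol(hold=60.0), params,
                       np.random.default_rng(1))
print(f"stress at hold start: {curve.stress[0]:.4f} Pa, "
      f"tau_half: {tau_half(curve):.2f} s")
```

Output:

```
fibrils: 49, mean chain length: 8.6 um, bundler junction angle: 10.0 deg
heterogeneity CV: 1.61, mean degree: 6.4, y-percolating: True
stress at hold start: 0.0070 Pa, tau_half: 2.72 s
```

49 fibrils reproduce 3.65 mg/ml in the 432 µm³ box; chains of three 3 µm
fibrils give ~9 µm effective fibres (the lone remainder chain pulls the
mean below 9), joined at exactly the configured 10° angle.  The crosslink
graph percolates between the y-walls, so the 20% shear is transmitted and
the held stress — about 7 mPa for this seed — halves in ~2.7 s as loaded
crosslinkers unbind (Bell's law) and rebind in relaxed positions.  A
matched fibrillar matrix has a heterogeneity CV of 1.59 for the same
seed (lower on average across seeds) and relaxes faster at desk scale; see
`docs/methods.md` for which architecture trends this model does and does
not reproduce.

The same pipeline is scriptable from the shell:

```sh
fibrelax assemble --profile desk --seed 42 --out scratch/state
fibrelax metrics  --state scratch/state --cell-size 1.0
fibrelax relax    --profile desk --seed 42 --out scratch/curve.csv
fibrelax sweep    --profile desk --param theta_deg --values 0,30 \
                  --replicates 4 --out scratch/theta_sweep.csv
fibrelax mechlab circ --area 314.159265 --perimeter 62.8318531
```

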