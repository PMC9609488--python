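# fibergen

Stochastic generation and structural analysis of fibrous materials —
fibrin clots, collagen matrices, nonwovens, mineral wools — as 3D fiber
networks in a periodic box whose diameter, length, orientation, and
tortuosity distributions match prescribed (typically experimentally
measured) statistics.

## What it does

**Orientation, with projection-distortion correction.** Fiber orientations
are drawn from de la Vallée Poussin (VP) kernel mixtures,
`p(n̂) ∝ Σᵢ (2kᵢ+1)(n̂·m̂ᵢ)^{2kᵢ}`, which represent isotropic, transverse
isotropic (1 kernel), orthotropic (2), and hexagonal (3) symmetries.
Experimental orientation data are almost always 2D projections of 3D
structures, and the projection distorts the fitted concentration: a
distribution of true strength `k3D` whose mean axis is tilted by ψ out of
the imaging plane fits in-plane to a different strength `k2D`. The package
fits 2D VP mixtures to angle histograms and applies the correction
`k3D = 3·√N_VP · k2D / (8 cos²ψ)` to published measured strengths (the
literal `N_VP`-in-denominator variant is selectable), and the exact inverse
`k3D = (k_shape + 0.36 sin²ψ)/cos²ψ` to its own projected-sample fits.

**Tortuosity, with calibrated von Mises–Fisher walks.** Curvilinear fibers
are smoothed VMF random walks. The concentration required for a target
tortuosity ⟨τ⟩ is the closed-form calibration

    κ(⟨τ⟩) = exp((−0.2⟨τ⟩³ − 0.15⟨τ⟩² + 1.56⟨τ⟩ − 1.2) / (⟨τ⟩² − 1.75⟨τ⟩ + 0.75))

with step count `N = ⌈β(⟨τ⟩²/2 + 1)⌉` (a walk with fewer than ⌈⟨τ⟩²/2+1⌉
steps cannot reach ⟨τ⟩ at all). Walks whose realized τ errs by more than 5%
are redrawn, so prescribed tortuosity distributions are reproduced without
trial-and-error parameter hunting.

**Non-penetration by damped bead-spring dynamics.** Randomly placed fibers
interpenetrate; each fiber is discretized into bonded spherical beads with
harmonic bonds, cosine angle forces, a soft finite-range contact force, and
Stokes drag, integrated by velocity Verlet under periodic boundaries until
the percent fiber overlap (PFO) plateaus. The package reports how much this
necessary step perturbs each fiber's length, tortuosity, and orientation.

**Pore sizes by distance transform + watershed.** The relaxed network is
voxelized (edge ≤ min diameter/5), the periodic Euclidean distance
transform is computed, and watershed basins of its negation give one pore
per basin; mean pore diameters follow `⟨dp⟩ ∝ df` and `⟨dp⟩ ∝ 1/√φ`.

## Worked example

```python
import math
import numpy as np
from fibergen import (NetworkSpec, VPParams, VPKernel,
                      lognormal_params_from_moments, build_network)
from fibergen.network import characterize
from fibergen.relax import MechanicsParams, relax
from fibergen.pores import measure_pore_sizes, predict_mean_pore

spec = NetworkSpec(
    box_length=16.8, volume_fraction=0.2,
    diameter_mean=1.0, diameter_std=0.05,
    length_mean=12.0, length_std=1.2,
    orientation=VPParams((VPKernel([0, 0, 1], 3.0),)),
    tortuosity=lognormal_params_from_moments(1.2, 0.05),
    seed=20,
)
net = build_network(spec)
print(f"{net.n_fibers} fibers, realized volume fraction "
      f"{net.realized_volume_fraction():.3f}")

res = relax(net, MechanicsParams(fixed_end_steps=200, max_steps=1200,
                                 stop_window=600, stop_tolerance=5e-3))
print(f"PFO {res.pfo_trace[0,1]:.1f}% -> {res.pfo_trace[-1,1]:.2f}% "
      f"in {res.n_steps} steps")

sys_ = res.system
pores = measure_pore_sizes(sys_.wrapped_positions(), sys_.radii,
                           spec.box_length)
pred, band = predict_mean_pore(1.0, model="eq23")
print(f"{pores.n_pores} pores, mean dp = {pores.mean_diameter:.2f} "
      f"(2*df predictor {pred:.2f} ± {band:.0%})")
```

prints

```
101 fibers, realized volume fraction 0.201
PFO 23.2% -> 2.03% in 1200 steps
68 pores, mean dp = 1.36 (2*df predictor 2.00 ± 60%)
```

The generator hit the prescribed 20% volume fraction within half a percent;
the damped relaxation removed over 90% of the fiber–fiber overlap in a
short schedule; and the measured mean pore diameter sits inside the
`⟨dp⟩ ≈ 2⟨df⟩` predictor's ~60% band (at 20% volume fraction pores run
smaller than the diameter-only rule of thumb, as the `df/√φ` law says they
should).

There is also a CLI over the same functions:

```sh
fibergen generate --config run.yaml       # build a network + artifacts
fibergen relax --config run.yaml          # enforce non-penetration
fibergen pores --config run.yaml          # pore-size distribution
fibergen fit-orientation histogram.tsv    # 2D VP fit + k2D -> k3D
fibergen calibrate-tortuosity             # kappa(tau) calibration curve
fibergen fixtures                         # synthetic test histograms
```

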