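# Methods

This note documents the models implemented in fibergen, the calibrations
and conventions they rest on, the numerical choices, and what the validation
studies do and do not demonstrate.

## Network construction

A network is prescribed by a periodic cubic box of side `L`, a fiber volume
fraction `φ`, gamma-distributed diameters and lengths (moment-matched:
`k = μ²/σ²`, `θ = σ²/μ`), a de la Vallée Poussin (VP) orientation mixture,
and a tortuosity distribution (truncated lognormal or an empirical
histogram, the histogram taking precedence because measured tortuosity
rarely follows a clean parametric family). The fiber count is the
cylinder-volume estimate `N_f = round(4 L³ φ / (π⟨l⟩⟨d⟩²))`; seeds are
uniform in the box and are the walks' origins. All scalar draws go through
a generic rejection sampler (uniform proposals against the density or a
linearly interpolated histogram; mean ± 6σ bounds for infinite support);
orientations are rejection-sampled on the sphere with the exact envelope
`Σ(2kᵢ+1)/(4πN)`. One seeded `numpy` generator is threaded through every
draw, so a spec + seed reproduces a network bit-for-bit.

Gamma diameter draws below a configurable floor (default ⟨d⟩/5) are
redrawn: the pore analysis ties its voxel edge to the smallest diameter,
and unboundedly small draws would make the voxel grid explode. Setting the
floor fraction to 0 disables this.

## Orientation: projection distortion and its correction

The VP density `p(n̂) ∝ ((n̂·m̂)²)^k` is antipodally symmetric and
superposable; 1/2/3 equal-strength kernels give transverse isotropic,
orthotropic, and hexagonal symmetry. The in-plane (2D) form on [0, π) is
`C(k) cos^{2k}(θ−θ_VP)` with `C(k) = Γ(k+1)/(√π Γ(k+1/2))`, which
integrates to one (verified by quadrature; this is the normalizing
reconstruction of a garbled printed constant).

Two facts drive the correction machinery, both derived here by quadrature
of the projected marginal and verified by sampling:

1. For a single kernel with axis tilted ψ out of the imaging plane, the
   density-shape parameter of the projected angle histogram follows
   `k_shape = k3D·cos²ψ − 0.36·sin²ψ` (at ψ = 0 it is *exactly* `k3D`
   because the azimuthal marginal factorizes to `cos^{2k3D}θ`). The
   intercept term matters only for weak kernels at strong tilt.
2. Published "measured" 2D strengths follow a fit convention ≈ 8/3 times
   the density-shape parameter (`PROJECTION_FIT_SCALE`). The published
   2D→3D correction `k3D = 3√N_VP·k2D/(8cos²ψ)` undoes exactly this
   constant; the package reports fitted strengths in both conventions.

`correct_k2d_to_k3d` implements the published correction in two modes:
"table" (default; the `√N_VP` numerator reproduces every published
per-material corrected value) and "literal" (the `N_VP` denominator as the
correction is usually printed, which contradicts those same values for
`N_VP > 1`). For fits of projected *sample* data the kernel-count factor
does not apply at all: each kernel of a symmetric mixture projects
independently (the marginal of an N-kernel mixture at ψ = 0 is exactly the
2D mixture with the same per-kernel strengths), so `fit_projected` inverts
relation (1) per kernel. Averaging over an unknown tilt is supported via
the closed-form mean `4k3D/(3N_VP)·(1 + (sinΨ₂cosΨ₂ − sinΨ₁cosΨ₁)/(Ψ₂−Ψ₁))`.

The correction applies to symmetric mixtures only; asymmetric orientation
distributions (unequal kernels) are out of scope, and fits of them should
be treated as descriptive.

2D fits are multi-started least squares on the unit-mass histogram density
(36 bins over [0, π) by default, matching 5°-resolution polar plots):
kernel angles seeded at the histogram's largest circular local maxima with
angular non-max suppression (π/(2N) minimum separation), strength seeded at
1, ten jittered restarts, bounds k ≥ 0. Whether bins should be weighted by
count is unknowable from typical published plots; unweighted density least
squares is used.

## Tortuosity: calibrated VMF walks

A fiber of length `l` and target tortuosity τ is generated as an
`N = ⌈β(τ²/2+1)⌉`-step walk of step `Δ = l/N` whose i.i.d. step directions
follow a von Mises–Fisher distribution about the fiber's mean orientation,
then smoothed by a natural cubic spline (chord-length parameterized,
arc-length resampled). β defaults to 20; larger β narrows the spread of
realized τ. The minimum step count `⌈τ²/2+1⌉` is the isotropic-walk
ceiling: with fewer steps the target is unreachable no matter how weak the
concentration (the mean plateaus near 1.38√N; the step-limit study
demonstrates this with a 10%-trimmed mean, since τ = L/R is heavy-tailed
for short walks).

The concentration comes from the closed-form calibration κ(τ) (see README),
which diverges as τ → 1⁺ and is monotone decreasing; beyond τ ≈ 3.5 it is
an extrapolation and a warning is logged. The calibration is expressed in a
VMF convention whose concentration is **half** the standard `exp(κ n̂·m̂)`
exponent: walks driven by the standard sampler use `2κ(τ)`
(`WALK_CONCENTRATION_FACTOR`). This factor was fixed by matching the
asymptotic walk tortuosity `1/(coth κ_eff − 1/κ_eff)` to the calibration's
own targets, and validated by simulation: with it, unscreened smoothed
walks hit targets within ~5% across τ ∈ [1.1, 3]; without it they overshoot
by up to ~80%.

Walks whose realized τ errs by more than 5% (relative) are discarded and
redrawn; targets within half a tolerance of 1 are returned as straight
segments (κ diverges there). Two residual biases are worth knowing:

* **Discretization.** The fiber's polyline is resampled at the spline step
  Δ_CS (clamped to at most the walk step — coarser spacing aliases the
  curve). Measured on that polyline, τ carries a chord-vs-arc bias of a few
  percent at Δ_CS = Δ; it converges once Δ_CS ≲ Δ/5. Ensemble mean τ is
  insensitive (< 2%) to Δ_CS within the converged regime.
* **Low-τ centering.** At τ ≈ 1.1 the realized-τ distribution is narrower
  than the ±5% screen and centered 1–2.5% below target (depending on the
  measure), so screening cannot recenter it; the screened mean error there
  is ~1.3–2.4% rather than < 1%. At τ ≥ 1.3 the screen clips the
  distribution and pins the mean within 1%. No constant convention factor
  removes the low-τ bias without pushing the τ = 2.2 unscreened mean
  outside 10%; the κ(τ) calibration is itself only ~5–10% accurate.

A physical validity constraint is enforced as a warning: the walk's bend
radius `Δ√(2κ_eff)` should stay above half the fiber diameter, otherwise
the centerline curls inside the fiber's own thickness and the initial
state is dominated by self-overlap. High tortuosity therefore requires a
high aspect ratio (or a smaller β).

## Non-penetration relaxation

Each fiber becomes a chain of spherical beads (radius d/2) at the spline
points. Bond rest lengths and angle rest values are the *initial* spacings
and angles, so a fresh network is force-free apart from contacts. Forces:

* bond `f = −2k_b(R−R₀)r̂`, `k_b = E·(π/4 d²)/R₀`;
* angle `f_i = k_θ sin(θ−θ₀)·unit((r_ij×r_kj)×r_ij)` (mirrored on k,
  reaction on j), `k_θ = E·I/R₀` with `I = πd⁴/32` as published (the
  standard `πd⁴/64` is a flag). As printed this is a unit-direction force,
  not the exact gradient of a cosine potential; trio torque about the
  center vanishes only for equal arms (chains here have nearly equal
  spacing). Collinear trios are regularized by an arbitrary perpendicular.
* contact `f = (πk_c/R_c)sin(πR/R_c)r̂` for `R < R_c = (d_i+d_j)/2`,
  `k_c = (E/16)ν^{1/3}√R̄`, `1/R̄ = 1/d_i + 1/d_j` — a Hertz-like soft
  core, finite everywhere and vanishing at zero separation so deeply
  overlapped initial states do not explode. The printed expression is
  garbled; this reconstruction is configurable (`kc_scale`) and the
  *overlap removal* is insensitive to its prefactor.
* Stokes drag `f = −3πηd v`.

Velocity Verlet (semi-implicit in the drag) with
`dt = 0.02√(m/k_b,max)` (the printed time step is garbled; this is the
dimensionally consistent stability-limited choice, halved automatically on
divergence). Fiber ends are pinned for an initial phase to suppress rigid
rotations. Neighbor search uses a periodic cKDTree with a 0.3·R_c skin —
the same O(N) fixed-radius pair search a cell list provides. Masses are
uniform (per-particle volume scaling is unstated in the source method and
makes no difference to the relaxed geometry). The run stops when the
percent fiber overlap (PFO — pairwise sphere–sphere lens volume over total
sphere volume, excluded pairs not counted) changes by less than a relative
tolerance over a trailing window, or at `max_steps`.

**Change statistics depend on the protocol's vigor.** The perturbation that
non-penetration inflicts on fiber length/tortuosity/orientation is not
intrinsic: at near-critical damping (damping ratio ζ ≈ 0.5, the package
default — fastest clean settling) the mean per-fiber changes are several
times smaller (~0.5/1/1.5%) than in an energetic, weakly damped run. The
reference procedure this replicates ran "high-energy dynamics" with
randomly chosen physical parameters, so the change-statistics study uses
ζ = 0.01 (`MechanicsParams.damping_ratio`); with it the pooled means over
ten networks spanning aspect ratio 10–150, φ = 1–40%, k3D = 0–10,
τ = 1.05–2.5 land near 2% (length), 9% (tortuosity), 6% (orientation) —
within a factor 2 of the reference values 2/14/5. The orientation change is
reported as the rotation angle of the fiber's mean orientation divided by
90°, ×100 (no canonical denominator exists for an angular percent; the
convention is recorded in the report).

## Pore analysis

Beads are voxelized on a periodic grid (edge = smallest diameter/5 by
default; a voxel is occupied when its center is within radius + half the
voxel diagonal of a bead center — the partial-containment rule, which
dilates surfaces by up to ~0.87 voxel, a known small bias). The periodic
Euclidean distance transform is computed exactly by half-box wrap padding,
and watershed basins of the negated EDT (26-connectivity, markers =
h-maxima with one voxel of suppression depth to merge spurious single-voxel
minima) give one pore per basin at its EDT maximum.

Detections with EDT below 3 voxel edges are discarded as sub-resolution:
the voxelized fiber surface is rough at the single-voxel scale, and at
φ = 0.4 half of the raw watershed detections sit at 1–2 voxels (the minimum
representable value), dragging the φ-scaling exponent from ≈ −0.56 to
≈ −0.79. The floor is configurable (`min_edt_voxels=0` keeps everything).

**Diameter convention.** The pore size is reported as the raw EDT value at
the pore ("radius" convention) by default, with the inscribed-sphere 2×EDT
("diameter") selectable. The default was fixed by calibrating both against
the mean-pore-size laws on the 20-network ensemble (three diameters × five
volume fractions at τ = 1.2 plus five τ/orientation variations, aspect
ratio 12, 100 fibers each, relaxed, common random numbers across the grid):

| convention | ⟨dp⟩/⟨df⟩ (law ≈ 2, ±60%) | ⟨dp⟩/(⟨df⟩/√φ) (law ≈ 1, ±40%) |
|---|---|---|
| radius (default) | 1.72–1.82 | ≈ 0.60 |
| diameter (2×EDT) | ≈ 3.44 | ≈ 1.19 |

Each convention matches one law well and sits at/over the other's band
edge; the radius convention has the smaller aggregate error and is the
literal reading of "the value of the distance transform". The scaling
*exponents* are convention-independent: log–log slopes ≈ 1.05 in d_f and
≈ −0.56 in φ on this ensemble. Closed-form predictors
(`2⟨df⟩`, `⟨df⟩/√φ`, `⟨df⟩(1/√φ − 0.05⟨τ⟩)`) are provided with their
~60/40/20% error bands as metadata.

## Validation ensembles and their scope

The studies in `fibergen.studies` are reduced replications: tens of
networks of 10–100 fibers rather than hundreds of large ones, with
relaxation schedules of a few thousand steps chosen to pass the PFO
plateau on systems of this size. The synthetic histogram fixtures emulate
digitized experimental plots (2D VP mixtures and truncated lognormals with
multiplicative noise); they share none of real data's segmentation
artifacts, finite imaging depth, or fiber-detection bias, so passing
recovery tests demonstrates correctness of the fitting machinery, not
robustness to real measurement error. Box sizes put fiber length near or
above the box edge for high aspect ratios (periodic self-interaction is
physical there), and pore statistics at the dilute end are mildly truncated
by the finite box.

## Known limitations

* Asymmetric (unequal-kernel) orientation corrections are out of scope; the
  published correction is only valid for symmetric mixtures.
* κ(τ) centering bias at τ ≈ 1.1 (see above); τ > 3.5 is extrapolation.
* The angle force is the published unit-direction form, not a potential
  gradient; energy-based diagnostics use bond+contact configurations.
* Change statistics characterize the implemented protocol at the stated
  damping; they are not universal constants of "enforcing non-penetration".
* Pore detection inherits voxel-scale biases (surface dilation, resolution
  floor); mean pore sizes carry the convention ambiguity documented above,
  while scaling exponents do not.
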