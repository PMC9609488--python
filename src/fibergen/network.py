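"""Assembly of a full fiber network in a periodic cubic domain.

Given a prescription — box size, fiber volume fraction, diameter and length
moments, an orientation distribution (VP mixture or 2D histogram), and a
tortuosity distribution (truncated lognormal or histogram) — the builder
estimates the fiber count N_f ≈ 4 V φ / (π ⟨l⟩ ⟨d⟩²), seeds fiber origins
uniformly, draws each fiber's diameter/length/orientation/tortuosity, and
generates its curvilinear path.  Prescribed (drawn) and realized (measured)
per-fiber values are both retained for provenance.

Paths may extend beyond the box at this stage; periodic wrapping is applied
only during the subsequent bead-spring relaxation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibergen.distributions import (
    DEFAULT_DIAMETER_FLOOR_FRAC,
    GammaParams,
    HistogramDensity,
    SamplingDomain,
    TruncatedLognormalParams,
    VPParams,
    gamma_params_from_moments,
    lognormal_params_from_moments,
    sample_gamma_rejection,
    sample_rejection,
    sample_vp,
)
from fibergen.orientation import fit_projected
from fibergen.tortuosity import FiberPath, generate_fiber, measure_tortuosity

logger = logging.getLogger(__name__)


@dataclass
class NetworkSpec:
    """Prescription for one stochastic fiber network.

    ``orientation`` is a :class:`VPParams`; ``tortuosity`` is either
    :class:`TruncatedLognormalParams` or a :class:`HistogramDensity`
    (histograms take precedence when both could apply, since empirical
    tortuosity rarely follows a clean parametric family).
    """

    box_length: float
    volume_fraction: float
    diameter_mean: float
    diameter_std: float
    length_mean: float
    length_std: float
    orientation: VPParams
    tortuosity: TruncatedLognormalParams | HistogramDensity
    beta: float = 20.0
    spline_step: float | None = None  # default: diameter_mean / 2
    diameter_floor_frac: float = DEFAULT_DIAMETER_FLOOR_FRAC
    tau_tol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume fraction must lie in (0, 1)")
        if self.box_length <= 0:
            raise ValueError("box length must be positive")
        for name in ("diameter_mean", "length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diameter_std", "length_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def box_volume(self) -> float:
        return self.box_length**3

    @property
    def effective_spline_step(self) -> float:
        return self.spline_step if self.spline_step is not None else self.diameter_mean / 2.0


@dataclass
class FiberNetwork:
    """A generated network: fibers plus prescribed-vs-realized provenance."""

    fibers: list[FiberPath]
    spec: NetworkSpec
    prescribed: pd.DataFrame  # columns: diameter, length, tau, nx, ny, nz
    seeds: np.ndarray

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def realized_table(self) -> pd.DataFrame:
        """Measured per-fiber diameter, contour length, tau, orientation."""
        rows = []
        for f in self.fibers:
            n = f.mean_orientation
            rows.append((f.diameter, f.contour_length, measure_tortuosity(f),
                         n[0], n[1], n[2]))
        return pd.DataFrame(rows, columns=["diameter", "length", "tau", "nx", "ny", "nz"])

    def realized_volume_fraction(self) -> float:
        vol = sum(math.pi / 4.0 * f.diameter**2 * f.contour_length for f in self.fibers)
        return vol / self.spec.box_volume


def estimate_fiber_count(spec: NetworkSpec) -> int:
    """N_f = round(4 V φ / (π ⟨l⟩ ⟨d⟩²)), the cylinder-volume estimate."""
    nf = 4.0 * spec.box_volume * spec.volume_fraction / (
        math.pi * spec.length_mean * spec.diameter_mean**2
    )
    nf = int(round(nf))
    if nf == 0:
        warnings.warn("prescription yields an empty network (N_f = 0)", stacklevel=2)
    return nf


def seed_positions(n: int, box_length: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` fiber seed points, uniform in [0, L]³."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return rng.uniform(0.0, box_length, size=(n, 3))


def mean_orientation(path: FiberPath) -> np.ndarray:
    """Normalized average of segment unit tangents along a fiber backbone."""
    return path.mean_orientation


def _draw_diameters(spec: NetworkSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    params = (gamma_params_from_moments(spec.diameter_mean, spec.diameter_std)
              if spec.diameter_std > 0 else None)
    if params is None:
        return np.full(n, spec.diameter_mean)
    floor = spec.diameter_floor_frac * spec.diameter_mean
    return sample_gamma_rejection(params, n, rng, floor=floor)


def _draw_lengths(spec: NetworkSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.length_std == 0:
        return np.full(n, spec.length_mean)
    params = gamma_params_from_moments(spec.length_mean, spec.length_std)
    # lengths shorter than one spline step are meaningless; redraw below that
    return sample_gamma_rejection(params, n, rng,
                                  floor=2.0 * spec.effective_spline_step)


def _draw_tortuosities(spec: NetworkSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    tort = spec.tortuosity
    if isinstance(tort, HistogramDensity):
        taus = sample_rejection(tort, tort.domain, n, rng)
        return np.maximum(taus, 1.0)
    if tort.s_ln == 0:
        return np.full(n, math.exp(tort.m_ln))
    mean = math.exp(tort.m_ln + tort.s_ln**2 / 2)
    std = mean * math.sqrt(math.expm1(tort.s_ln**2))
    domain = SamplingDomain(1.0, mean + 6 * std)
    return sample_rejection(tort.pdf, domain, n, rng)


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None) -> FiberNetwork:
    """Build a network from a prescription (deterministic given spec + seed)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    nf = estimate_fiber_count(spec)
    seeds = seed_positions(nf, spec.box_length, rng)
    diameters = _draw_diameters(spec, nf, rng)
    lengths = _draw_lengths(spec, nf, rng)
    orientations = sample_vp(spec.orientation, nf, rng)
    taus = _draw_tortuosities(spec, nf, rng)

    # physical validity: the walk's bend radius ~ step * sqrt(2 kappa) should
    # stay above half the fiber diameter, or the centerline curls at a scale
    # below the fiber's own thickness and self-overlaps
    from fibergen.tortuosity import (
        WALK_CONCENTRATION_FACTOR,
        kappa_for_tortuosity,
        steps_for_walk,
    )

    steps_est = np.array([steps_for_walk(max(t, 1.0), spec.beta) for t in taus])
    kappas = np.array([
        WALK_CONCENTRATION_FACTOR * kappa_for_tortuosity(t) if t > 1.001 else np.inf
        for t in taus
    ])
    bend_radius = lengths / steps_est * np.sqrt(2.0 * kappas)
    bad = bend_radius < diameters / 2.0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())}/{nf} fibers bend at a radius below half their "
            "diameter (tortuosity too high for their aspect ratio); the "
            "generated centerlines will self-overlap", stacklevel=2,
        )

    fibers: list[FiberPath] = []
    records = []
    for i in range(nf):
        path, rec = generate_fiber(
            length=float(lengths[i]),
            tau_target=float(taus[i]),
            orientation=orientations[i],
            origin=seeds[i],
            beta=spec.beta,
            spline_step=spec.effective_spline_step,
            tol=spec.tau_tol,
            diameter=float(diameters[i]),
            rng=rng,
        )
        fibers.append(path)
        records.append((diameters[i], lengths[i], taus[i],
                        orientations[i, 0], orientations[i, 1], orientations[i, 2],
                        rec.rejections, rec.kappa, rec.n_steps))
    prescribed = pd.DataFrame(
        records,
        columns=["diameter", "length", "tau", "nx", "ny", "nz",
                 "rejections", "kappa", "n_steps"],
    )
    net = FiberNetwork(fibers=fibers, spec=spec, prescribed=prescribed, seeds=seeds)
    logger.info("built network: %d fibers, realized phi=%.4f (target %.4f)",
                nf, net.realized_volume_fraction(), spec.volume_fraction)
    return net


def _mape(prescribed: np.ndarray, realized: np.ndarray) -> float:
    prescribed = np.asarray(prescribed, float)
    realized = np.asarray(realized, float)
    return float(np.mean(np.abs(realized - prescribed) / np.abs(prescribed)) * 100.0)


def characterize(network: FiberNetwork, n_bins: int = 36, fit_orientation: bool = True,
                 seed: int = 0) -> dict:
    """Summarize realized structure against the prescription.

    Reports realized volume fraction, moments of diameter/length/tau, MAPE
    between prescribed and realized per-fiber length and tortuosity, and (if
    requested) projected-orientation fits on the three coordinate planes
    with corrected 3D strengths.
    """
    if network.n_fibers == 0:
        raise ValueError("cannot characterize an empty network")
    realized = network.realized_table()
    pres = network.prescribed
    summary: dict = {
        "n_fibers": network.n_fibers,
        "volume_fraction": network.realized_volume_fraction(),
        "diameter_mean": float(realized["diameter"].mean()),
        "diameter_std": float(realized["diameter"].std(ddof=1)) if network.n_fibers > 1 else 0.0,
        "length_mean": float(realized["length"].mean()),
        "length_std": float(realized["length"].std(ddof=1)) if network.n_fibers > 1 else 0.0,
        "tau_mean": float(realized["tau"].mean()),
        "tau_std": float(realized["tau"].std(ddof=1)) if network.n_fibers > 1 else 0.0,
        "length_mape": _mape(pres["length"].to_numpy(), realized["length"].to_numpy()),
        "tau_mape": _mape(pres["tau"].to_numpy(), realized["tau"].to_numpy()),
    }
    if fit_orientation:
        from fibergen.orientation import ProjectionSetup

        vecs = realized[["nx", "ny", "nz"]].to_numpy()
        n_vp = network.spec.orientation.n_vp
        planes = {}
        for axis, name in zip(np.eye(3), ("yz", "zx", "xy")):
            rep = fit_projected(vecs, ProjectionSetup(plane_normal=axis),
                                n_vp=n_vp, n_bins=n_bins, seed=seed)
            planes[name] = rep
        summary["orientation_planes"] = planes
    return summary
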