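"""Random-sampling primitives for stochastic fiber network generation.

All fiber-level quantities are drawn from a small set of distributions:

* gamma (fiber diameters and lengths), parameterized by moment matching;
* lognormal truncated at 1 (fiber tortuosity);
* de la Vallée Poussin (VP) mixtures on the sphere (fiber orientations),
  antipodally symmetric with density per kernel
  ``(2k+1)/(4π) (n·m)^(2k)``;
* von Mises-Fisher (VMF) on the sphere (random-walk step directions).

Scalar quantities are drawn by rejection sampling against either a
continuous density or a linearly interpolated histogram, mirroring how
digitized experimental histograms are consumed.  All samplers take an
explicit :class:`numpy.random.Generator` so that runs are reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-9


def _as_unit(v: Sequence[float], name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise ValueError(f"{name} must be a nonzero 3-vector")
    return v / n


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parameters of a gamma distribution.

    ``k_shape`` (dimensionless) and ``theta_scale`` (units of the modeled
    quantity) imply mean ``k*theta`` and variance ``k*theta**2``.
    """

    k_shape: float
    theta_scale: float

    def __post_init__(self) -> None:
        if self.k_shape <= 0 or self.theta_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.k_shape * self.theta_scale

    @property
    def std(self) -> float:
        return math.sqrt(self.k_shape) * self.theta_scale

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        k, th = self.k_shape, self.theta_scale
        logp = (
            (k - 1) * np.log(x[pos])
            - x[pos] / th
            - gammaln(k)
            - k * math.log(th)
        )
        out[pos] = np.exp(logp)
        return out


@dataclass(frozen=True)
class TruncatedLognormalParams:
    """Lognormal parameters in log space, support truncated at 1.

    Tortuosity can never fall below 1, so the density is cut there; the
    moment-matching formulas are therefore approximate for wide spreads.
    """

    m_ln: float
    s_ln: float
    lower_bound: float = 1.0

    def __post_init__(self) -> None:
        if self.s_ln < 0:
            raise ValueError("log-space standard deviation must be >= 0")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        ok = x >= self.lower_bound
        if self.s_ln == 0:
            # degenerate: point mass at exp(m_ln); represented as a spike
            # for rejection sampling purposes the caller should shortcut
            return np.where(np.isclose(x, math.exp(self.m_ln)), np.inf, 0.0)
        z = (np.log(x[ok]) - self.m_ln) / self.s_ln
        out[ok] = np.exp(-0.5 * z**2) / (x[ok] * self.s_ln * math.sqrt(2 * math.pi))
        return out


@dataclass(frozen=True)
class VPKernel:
    """One de la Vallée Poussin kernel: mean axis and 3D strength."""

    mean_axis: np.ndarray
    k3d: float

    def __post_init__(self) -> None:
        if self.k3d < 0:
            raise ValueError("VP orientation strength must be >= 0")
        object.__setattr__(self, "mean_axis", _as_unit(self.mean_axis, "mean_axis"))


@dataclass(frozen=True)
class VPParams:
    """Superposition of VP kernels; density is the equal-weight mixture."""

    kernels: tuple[VPKernel, ...]

    def __post_init__(self) -> None:
        kernels = tuple(self.kernels)
        if len(kernels) < 1:
            raise ValueError("at least one VP kernel is required")
        object.__setattr__(self, "kernels", kernels)

    @property
    def n_vp(self) -> int:
        return len(self.kernels)

    def pdf(self, directions: np.ndarray) -> np.ndarray:
        """Mixture density at unit vectors ``directions`` (n, 3)."""
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        dens = np.zeros(directions.shape[0])
        for ker in self.kernels:
            c2 = (directions @ ker.mean_axis) ** 2
            dens += (2 * ker.k3d + 1) / (4 * math.pi) * c2**ker.k3d
        return dens / self.n_vp


@dataclass(frozen=True)
class VMFParams:
    """von Mises-Fisher distribution on the sphere: exp(kappa * n·m)."""

    mean_dir: np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("VMF concentration kappa must be >= 0")
        object.__setattr__(self, "mean_dir", _as_unit(self.mean_dir, "mean_dir"))


@dataclass(frozen=True)
class SamplingDomain:
    """Interval [lower, upper] over which rejection proposals are drawn.

    For infinite-support densities use mean +/- 6 sigma; for finite support
    the support bounds; for histograms the outer bin edges.
    """

    lower: float
    upper: float
    source: str = "continuous"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("sampling domain requires lower < upper")

    @classmethod
    def from_moments(cls, mean: float, std: float, lower_support: float | None = None,
                     upper_support: float | None = None) -> "SamplingDomain":
        a = mean - 6 * std if lower_support is None else lower_support
        b = mean + 6 * std if upper_support is None else upper_support
        return cls(a, b, "continuous")


def gamma_params_from_moments(mean: float, std: float) -> GammaParams:
    """Moment-match a gamma distribution: k = mean²/std², theta = std²/mean."""
    if mean <= 0 or std <= 0:
        raise ValueError("mean and std must be positive")
    return GammaParams(k_shape=mean**2 / std**2, theta_scale=std**2 / mean)


def lognormal_params_from_moments(mean_tau: float, std_tau: float) -> TruncatedLognormalParams:
    """Moment-match a lognormal to mean/std of tortuosity, truncated at 1.

    Uses ``m = ln(mu²/sqrt(sigma²+mu²))`` and ``s = sqrt(ln(1+sigma²/mu²))``.
    Because the support is cut at tau = 1 these are only approximate for the
    truncated density; a log record flags this.
    """
    if mean_tau < 1:
        raise ValueError("mean tortuosity must be >= 1")
    if std_tau < 0:
        raise ValueError("std of tortuosity must be >= 0")
    if std_tau == 0:
        return TruncatedLognormalParams(m_ln=math.log(mean_tau), s_ln=0.0)
    var = std_tau**2
    m_ln = math.log(mean_tau**2 / math.sqrt(var + mean_tau**2))
    s_ln = math.sqrt(math.log(1 + var / mean_tau**2))
    logger.info(
        "lognormal moment matching with truncation at tau=1 is approximate "
        "(mean=%.4g, std=%.4g)", mean_tau, std_tau,
    )
    return TruncatedLognormalParams(m_ln=m_ln, s_ln=s_ln)


class HistogramDensity:
    """Linearly interpolated histogram usable as a rejection-sampling target.

    ``bin_centers`` and ``values`` are the two columns of the text format;
    the density is zero outside the outer bin edges (edges inferred from
    the outermost bin spacing).
    """

    def __init__(self, bin_centers: Sequence[float], values: Sequence[float]):
        centers = np.asarray(bin_centers, dtype=float)
        vals = np.asarray(values, dtype=float)
        if centers.ndim != 1 or centers.size < 1 or centers.shape != vals.shape:
            raise ValueError("histogram needs matching 1-D centers and values")
        if np.any(vals < 0):
            raise ValueError("histogram values must be nonnegative")
        order = np.argsort(centers)
        self.centers = centers[order]
        self.values = vals[order]
        if self.centers.size > 1:
            dl = self.centers[1] - self.centers[0]
            dr = self.centers[-1] - self.centers[-2]
        else:
            dl = dr = 1.0
        self.lower = self.centers[0] - dl / 2
        self.upper = self.centers[-1] + dr / 2

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.centers, self.values,
                         left=0.0, right=0.0)

    @property
    def domain(self) -> SamplingDomain:
        return SamplingDomain(self.lower, self.upper, "histogram")

    @property
    def max_value(self) -> float:
        return float(self.values.max())


def sample_rejection(
    target: Callable[[np.ndarray], np.ndarray],
    domain: SamplingDomain,
    n: int,
    rng: np.random.Generator,
    target_max: float | None = None,
    max_batches: int = 10_000,
) -> np.ndarray:
    """Draw ``n`` scalars from an unnormalized density by rejection.

    Proposals are uniform over the domain; a proposal x' is accepted when a
    second uniform draw p' on [0, max(target)] falls below target(x').
    ``target_max`` may be supplied when known; otherwise it is estimated on
    a dense grid over the domain.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    a, b = domain.lower, domain.upper
    if target_max is None:
        if isinstance(target, HistogramDensity):
            target_max = target.max_value
        else:
            grid = np.linspace(a, b, 4097)
            vals = np.asarray(target(grid), dtype=float)
            if np.any(~np.isfinite(vals)):
                raise ValueError("target density is unbounded on the domain")
            target_max = float(vals.max()) * 1.0001
    if not np.isfinite(target_max):
        raise ValueError("target density is unbounded on the domain")
    if target_max <= 0:
        raise ValueError("target density has no mass on the domain")

    out = np.empty(n)
    filled = 0
    batch = max(int(n * 1.5), 1024)
    for _ in range(max_batches):
        if filled >= n:
            break
        x = rng.uniform(a, b, size=batch)
        p = rng.uniform(0.0, target_max, size=batch)
        acc = x[p < np.asarray(target(x), dtype=float)]
        take = min(acc.size, n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    if filled < n:
        raise RuntimeError("rejection sampling failed to accept enough samples")
    return out


def sample_uniform_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vectors via normalized Gaussian triples."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_vp(params: VPParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` unit vectors from a VP kernel mixture.

    Proposals are uniform on the sphere; the envelope is the mixture density
    at perfect alignment, sum_i (2k_i+1)/(4πN), which is exact (per-kernel
    acceptance >= 1/(2k+1)).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    env = sum((2 * k.k3d + 1) / (4 * math.pi) for k in params.kernels) / params.n_vp
    out = np.empty((n, 3))
    filled = 0
    batch = max(int(n * 1.5), 1024)
    while filled < n:
        cand = sample_uniform_sphere(batch, rng)
        p = rng.uniform(0.0, env, size=batch)
        acc = cand[p < params.pdf(cand)]
        take = min(acc.shape[0], n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def sample_vmf(params: VMFParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit vectors from a von Mises-Fisher distribution.

    Uses the exact inverse-CDF of the polar cosine,
    ``w = 1 + log(u + (1-u) e^(-2κ)) / κ``, written in a form that is stable
    for large κ, plus a uniform azimuth, then rotates the pole onto the mean
    direction.  κ = 0 reduces to the uniform sphere.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    kappa = params.kappa
    if kappa == 0:
        return sample_uniform_sphere(n, rng)
    u = rng.uniform(size=n)
    # w = 1 + (1/k) * log(u + (1-u) exp(-2k)), evaluated via log1p for stability
    w = 1.0 + np.log1p(-(1.0 - u) * -np.expm1(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.uniform(0.0, 2 * math.pi, size=n)
    s = np.sqrt(np.maximum(0.0, 1.0 - w**2))
    local = np.column_stack((s * np.cos(phi), s * np.sin(phi), w))
    return local @ _rotation_from_z(params.mean_dir).T


def _rotation_from_z(target: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto the unit vector ``target``."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, target))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, target)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def vp_norm_2d(k2d: float) -> float:
    """Normalization of the in-plane VP density on [0, π): Γ(k+1)/(√π Γ(k+1/2))."""
    return math.exp(gammaln(k2d + 1.0) - gammaln(k2d + 0.5)) / math.sqrt(math.pi)


def vp_pdf_2d(theta: np.ndarray | float,
              kernels2d: Sequence[tuple[float, float]]) -> np.ndarray:
    """In-plane VP mixture density at angles ``theta`` (radians, [0, π)).

    Each kernel is ``(theta_vp, k2d)`` with density
    ``C(k) cos(theta-theta_vp)^(2k)``, C(k) = Γ(k+1)/(√π Γ(k+1/2)); the
    equal-weight mixture integrates to 1 over [0, π).
    """
    theta = np.asarray(theta, dtype=float)
    dens = np.zeros_like(theta, dtype=float)
    n = len(kernels2d)
    if n < 1:
        raise ValueError("at least one 2D kernel is required")
    for theta_vp, k2d in kernels2d:
        if k2d < 0:
            raise ValueError("k2d must be >= 0")
        dens += vp_norm_2d(k2d) * (np.cos(theta - theta_vp) ** 2) ** k2d
    return dens / n


# Floor for gamma diameter draws, as a fraction of the mean: redraw values
# below floor_frac * mean so the pore voxel grid (edge = min diameter / 5)
# stays bounded.  Set floor_frac=0 to disable (strict mode).
DEFAULT_DIAMETER_FLOOR_FRAC = 0.2


def sample_gamma_rejection(
    params: GammaParams,
    n: int,
    rng: np.random.Generator,
    floor: float = 0.0,
) -> np.ndarray:
    """Sample a gamma via the generic rejection sampler, with optional floor.

    Values below ``floor`` are redrawn (used for fiber diameters so that the
    smallest diameter does not force an unboundedly fine voxel grid).
    """
    lo = max(floor, 0.0)
    domain = SamplingDomain(lo, params.mean + 6 * params.std)
    if params.k_shape >= 1:
        mode = (params.k_shape - 1) * params.theta_scale
        peak = float(params.pdf(np.array([max(mode, lo)]))[0])
    else:
        # density unbounded at 0; bound it just inside the domain
        if lo <= 0:
            raise ValueError("gamma with shape < 1 needs a positive floor")
        peak = float(params.pdf(np.array([lo]))[0])
    return sample_rejection(params.pdf, domain, n, rng, target_max=peak * 1.0001)
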