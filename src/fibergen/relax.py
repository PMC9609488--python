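"""Non-penetration enforcement by damped bead-spring dynamics.

Each fiber is discretized as a chain of spherical particles at the spline
points.  Harmonic bonds hold neighbor spacing at its initial value, cosine
angle forces hold the initial bend angles, a soft finite-range contact force
pushes non-bonded particles apart when their surfaces overlap, and Stokes
drag dissipates energy so the system settles into a non-penetrating, lower
energy configuration.  Positions are advanced with velocity Verlet under
periodic boundary conditions; fiber ends are pinned for an initial phase to
suppress rigid rotations while the largest overlaps resolve.

Forces (r_ij = x_i - x_j, R_ij = |r_ij|):

* bond:    f_i = -2 k_b (R_ij - R_0) r̂_ij, with k_b = E A / R_0;
* angle:   f_i = k_θ sin(θ - θ_0) · unit((r_ij × r_kj) × r_ij) (and the
  mirrored form on k, reaction on j), with k_θ = E I / R_0, I = π d⁴/32;
* contact: f_i = (π k_c / R_c) sin(π R_ij / R_c) r̂_ij for R_ij < R_c,
  R_c = (d_i + d_j)/2 — a soft core that vanishes at zero separation so
  deeply overlapped initial states do not explode;
* drag:    f = -3π η d v (Stokes).

Progress is tracked by the percent fiber overlap (PFO): total pairwise
sphere-sphere lens volume over total sphere volume × 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from fibergen.network import FiberNetwork
from fibergen.tortuosity import FiberPath, measure_tortuosity

logger = logging.getLogger(__name__)


@dataclass
class MechanicsParams:
    """Physical and numerical parameters of the damped relaxation.

    Units are normalized: only the relaxed geometry matters, so the elastic
    modulus and particle mass are set to 1 and the viscosity is chosen to
    give a near-critically damped bond dimer (fast settling).  ``dt`` is
    derived from the stiffest bond when left as None: dt = 0.02 √(m/k_b,max).
    """

    youngs: float = 1.0
    poisson: float = 0.3
    viscosity: float | None = None  # None: derive from damping_ratio
    damping_ratio: float = 0.5  # bond-dimer damping ratio when viscosity is None
    particle_mass: float = 1.0
    dt: float | None = None
    fixed_end_steps: int = 10_000
    max_steps: int = 100_000
    stop_tolerance: float = 1e-3
    stop_window: int = 2000
    pfo_every: int = 100
    standard_second_moment: bool = False  # True: I = pi d^4/64 instead of /32
    kc_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.youngs <= 0 or self.particle_mass <= 0:
            raise ValueError("physical parameters must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


def stiffness_from_elasticity(
    E: float,
    nu: float,
    df_i: float,
    df_j: float | None = None,
    R0: float = 1.0,
    standard_second_moment: bool = False,
) -> tuple[float, float, float]:
    """Bond, angle, and contact stiffness from linear elasticity.

    k_b = E·(π/4 d²)/R_0;  k_θ = E·I/R_0 with I = π d⁴/32 (or the standard
    π d⁴/64);  k_c = (E/16)·ν^(1/3)·√R with 1/R = 1/d_i + 1/d_j (a
    Hertz-like soft-contact scale; the relaxation outcome is insensitive to
    its prefactor).
    """
    if E <= 0 or nu <= 0 or df_i <= 0 or R0 <= 0:
        raise ValueError("elasticity inputs must be positive")
    df_j = df_i if df_j is None else df_j
    area = math.pi / 4.0 * df_i**2
    denom = 64.0 if standard_second_moment else 32.0
    inertia = math.pi / denom * df_i**4
    kb = E * area / R0
    ktheta = E * inertia / R0
    r_eff = 1.0 / (1.0 / df_i + 1.0 / df_j)
    kc = E / 16.0 * nu ** (1.0 / 3.0) * math.sqrt(r_eff)
    return kb, ktheta, kc


@dataclass
class ParticleSystem:
    """Bead-chain state for the whole network (flat particle arrays).

    ``positions`` are kept unwrapped (continuous per fiber) so lengths and
    tortuosities remain directly measurable; periodic images are taken via
    the minimum-image convention in all pair interactions, and a wrapped
    copy feeds the neighbor search.
    """

    positions: np.ndarray           # (N, 3), unwrapped
    radii: np.ndarray               # (N,)
    box_length: float
    fiber_slices: list[slice]       # particle index range per fiber
    bonds_i: np.ndarray
    bonds_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_theta0: np.ndarray
    ang_stiff: np.ndarray
    masses: np.ndarray
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]
    fixed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded_keys: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        if self.fixed_mask is None:
            mask = np.zeros(n, dtype=bool)
            for s in self.fiber_slices:
                mask[s.start] = True
                mask[s.stop - 1] = True
            self.fixed_mask = mask
        if self.excluded_keys is None:
            # contact exclusions: bonded pairs and 1-3 pairs of angle trios
            pairs_i = np.concatenate([self.bonds_i, self.ang_i])
            pairs_j = np.concatenate([self.bonds_j, self.ang_k])
            lo = np.minimum(pairs_i, pairs_j).astype(np.int64)
            hi = np.maximum(pairs_i, pairs_j).astype(np.int64)
            self.excluded_keys = np.unique(lo * n + hi)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box_length)

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        L = self.box_length
        return d - L * np.rint(d / L)

    def fiber_paths(self) -> list[FiberPath]:
        """Per-fiber polylines at the current (unwrapped) positions."""
        return [
            FiberPath(self.positions[s], diameter=float(2 * self.radii[s.start]))
            for s in self.fiber_slices
        ]


def particle_system_from_network(
    network: FiberNetwork,
    params: MechanicsParams | None = None,
) -> ParticleSystem:
    """Discretize a network into a bead-spring particle system.

    Bond rest lengths and angle rest values are the initial spacings and
    angles of the spline points, so the freshly built system is force-free
    apart from contacts.
    """
    params = params or MechanicsParams()
    positions, radii, slices = [], [], []
    bi, bj, br0, bk = [], [], [], []
    ai, aj, ak, at0, akth = [], [], [], [], []
    offset = 0
    for fiber in network.fibers:
        pts = np.asarray(fiber.points, dtype=float)
        n = pts.shape[0]
        positions.append(pts)
        radii.append(np.full(n, fiber.diameter / 2.0))
        slices.append(slice(offset, offset + n))
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        kb_f, kth_f, _ = stiffness_from_elasticity(
            params.youngs, params.poisson, fiber.diameter, fiber.diameter,
            R0=float(np.mean(seg_len)),
            standard_second_moment=params.standard_second_moment,
        )
        idx = np.arange(offset, offset + n)
        bi.extend(idx[:-1]); bj.extend(idx[1:])
        br0.extend(seg_len); bk.extend([kb_f] * (n - 1))
        if n >= 3:
            v1 = -seg[:-1]  # r_ij: from center j to i
            v2 = seg[1:]    # r_kj: from center j to k
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            theta0 = np.arccos(np.clip(cosang, -1.0, 1.0))
            ai.extend(idx[:-2]); aj.extend(idx[1:-1]); ak.extend(idx[2:])
            at0.extend(theta0); akth.extend([kth_f] * (n - 2))
        offset += n
    pos = np.vstack(positions)
    system = ParticleSystem(
        positions=pos,
        radii=np.concatenate(radii),
        box_length=network.spec.box_length,
        fiber_slices=slices,
        bonds_i=np.asarray(bi, dtype=np.int64),
        bonds_j=np.asarray(bj, dtype=np.int64),
        bond_r0=np.asarray(br0, dtype=float),
        bond_k=np.asarray(bk, dtype=float),
        ang_i=np.asarray(ai, dtype=np.int64),
        ang_j=np.asarray(aj, dtype=np.int64),
        ang_k=np.asarray(ak, dtype=np.int64),
        ang_theta0=np.asarray(at0, dtype=float),
        ang_stiff=np.asarray(akth, dtype=float),
        masses=np.full(pos.shape[0], params.particle_mass),
    )
    return system



def _scatter_add(out: np.ndarray, idx: np.ndarray, vec: np.ndarray) -> None:
    """Accumulate rows of ``vec`` into ``out`` at ``idx`` (bincount-based)."""
    n = out.shape[0]
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vec[:, k], minlength=n)


def bond_forces(system: ParticleSystem, out: np.ndarray | None = None) -> np.ndarray:
    """Accumulate harmonic bond forces: f_i = -2 k_b (R - R_0) r̂."""
    out = np.zeros_like(system.positions) if out is None else out
    if system.bonds_i.size == 0:
        return out
    d = system.positions[system.bonds_i] - system.positions[system.bonds_j]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(r < 1e-14) or not np.all(np.isfinite(r)):
        raise FloatingPointError("coincident bonded particles (singular geometry)")
    f = (-2.0 * system.bond_k * (r - system.bond_r0) / r)[:, None] * d
    _scatter_add(out, system.bonds_i, f)
    _scatter_add(out, system.bonds_j, -f)
    return out


def angle_forces(system: ParticleSystem, out: np.ndarray | None = None,
                 collinear_tol: float = 1e-8) -> np.ndarray:
    """Accumulate cosine angle forces on each (i, j, k) trio.

    f_i = k_θ sin(θ-θ_0) unit((r_ij × r_kj) × r_ij), mirrored on k, with the
    reaction -f_i - f_k on the center j so each trio's forces sum to zero.
    Collinear arms (undefined force plane) are regularized by an arbitrary
    perpendicular direction.
    """
    out = np.zeros_like(system.positions) if out is None else out
    if system.ang_j.size == 0:
        return out
    rij = system.positions[system.ang_i] - system.positions[system.ang_j]
    rkj = system.positions[system.ang_k] - system.positions[system.ang_j]
    nij = np.sqrt(np.einsum("ij,ij->i", rij, rij))
    nkj = np.sqrt(np.einsum("ij,ij->i", rkj, rkj))
    cross = np.cross(rij, rkj)
    sin_abs = np.sqrt(np.einsum("ij,ij->i", cross, cross)) / (nij * nkj)
    cosang = np.einsum("ij,ij->i", rij, rkj) / (nij * nkj)
    theta = np.arctan2(sin_abs, cosang)

    collinear = sin_abs < collinear_tol
    if np.any(collinear):
        # arbitrary perpendicular to rij for degenerate trios
        ref = np.zeros_like(rij[collinear])
        ref[:, 0] = 1.0
        alt = np.abs(rij[collinear, 0]) > 0.9 * nij[collinear]
        ref[alt] = np.array([0.0, 1.0, 0.0])
        cross[collinear] = np.cross(rij[collinear], ref)

    di = np.cross(cross, rij)
    dk = np.cross(-cross, rkj)
    di /= np.maximum(np.sqrt(np.einsum("ij,ij->i", di, di)), 1e-300)[:, None]
    dk /= np.maximum(np.sqrt(np.einsum("ij,ij->i", dk, dk)), 1e-300)[:, None]
    amp = (system.ang_stiff * np.sin(theta - system.ang_theta0))[:, None]
    fi = amp * di
    fk = amp * dk
    _scatter_add(out, system.ang_i, fi)
    _scatter_add(out, system.ang_k, fk)
    _scatter_add(out, system.ang_j, -(fi + fk))
    return out


class NeighborList:
    """Periodic fixed-radius pair list with a displacement skin.

    Pairs are found with a cKDTree over wrapped positions (periodic
    ``boxsize``); the list is rebuilt only when some particle has moved more
    than half the skin since the last build.  Excluded (bonded / angle-trio)
    pairs are filtered out once per build.
    """

    def __init__(self, system: ParticleSystem, skin_frac: float = 0.3):
        self.rc_max = float(2.0 * system.radii.max())
        self.skin = skin_frac * self.rc_max
        self.pairs_i: np.ndarray = np.empty(0, dtype=np.int64)
        self.pairs_j: np.ndarray = np.empty(0, dtype=np.int64)
        self._ref_positions: np.ndarray | None = None
        self.rebuild(system)

    def rebuild(self, system: ParticleSystem) -> None:
        L = system.box_length
        wrapped = np.mod(system.positions, L)
        # cKDTree requires strictly < boxsize
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
        pairs = tree.query_pairs(self.rc_max + self.skin, output_type="ndarray")
        if pairs.size:
            n = system.n_particles
            keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
            keep = ~np.isin(keys, system.excluded_keys)
            pairs = pairs[keep]
        self.pairs_i = pairs[:, 0] if pairs.size else np.empty(0, dtype=np.int64)
        self.pairs_j = pairs[:, 1] if pairs.size else np.empty(0, dtype=np.int64)
        self._ref_positions = system.positions.copy()

    def maybe_rebuild(self, system: ParticleSystem) -> None:
        disp = system.positions - self._ref_positions
        if disp.size and float(np.max(np.abs(disp))) > self.skin / 2.0:
            self.rebuild(system)


def contact_forces(
    system: ParticleSystem,
    neighbor: NeighborList,
    E: float = 1.0,
    nu: float = 0.3,
    kc_scale: float = 1.0,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulate soft contact forces over non-excluded overlapping pairs.

    Magnitude (π k_c / R_c) sin(π R / R_c) for R < R_c = r_i + r_j, repulsive
    along the minimum-image separation; zero at and beyond the cutoff and at
    zero separation (soft core).
    """
    out = np.zeros_like(system.positions) if out is None else out
    i, j = neighbor.pairs_i, neighbor.pairs_j
    if i.size == 0:
        return out
    d = system.minimum_image(system.positions[i] - system.positions[j])
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    rc = system.radii[i] + system.radii[j]
    hit = r < rc
    if not np.any(hit):
        return out
    i, j, d, r, rc = i[hit], j[hit], d[hit], r[hit], rc[hit]
    di, dj = 2.0 * system.radii[i], 2.0 * system.radii[j]
    r_eff = 1.0 / (1.0 / di + 1.0 / dj)
    kc = kc_scale * E / 16.0 * nu ** (1.0 / 3.0) * np.sqrt(r_eff)
    mag = math.pi * kc / rc * np.sin(math.pi * r / rc)
    safe = np.maximum(r, 1e-12)
    f = (mag / safe)[:, None] * d
    _scatter_add(out, i, f)
    _scatter_add(out, j, -f)
    return out


def drag_forces(system: ParticleSystem, eta: float,
                velocities: np.ndarray | None = None,
                out: np.ndarray | None = None) -> np.ndarray:
    """Stokes drag: f = -3π η d v per particle."""
    out = np.zeros_like(system.positions) if out is None else out
    v = system.velocities if velocities is None else velocities
    out -= (3.0 * math.pi * eta * 2.0 * system.radii)[:, None] * v
    return out


def _lens_volumes(r: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Sphere-sphere intersection (lens) volume for center distance r."""
    vol = np.zeros_like(r)
    rmin = np.minimum(r1, r2)
    rmax = np.maximum(r1, r2)
    contained = r <= rmax - rmin
    vol[contained] = 4.0 / 3.0 * math.pi * rmin[contained] ** 3
    partial = (~contained) & (r < r1 + r2)
    if np.any(partial):
        d = r[partial]
        a, b = r1[partial], r2[partial]
        vol[partial] = (
            math.pi
            * (a + b - d) ** 2
            * (d**2 + 2 * d * (a + b) - 3 * (a - b) ** 2)
            / (12 * d)
        )
    return vol


def percent_fiber_overlap(system: ParticleSystem,
                          neighbor: NeighborList | None = None) -> float:
    """Total pairwise lens volume over total particle volume, ×100.

    Excluded (bonded / angle-trio) pairs are not counted: neighbor beads of
    a chain overlap by construction and do not represent fiber penetration.
    """
    if neighbor is None:
        neighbor = NeighborList(system)
    else:
        neighbor.maybe_rebuild(system)
    total = float(np.sum(4.0 / 3.0 * math.pi * system.radii**3))
    i, j = neighbor.pairs_i, neighbor.pairs_j
    if i.size == 0:
        return 0.0
    d = system.minimum_image(system.positions[i] - system.positions[j])
    r = np.linalg.norm(d, axis=1)
    lens = _lens_volumes(r, system.radii[i], system.radii[j])
    return float(lens.sum() / total * 100.0)


def _auto_eta(system: ParticleSystem, zeta: float = 0.5) -> float:
    """Viscosity giving a bond-dimer damping ratio ≈ zeta.

    The stretched dimer obeys μ s̈ = -4 k_b s - c ṡ with μ = m/2 and
    c = 3π η d; ζ = c / (2 √(4 k_b μ)).
    """
    kb = float(np.max(system.bond_k)) if system.bond_k.size else 1.0
    m = float(np.mean(system.masses))
    d = float(np.mean(2.0 * system.radii))
    c = 2.0 * zeta * math.sqrt(4.0 * kb * (m / 2.0))
    return c / (3.0 * math.pi * d)


def _auto_dt(system: ParticleSystem, factor: float = 0.02) -> float:
    kb_max = float(np.max(system.bond_k)) if system.bond_k.size else 1.0
    m_min = float(np.min(system.masses))
    return factor * math.sqrt(m_min / kb_max)


def step_velocity_verlet(
    system: ParticleSystem,
    params: MechanicsParams,
    neighbor: NeighborList,
    dt: float,
    eta: float,
    step_index: int = 0,
) -> None:
    """One velocity-Verlet step with bond+angle+contact+drag forces.

    Fixed particles (fiber ends while ``step_index < fixed_end_steps``) keep
    their position and zero velocity.  Drag at the end-of-step velocity is
    applied semi-implicitly, which is stable for strong damping.
    """
    fixed = system.fixed_mask if step_index < params.fixed_end_steps else None
    m = system.masses[:, None]
    f = _conservative_forces(system, params, neighbor)
    gamma = (3.0 * math.pi * eta * 2.0 * system.radii)[:, None]
    a = (f - gamma * system.velocities) / m
    if fixed is not None:
        a[fixed] = 0.0
        system.velocities[fixed] = 0.0
    v_half = system.velocities + 0.5 * dt * a
    system.positions += dt * v_half
    neighbor.maybe_rebuild(system)
    f2 = _conservative_forces(system, params, neighbor)
    # semi-implicit drag: v = (v_half + dt/2 f2/m) / (1 + dt/2 gamma/m)
    v_new = (v_half + 0.5 * dt * f2 / m) / (1.0 + 0.5 * dt * gamma / m)
    if fixed is not None:
        v_new[fixed] = 0.0
    system.velocities = v_new
    if not np.all(np.isfinite(system.positions)):
        raise FloatingPointError(f"integration diverged (dt={dt:g} too large)")


def _conservative_forces(system: ParticleSystem, params: MechanicsParams,
                         neighbor: NeighborList) -> np.ndarray:
    f = bond_forces(system)
    angle_forces(system, out=f)
    contact_forces(system, neighbor, E=params.youngs, nu=params.poisson,
                   kc_scale=params.kc_scale, out=f)
    return f


@dataclass
class ChangeReport:
    """Per-fiber absolute percent changes caused by the relaxation."""

    length_pct: np.ndarray
    tau_pct: np.ndarray
    orientation_pct: np.ndarray  # angle change / 90 deg * 100

    @property
    def means(self) -> dict:
        return {
            "length": float(np.mean(self.length_pct)),
            "tau": float(np.mean(self.tau_pct)),
            "orientation": float(np.mean(self.orientation_pct)),
        }


@dataclass
class RelaxResult:
    system: ParticleSystem
    pfo_trace: np.ndarray  # (n_records, 2): step, PFO
    change: ChangeReport
    n_steps: int
    converged: bool


def relax(
    network: FiberNetwork,
    params: MechanicsParams | None = None,
) -> RelaxResult:
    """Run damped dynamics until the PFO plateaus or ``max_steps`` elapse.

    Returns the relaxed particle system, the PFO trace, and per-fiber change
    statistics (absolute percent change in contour length and tortuosity;
    orientation change as the rotation angle of the mean orientation divided
    by 90° × 100 — the reference angle is a convention, recorded here, since
    no canonical denominator exists for an angular percent change).
    """
    params = params or MechanicsParams()
    system = particle_system_from_network(network, params)
    before = [(measure_tortuosity(p), p.contour_length, p.mean_orientation)
              for p in system.fiber_paths()]
    neighbor = NeighborList(system)
    dt = params.dt if params.dt is not None else _auto_dt(system)
    eta = (params.viscosity if params.viscosity is not None
           else _auto_eta(system, zeta=params.damping_ratio))

    trace: list[tuple[int, float]] = []
    pfo0 = percent_fiber_overlap(system, neighbor)
    trace.append((0, pfo0))
    converged = False
    window_records = max(params.stop_window // max(params.pfo_every, 1), 2)
    step = 0
    halvings = 0
    while step < params.max_steps:
        snapshot = (system.positions.copy(), system.velocities.copy())
        try:
            step_velocity_verlet(system, params, neighbor, dt, eta, step_index=step)
        except FloatingPointError:
            halvings += 1
            if halvings > 20:
                raise
            dt *= 0.5
            logger.warning("instability detected; halving dt to %g", dt)
            system.positions, system.velocities = snapshot
            system.velocities[:] = 0.0
            neighbor.rebuild(system)
            continue
        step += 1
        if step % params.pfo_every == 0:
            pfo = percent_fiber_overlap(system, neighbor)
            trace.append((step, pfo))
            if step > params.fixed_end_steps and len(trace) > window_records:
                recent = trace[-window_records:]
                span = abs(recent[0][1] - recent[-1][1])
                if span < params.stop_tolerance * max(pfo0, 1e-12):
                    converged = True
                    break

    after = [(measure_tortuosity(p), p.contour_length, p.mean_orientation)
             for p in system.fiber_paths()]
    tau_pct, len_pct, ori_pct = [], [], []
    for (tau0, l0, n0), (tau1, l1, n1) in zip(before, after):
        tau_pct.append(abs(tau1 - tau0) / tau0 * 100.0)
        len_pct.append(abs(l1 - l0) / l0 * 100.0)
        cosang = abs(float(np.dot(n0, n1)))  # antipodal-symmetric
        ang = math.degrees(math.acos(min(cosang, 1.0)))
        ori_pct.append(ang / 90.0 * 100.0)
    change = ChangeReport(
        length_pct=np.asarray(len_pct),
        tau_pct=np.asarray(tau_pct),
        orientation_pct=np.asarray(ori_pct),
    )
    return RelaxResult(system=system, pfo_trace=np.asarray(trace, dtype=float),
                       change=change, n_steps=step, converged=converged)
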