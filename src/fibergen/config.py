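"""Validated run configuration (YAML) for the command-line interface.

A run config bundles the network prescription, mechanics parameters, pore
analysis options, mode flags, and the seed.  Validation is pydantic-based;
configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from fibergen.distributions import (
    VPKernel,
    VPParams,
    lognormal_params_from_moments,
)
from fibergen.network import NetworkSpec
from fibergen.relax import MechanicsParams


class KernelConfig(BaseModel):
    """One VP kernel: mean axis (any nonzero 3-vector) and strength k3d >= 0."""

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    k3d: float = 0.0

    @field_validator("k3d")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("k3d must be >= 0")
        return v


class OrientationConfig(BaseModel):
    kernels: list[KernelConfig] = Field(default_factory=lambda: [KernelConfig()])
    histogram_file: Optional[str] = None  # degrees; overrides kernels when set
    psi_deg: float = 0.0
    scaling_mode: Literal["table", "literal"] = "table"


class TortuosityConfig(BaseModel):
    mean: float = 1.2
    std: float = 0.1
    histogram_file: Optional[str] = None  # takes precedence when set

    @field_validator("mean")
    @classmethod
    def _ge_one(cls, v: float) -> float:
        if v < 1:
            raise ValueError("mean tortuosity must be >= 1")
        return v


class NetworkConfig(BaseModel):
    box_length: float = 20.0
    volume_fraction: float = 0.1
    diameter_mean: float = 1.0
    diameter_std: float = 0.1
    length_mean: float = 10.0
    length_std: float = 1.0
    beta: float = 20.0
    spline_step: Optional[float] = None
    diameter_floor_frac: float = 0.2
    tau_tol: float = 0.05
    orientation: OrientationConfig = Field(default_factory=OrientationConfig)
    tortuosity: TortuosityConfig = Field(default_factory=TortuosityConfig)

    @model_validator(mode="after")
    def _check(self) -> "NetworkConfig":
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must lie in (0, 1)")
        if self.diameter_mean <= 0 or self.length_mean <= 0:
            raise ValueError("mean diameter and length must be positive")
        return self


class MechanicsConfig(BaseModel):
    youngs: float = 1.0
    poisson: float = 0.3
    viscosity: Optional[float] = None
    particle_mass: float = 1.0
    dt: Optional[float] = None
    fixed_end_steps: int = 10_000
    max_steps: int = 100_000
    stop_tolerance: float = 1e-3
    stop_window: int = 2000
    standard_second_moment: bool = False


class PoreConfig(BaseModel):
    voxel_edge: Optional[float] = None  # default: min diameter / 5
    convention: Literal["diameter", "radius"] = "radius"
    max_voxels: int = 512**3


class RunConfig(BaseModel):
    """Top-level configuration for a generate/relax/pores run."""

    seed: int = 0
    outdir: str = "fibergen_out"
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    mechanics: MechanicsConfig = Field(default_factory=MechanicsConfig)
    pores: PoreConfig = Field(default_factory=PoreConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def network_spec(self) -> NetworkSpec:
        """Materialize the validated config into a NetworkSpec."""
        from fibergen.io import read_histogram
        from fibergen.orientation import correct_k2d_to_k3d, fit_vp_2d

        net = self.network
        ori = net.orientation
        if ori.histogram_file:
            hist = read_histogram(ori.histogram_file, angles_in_degrees=True)
            fit = fit_vp_2d(hist.centers, hist.values, n_vp=max(len(ori.kernels), 1))
            kernels = []
            for theta, k2d in fit.kernels2d:
                k3d = correct_k2d_to_k3d(k2d, n_vp=fit.n_vp,
                                         psi=math.radians(ori.psi_deg),
                                         scaling_mode=ori.scaling_mode)
                kernels.append(VPKernel([math.cos(theta), math.sin(theta), 0.0], k3d))
            orientation = VPParams(tuple(kernels))
        else:
            orientation = VPParams(tuple(
                VPKernel(k.axis, k.k3d) for k in ori.kernels
            ))
        tort_cfg = net.tortuosity
        if tort_cfg.histogram_file:
            from fibergen.io import read_histogram as _rh

            tortuosity = _rh(tort_cfg.histogram_file)
        else:
            tortuosity = lognormal_params_from_moments(tort_cfg.mean, tort_cfg.std)
        return NetworkSpec(
            box_length=net.box_length,
            volume_fraction=net.volume_fraction,
            diameter_mean=net.diameter_mean,
            diameter_std=net.diameter_std,
            length_mean=net.length_mean,
            length_std=net.length_std,
            orientation=orientation,
            tortuosity=tortuosity,
            beta=net.beta,
            spline_step=net.spline_step,
            diameter_floor_frac=net.diameter_floor_frac,
            tau_tol=net.tau_tol,
            seed=self.seed,
        )

    def mechanics_params(self) -> MechanicsParams:
        m = self.mechanics
        return MechanicsParams(
            youngs=m.youngs, poisson=m.poisson, viscosity=m.viscosity,
            particle_mass=m.particle_mass, dt=m.dt,
            fixed_end_steps=m.fixed_end_steps, max_steps=m.max_steps,
            stop_tolerance=m.stop_tolerance, stop_window=m.stop_window,
            standard_second_moment=m.standard_second_moment,
        )
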