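"""Seeded synthetic "experimental-like" histogram fixtures.

Real studies digitize fiber-orientation polar plots and tortuosity
histograms from micrographs.  These generators synthesize such inputs from
known ground truth — 2D VP mixtures for orientations, truncated lognormals
for tortuosity — with multiplicative noise, so fitting and recovery can be
tested without any external data.  Every fixture writes a JSON sidecar with
the generating parameters.

The orientation cases mirror the four material archetypes commonly reported:
a nearly isotropic protein gel (one weak kernel), a hexagonal mineral-wool
lay-up (three kernels at 60°), an orthotropic cross-laid nonwoven (two
kernels at 90°), and an asymmetric collagenous tissue (two unequal kernels).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from fibergen.distributions import (
    TruncatedLognormalParams,
    lognormal_params_from_moments,
    vp_pdf_2d,
)
from fibergen.io import write_histogram

#: Case name → (kernel angles in degrees, per-kernel 2D strengths).
ORIENTATION_CASES = {
    "fibrin-like": ((90.0,), (0.98,)),
    "stonewool-like": ((30.0, 90.0, 150.0), (5.25, 5.25, 5.25)),
    "polyester-like": ((45.0, 135.0), (2.50, 2.50)),
    "collagen-like": ((60.0, 150.0), (4.00, 2.20)),
}

#: Case name → (mean tortuosity, std) spanning typical reported ranges.
TORTUOSITY_CASES = {
    "collagen-like": (1.05, 0.03),
    "sintered-metal-like": (1.35, 0.25),
    "fiberboard-like": (2.2, 0.45),
}


def make_orientation_fixture(
    case: str,
    path: str | Path,
    seed: int = 0,
    n_bins: int = 36,
    noise: float = 0.05,
) -> dict:
    """Write a noisy 2D-VP-mixture orientation histogram (degrees) + sidecar."""
    if case not in ORIENTATION_CASES:
        raise ValueError(f"unknown orientation case {case!r}; "
                         f"choose from {sorted(ORIENTATION_CASES)}")
    angles_deg, strengths = ORIENTATION_CASES[case]
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_bins) + 0.5) * math.pi / n_bins
    kernels = [(math.radians(a), k) for a, k in zip(angles_deg, strengths)]
    density = vp_pdf_2d(centers, kernels)
    noisy = density * rng.lognormal(0.0, noise, size=n_bins)
    write_histogram(path, centers, noisy,
                    header=f"synthetic orientation histogram, case={case}",
                    angles_in_degrees=True)
    truth = {
        "case": case,
        "kernel_angles_deg": list(angles_deg),
        "k2d": list(strengths),
        "n_vp": len(strengths),
        "seed": seed,
        "noise": noise,
    }
    Path(str(path) + ".truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def make_tortuosity_fixture(
    case: str,
    path: str | Path,
    seed: int = 0,
    n_bins: int = 30,
    noise: float = 0.05,
) -> dict:
    """Write a noisy truncated-lognormal tortuosity histogram + sidecar."""
    if case not in TORTUOSITY_CASES:
        raise ValueError(f"unknown tortuosity case {case!r}; "
                         f"choose from {sorted(TORTUOSITY_CASES)}")
    mean_tau, std_tau = TORTUOSITY_CASES[case]
    rng = np.random.default_rng(seed)
    params = lognormal_params_from_moments(mean_tau, std_tau)
    upper = mean_tau + 4 * std_tau
    centers = np.linspace(1.0, upper, n_bins + 1)
    centers = 0.5 * (centers[:-1] + centers[1:])
    density = params.pdf(centers)
    noisy = density * rng.lognormal(0.0, noise, size=n_bins)
    write_histogram(path, centers, noisy,
                    header=f"synthetic tortuosity histogram, case={case}")
    truth = {
        "case": case,
        "mean_tau": mean_tau,
        "std_tau": std_tau,
        "m_ln": params.m_ln,
        "s_ln": params.s_ln,
        "seed": seed,
        "noise": noise,
    }
    Path(str(path) + ".truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def make_all_fixtures(outdir: str | Path, seed: int = 0) -> list[str]:
    """Emit every orientation and tortuosity fixture into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, case in enumerate(ORIENTATION_CASES):
        p = outdir / f"orientation_{case.replace('-like','')}.tsv"
        make_orientation_fixture(case, p, seed=seed + i)
        written.append(str(p))
    for i, case in enumerate(TORTUOSITY_CASES):
        p = outdir / f"tortuosity_{case.replace('-like','')}.tsv"
        make_tortuosity_fixture(case, p, seed=seed + 100 + i)
        written.append(str(p))
    return written
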