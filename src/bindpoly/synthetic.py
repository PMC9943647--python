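"""Seeded generators emulating every experimental input at desk scale.

Each generator draws noise around the exact forward model of the stage it
feeds, so noiseless mode (noise parameter 0) reproduces the model to machine
precision and any recovery test has a known ground truth.  Defaults mirror
the emulated experiments: three-site titrations at 20 nM DNA over a 0.1-1.3
uM protein grid; single-site binding curves over 0.5-50 uM; SPR injections at
0.1-1 uM; chase time courses with a 5% background floor.

Noise models: ligation-state fractions are compositional, so they are drawn
from a Dirichlet with mean at the true fractions and concentration alpha
(larger alpha = tighter; alpha = 0 means noiseless) — independent Gaussians
would leave the simplex.  Unconstrained signals (bound fraction, Req,
intensities) get additive Gaussian noise, clipped to the physical range where
one exists.  Every generator takes a mandatory seed and is bit-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .affinity import BindingCurve, SPRSeries
from .binding_model import MacroscopicConstants, species_fractions
from .footprint import LaneProfile
from .kinetics import DecaySeries
from .multisite import TitrationDataset, _free_ligand

__all__ = [
    "TITRATION_GRID_UM",
    "SINGLE_SITE_GRID_UM",
    "SPR_GRID_UM",
    "simulate_titration",
    "simulate_binding_curve",
    "simulate_decay",
    "simulate_spr",
    "simulate_footprint",
]

#: default protein grid for the three-site cooperativity titration (uM)
TITRATION_GRID_UM = tuple(np.round(np.linspace(0.1, 1.3, 12), 6))
#: default grid for single-site mobility-shift curves (uM)
SINGLE_SITE_GRID_UM = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 35.0, 50.0)
#: default SPR injection series (uM)
SPR_GRID_UM = (0.1, 0.25, 0.5, 0.75, 1.0)

TITRATION_DNA_UM = 0.02  # 20 nM probe


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_titration(
    K: MacroscopicConstants,
    *,
    grid_uM: Sequence[float] = TITRATION_GRID_UM,
    dna_uM: float = TITRATION_DNA_UM,
    reps: int = 1,
    noise_alpha: float = 0.0,
    seed: int | np.random.Generator,
    ligand: str = "total",
) -> TitrationDataset:
    """Simulate replicated three-site titration fractions.

    True fractions come from the binding polynomial at each grid point; with
    ``ligand="total"`` the grid concentration is used as free ligand directly
    (consistent with the fitter's default), with ``"exact"`` the free
    concentration is solved from the mass balance first.  ``noise_alpha`` is
    the Dirichlet concentration (0 = exact fractions).
    """
    grid = np.asarray(list(grid_uM), dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("grid must be non-empty with concentrations >= 0")
    if noise_alpha < 0:
        raise ValueError(f"noise_alpha must be >= 0, got {noise_alpha}")
    rng = _rng(seed)
    rows = []
    for rep in range(1, reps + 1):
        for p in grid:
            L = _free_ligand(p, dna_uM, K) if ligand == "exact" else p
            theta = np.array(tuple(species_fractions(L, K)))
            if noise_alpha > 0:
                # Dirichlet support excludes exact zeros; floor the mean
                alpha = np.maximum(theta, 1e-9) * noise_alpha
                frac = rng.dirichlet(alpha)
            else:
                frac = theta
            rows.append((f"rep{rep}", p, dna_uM, *frac))
    df = pd.DataFrame(rows, columns=[
        "replicate", "protein_uM", "dna_uM", "f0", "f1", "f2", "f3"
    ])
    return TitrationDataset(df)


def simulate_binding_curve(
    Kd: float,
    Bmax: float = 1.0,
    *,
    grid_uM: Sequence[float] = SINGLE_SITE_GRID_UM,
    sigma: float = 0.0,
    seed: int | np.random.Generator,
    replicate: object = None,
) -> BindingCurve:
    """Hyperbolic single-site curve y = Bmax*x/(Kd+x) with Gaussian noise on y."""
    if Kd <= 0 or Bmax <= 0:
        raise ValueError("Kd and Bmax must be > 0")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    x = np.asarray(list(grid_uM), dtype=float)
    if x.size == 0 or np.any(x < 0):
        raise ValueError("grid must be non-empty with concentrations >= 0")
    rng = _rng(seed)
    y = Bmax * x / (Kd + x)
    if sigma > 0:
        y = np.clip(y + rng.normal(0.0, sigma, size=x.shape), 0.0, 1.0)
    return BindingCurve(x=x, y=y, replicate=replicate)


def simulate_decay(
    koff: float,
    f0: float = 0.5,
    background: float = 0.05,
    *,
    t_grid_s: Sequence[float] = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0),
    sigma: float = 0.0,
    seed: int | np.random.Generator,
) -> DecaySeries:
    """Chase series f(t) = (f0 - bg)*exp(-koff*t) + bg with Gaussian noise."""
    if koff <= 0:
        raise ValueError(f"koff must be > 0, got {koff}")
    t = np.asarray(list(t_grid_s), dtype=float)
    rng = _rng(seed)
    f = (f0 - background) * np.exp(-koff * t) + background
    if sigma > 0:
        f = np.clip(f + rng.normal(0.0, sigma, size=t.shape), 0.0, 1.0)
    return DecaySeries(t=t, f=f, background=background)


def simulate_spr(
    Kd: float,
    Rmax: float = 100.0,
    *,
    grid_uM: Sequence[float] = SPR_GRID_UM,
    sigma: float = 0.0,
    seed: int | np.random.Generator,
) -> SPRSeries:
    """Steady-state SPR responses Req = Rmax*c/(Kd+c) with Gaussian noise (RU)."""
    if Kd <= 0 or Rmax <= 0:
        raise ValueError("Kd and Rmax must be > 0")
    c = np.asarray(list(grid_uM), dtype=float)
    rng = _rng(seed)
    req = Rmax * c / (Kd + c)
    if sigma > 0:
        req = req + rng.normal(0.0, sigma, size=c.shape)
    return SPRSeries(conc=c, Req=req)


def simulate_footprint(
    protection: Sequence[float],
    sequence: str,
    *,
    strand: str = "top",
    baseline: float = 1000.0,
    sigma: float = 0.0,
    seed: int | np.random.Generator,
) -> tuple[LaneProfile, LaneProfile]:
    """Paired free/complexed lane profiles with known per-base protection factors.

    Free-lane intensities are log-normal around ``baseline`` (band intensities
    are positive and right-skewed); the complexed lane is the free lane times
    the per-base protection factor p_b (p_b < 1 protection, > 1 hyperexposure)
    with multiplicative Gaussian noise of relative size ``sigma``.
    """
    p = np.asarray(list(protection), dtype=float)
    if len(p) != len(sequence):
        raise ValueError("protection factors and sequence must have equal length")
    if np.any(p < 0):
        raise ValueError("protection factors must be >= 0")
    rng = _rng(seed)
    n = len(p)
    free_int = baseline * rng.lognormal(mean=0.0, sigma=0.25, size=n)
    noise = 1.0 + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)
    cplx_int = free_int * p * noise
    base_idx = np.arange(1, n + 1)
    free = LaneProfile(pd.DataFrame({
        "base_index": base_idx, "base": list(sequence),
        "strand": strand, "intensity": free_int,
    }))
    cplx = LaneProfile(pd.DataFrame({
        "base_index": base_idx, "base": list(sequence),
        "strand": strand, "intensity": cplx_int,
    }))
    return free, cplx
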