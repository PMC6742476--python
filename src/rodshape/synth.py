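"""Synthetic shape tables and lineages with the statistical structure the
analysis assumes.

Three generators:

* :func:`make_population_table` — condition-averaged S-V points with a
  power-law backbone ``S = gamma * V^beta`` and log-normal scatter, volumes
  log-uniform over two decades (balanced leverage for the log-log fit).
* :func:`make_newborn_table` — per-cell newborn rows whose aspect-ratio
  distribution is log-normal with condition-independent parameters, widths
  tied to the growth rate through ``w = 4k/beta(k)``.
* :func:`make_lineage_table` — one simulated lineage from the division
  model, with per-generation birth/division lengths and added length.

Default aspect-ratio parameters are calibrated so the arithmetic mean is
4.14 and the coefficient of variation ~14% (mu_log = log(4.14) - sigma^2/2,
sigma_log = 0.14) — a calibration to the published summary statistics of
rod-shaped cells, not a resampling of any raw dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geom
from .divider import CellState, DivisionEvent, ModelParams, advance_cell, steady_state_width, beta_of_k

__all__ = ["SynthSpec", "make_population_table", "make_newborn_table",
           "make_lineage_table"]

_DEFAULT_SIGMA_ETA = 0.14


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic-table generators."""

    n_conditions: int = 5
    cells_per_condition: int = 200
    volume_range: tuple[float, float] = (0.4, 40.0)   # um^3, log-uniform, 2 decades
    gamma: float = 6.24            # true prefactor
    exponent: float = 2.0 / 3.0    # true power-law exponent
    sigma_log: float = 0.05        # SD of log-scatter around the power law
    eta_mu_log: float = math.log(4.14) - _DEFAULT_SIGMA_ETA ** 2 / 2.0
    eta_sigma_log: float = _DEFAULT_SIGMA_ETA
    growth_rate_range: tuple[float, float] = (0.25, 2.0)  # h^-1
    width_sigma_log: float = 0.03  # newborn width noise (unit-mean log-normal)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.volume_range
        if not (0 < lo < hi):
            raise ValueError(f"volume_range must be positive and ordered, got {self.volume_range}")
        for name in ("sigma_log", "eta_sigma_log", "width_sigma_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_conditions < 1 or self.cells_per_condition < 1:
            raise ValueError("n_conditions and cells_per_condition must be >= 1")


def _condition_kappas(spec: SynthSpec) -> np.ndarray:
    lo, hi = spec.growth_rate_range
    if spec.n_conditions == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, spec.n_conditions)


def make_population_table(spec: SynthSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Population-level S-V table on a noisy power-law backbone.

    Volumes are drawn log-uniformly; conditions partition the volume range
    into contiguous log-bands, and each condition's growth rate follows the
    inverse nutrient growth law (log V linear in kappa) at its band centre.
    Surfaces are ``gamma * V^exponent * eps`` with log-normal ``eps``; rows
    whose implied prefactor falls below the sphere bound (possible under
    large scatter) are redrawn, with the count recorded in
    ``df.attrs["n_redrawn"]``.  Lengths and widths are back-solved per row so
    the table is exactly geometry-consistent.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    kappas = _condition_kappas(spec)
    log_lo, log_hi = np.log(spec.volume_range[0]), np.log(spec.volume_range[1])
    band_edges = np.linspace(log_lo, log_hi, spec.n_conditions + 1)
    n_redrawn = 0
    rows = []
    for i in range(spec.n_conditions):
        n = spec.cells_per_condition
        logV = rng.uniform(band_edges[i], band_edges[i + 1], size=n)
        V = np.exp(logV)
        S = spec.gamma * V ** spec.exponent * np.exp(rng.normal(0.0, spec.sigma_log, size=n))
        # redraw scatter for rows below the sphere prefactor
        bad = S / V ** (2.0 / 3.0) <= geom.GAMMA_SPHERE
        while np.any(bad):
            n_redrawn += int(bad.sum())
            S[bad] = (spec.gamma * V[bad] ** spec.exponent
                      * np.exp(rng.normal(0.0, spec.sigma_log, size=int(bad.sum()))))
            bad = S / V ** (2.0 / 3.0) <= geom.GAMMA_SPHERE
        for Vj, Sj in zip(V, S):
            eta = geom.eta_from_gamma_rod(Sj / Vj ** (2.0 / 3.0))
            shape = geom.rod_dimensions_from_volume(Vj, eta)
            rows.append({
                "condition": f"cond{i:02d}",
                "length_um": shape.length,
                "width_um": shape.width,
                "growth_rate_per_h": kappas[i],
                "surface_um2": Sj,
                "volume_um3": Vj,
                "geometry": "rod",
            })
    df = pd.DataFrame(rows)
    df.attrs["n_redrawn"] = n_redrawn
    df.attrs["seed"] = spec.seed
    return df


def make_newborn_table(spec: SynthSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cell newborn table with growth-rate-independent aspect ratios.

    Per condition, widths are ``4*kappa/beta(kappa)`` times unit-mean
    log-normal noise, and aspect ratios are log-normal with the *same*
    (mu_log, sigma_log) in every condition — the construction behind the
    observation that the newborn aspect-ratio distribution does not depend
    on growth rate.  Lengths are ``eta * w``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    kappas = _condition_kappas(spec)
    rows = []
    for i, kap in enumerate(kappas):
        n = spec.cells_per_condition
        g = np.exp(rng.normal(-spec.width_sigma_log ** 2 / 2.0, spec.width_sigma_log, size=n))
        w = 4.0 * kap / beta_of_k(kap) * g
        eta = np.exp(rng.normal(spec.eta_mu_log, spec.eta_sigma_log, size=n))
        eta = np.maximum(eta, 1.0)  # spherocylinder floor; ~never binds at defaults
        L = eta * w
        for Lj, wj in zip(L, w):
            rows.append({
                "condition": f"cond{i:02d}",
                "length_um": Lj,
                "width_um": wj,
                "growth_rate_per_h": kap,
                "surface_um2": np.nan,
                "volume_um3": np.nan,
                "geometry": "rod",
            })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    return df


def make_lineage_table(params: ModelParams | None = None, n_generations: int = 30,
                       seed: int = 0, dt: float | None = None) -> pd.DataFrame:
    """Simulate one lineage and tabulate per-generation cycle statistics.

    Columns: generation, birth_length_um, division_length_um, mean_width_um,
    delta_L_um, delta_L_over_w.  The added length per cycle is the adder
    quantity rho*pi*w*k/kP; at fixed parameters delta_L/w is constant up to
    integration error regardless of the division-asymmetry noise.
    """
    if params is None:
        params = ModelParams()
    if dt is None:
        dt = params.default_dt
    rng = np.random.default_rng(seed)
    w0 = steady_state_width(params) if params.evolve_width else 1.0
    L0 = params.eta_birth * w0
    state = CellState(L=L0, w=w0, Pc=params.Pstar, Pr=0.0, Pstar=params.Pstar)
    rows = []
    birth_L, birth_w = state.L, state.w
    while len(rows) < n_generations:
        state, event = advance_cell(state, params, dt, rng)
        if event is not None:
            mean_w = 0.5 * (birth_w + event.width)
            dL = event.mother_length - birth_L
            rows.append({
                "generation": len(rows),
                "birth_length_um": birth_L,
                "division_length_um": event.mother_length,
                "mean_width_um": mean_w,
                "delta_L_um": dL,
                "delta_L_over_w": dL / mean_w,
            })
            # next cycle starts at the crossing, not at the step boundary
            birth_L = event.daughter_fraction * event.mother_length
            birth_w = event.width
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    return df
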