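"""Ensemble simulations: steady state, nutrient shifts, and shape perturbations.

The ensemble is a fixed-size set of independent lineages with mother-machine
semantics: at each division one daughter is kept (division-fraction noise is
symmetric, so this is an unbiased random choice) and the other is discarded.
Tracking every descendant would grow the population exponentially; the
lineage ensemble has the same steady-state newborn statistics under this
noise model, at constant cost.

Lineages are initialised at a uniformly random phase of the analytic
division cycle at the pre-shift steady state and burned in for a configurable
number of generations before recording starts, which guarantees stationarity
of the pre-shift trace.  During a nutrient shift the elongation rate ``k``
changes as a step function; the surface-synthesis rate ``beta`` and the
production rate ``kP`` follow ``k`` instantaneously (both are derived from
``k`` unless explicitly overridden), so the steady-state newborn aspect
ratio ``rho*pi*k/kP`` is the same before and after the shift — the transient
in aspect ratio comes entirely from the lag between width relaxation and the
adder's length response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .divider import (
    ModelParams,
    _step_ensemble,
    beta_of_k,
    steady_state_width,
)
from . import geometry as geom

__all__ = [
    "Protocol",
    "PopulationTrace",
    "run_protocol",
    "run_ensemble",
    "run_ftsz_knockdown",
    "constant_eta_sweep",
    "run_mreb_depletion",
    "run_filamentation",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Protocol:
    """An ensemble protocol: who is simulated, for how long, and what shifts."""

    n_cells: int = 100_000       # ensemble size (reduce for tests)
    burn_in: int = 10            # generations discarded before recording
    k_pre: float = 0.75          # pre-shift elongation rate, h^-1
    k_post: Optional[float] = None  # post-shift rate; None = no shift
    t_shift: float = 0.0         # shift time, h
    duration: float = 12.0       # simulated time after t_shift, h
    record_start: float = -2.0   # start of the recorded window, h
    bin_minutes: float = 10.0    # newborn aspect-ratio bin width, min
    dt: float = 0.0025           # integrator step, h
    sample_every: int = 20       # population means recorded every this many steps
    max_length_um: float = 1000.0  # length cap (filamentation guard)
    perturbation: str = "none"   # none | ftsz_knockdown | mreb_depletion | filamentation

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.burn_in < 1:
            raise ValueError(f"burn_in must be >= 1, got {self.burn_in}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.bin_minutes <= 0:
            raise ValueError(f"bin_minutes must be > 0, got {self.bin_minutes}")
        if self.record_start > self.t_shift:
            raise ValueError("record_start must not be after t_shift")
        if self.perturbation not in ("none", "ftsz_knockdown", "mreb_depletion",
                                     "filamentation"):
            raise ValueError(f"unknown perturbation {self.perturbation!r}")


@dataclass
class PopulationTrace:
    """Recorded output of an ensemble run."""

    time_h: np.ndarray
    mean_length_um: np.ndarray
    mean_width_um: np.ndarray
    mean_surface_um2: np.ndarray
    mean_volume_um3: np.ndarray
    mean_eta: np.ndarray
    newborn: pd.DataFrame     # bin_time_h, mean_eta, n_events
    events: pd.DataFrame      # per-lineage division log
    seed: int
    length_capped: bool = False
    final: dict = field(default_factory=dict)  # arrays L, w, Pc, Pr, generation at t_end


def _init_lineages(params: ModelParams, n: int, rng: np.random.Generator,
                   w0: Optional[float] = None):
    """Random-phase initialisation on the analytic constant-width cycle."""
    if w0 is None:
        w0 = steady_state_width(params)
    k, kP = params.k, params.kP_eff
    dL = params.rho * math.pi * w0 * k / kP if kP > 0 else params.eta_birth * w0
    Lb = dL  # homeostatic newborn length equals the added length
    u = rng.uniform(0.0, 1.0, size=n)
    age = u * _LN2 / k
    L = Lb * np.exp(k * age)
    P = (kP * Lb / k) * (np.exp(k * age) - 1.0)
    w = np.full(n, float(w0))
    if params.mode == "two_component":
        # quasi-steady cytoplasmic pool: production balances fast binding
        Pc = params.Pstar + kP * L / params.kb_eff
        Pr = np.maximum(P - kP * L / params.kb_eff, 0.0)
    else:
        Pc = params.Pstar + P
        Pr = np.zeros(n)
    gen = np.zeros(n, dtype=int)
    return L, w, Pc, Pr, gen


def _simulate_phases(phases, protocol: Protocol, rng: np.random.Generator,
                     init, seed: int) -> PopulationTrace:
    """Integrate through a list of (t_start, t_end, params) phases."""
    L, w, Pc, Pr, gen = init
    dt = protocol.dt
    rec0 = protocol.record_start
    times, mL, mw, mS, mV, me = [], [], [], [], [], []
    ev_store = {k: [] for k in ("time", "cell", "mother_length", "width",
                                "fraction", "generation", "newborn_eta")}
    capped = False
    step_index = 0
    t = phases[0][0]
    for (t0, t1, p) in phases:
        n_steps = max(1, int(math.ceil((t1 - t0) / dt - 1e-9)))
        for i in range(n_steps):
            h = min(dt, t1 - t)
            if h <= 0:
                break
            L, w, Pc, Pr, gen, ev = _step_ensemble(L, w, Pc, Pr, gen, t, h, p, rng)
            t += h
            if np.any(L > protocol.max_length_um):
                capped = True
                np.minimum(L, protocol.max_length_um, out=L)
            if ev is not None and t >= rec0:
                for key in ev_store:
                    ev_store[key].append(ev[key])
            step_index += 1
            if t >= rec0 and step_index % protocol.sample_every == 0:
                times.append(t)
                mL.append(L.mean())
                mw.append(w.mean())
                mS.append(np.mean(math.pi * w * L))
                mV.append(np.mean(math.pi / 4.0 * w * w * L - math.pi / 12.0 * w ** 3))
                me.append(np.mean(L / w))

    if ev_store["time"]:
        events = pd.DataFrame({
            "time_h": np.concatenate(ev_store["time"]),
            "lineage": np.concatenate(ev_store["cell"]),
            "mother_length_um": np.concatenate(ev_store["mother_length"]),
            "width_um": np.concatenate(ev_store["width"]),
            "daughter_fraction": np.concatenate(ev_store["fraction"]),
            "newborn_eta": np.concatenate(ev_store["newborn_eta"]),
            "generation": np.concatenate(ev_store["generation"]),
        }).sort_values("time_h", kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["time_h", "lineage", "mother_length_um",
                                       "width_um", "daughter_fraction",
                                       "newborn_eta", "generation"])

    bin_h = protocol.bin_minutes / 60.0
    t_end = phases[-1][1]
    edges = np.arange(rec0, t_end + bin_h, bin_h)
    if len(events) and len(edges) > 1:
        which = np.digitize(events["time_h"].to_numpy(), edges) - 1
        ok = (which >= 0) & (which < len(edges) - 1)
        df = pd.DataFrame({"bin": which[ok], "eta": events["newborn_eta"].to_numpy()[ok]})
        g = df.groupby("bin")["eta"].agg(["mean", "count"])
        newborn = pd.DataFrame({
            "bin_time_h": edges[g.index.to_numpy()] + bin_h / 2.0,
            "mean_eta": g["mean"].to_numpy(),
            "n_events": g["count"].to_numpy(),
        })
    else:
        newborn = pd.DataFrame(columns=["bin_time_h", "mean_eta", "n_events"])

    return PopulationTrace(
        time_h=np.asarray(times), mean_length_um=np.asarray(mL),
        mean_width_um=np.asarray(mw), mean_surface_um2=np.asarray(mS),
        mean_volume_um3=np.asarray(mV), mean_eta=np.asarray(me),
        newborn=newborn, events=events, seed=seed, length_capped=capped,
        final={"L": L, "w": w, "Pc": Pc, "Pr": Pr, "generation": gen},
    )


def run_ensemble(params: ModelParams, L0, w0, duration: float,
                 dt: float = 0.0025, seed: int = 0, t0: float = 0.0):
    """Low-level ensemble run from explicit initial conditions.

    ``L0`` and ``w0`` are scalars or per-cell arrays of birth lengths and
    widths; protein starts at the birth condition (Pc = Pstar, Pr = 0).
    Integrates for ``duration`` hours and returns a
    :class:`PopulationTrace` whose ``events`` DataFrame is the per-lineage
    division log (the ``lineage`` column indexes into the initial arrays)
    and whose ``final`` dict holds the end-state arrays (L, w, Pc, Pr,
    generation).

    This is the building block the protocol runners share; it is also the
    convenient way to measure per-cycle quantities (added length per
    division, width relaxation from arbitrary starts) without a protocol.
    """
    L = np.atleast_1d(np.asarray(L0, dtype=float)).copy()
    w = np.broadcast_to(np.asarray(w0, dtype=float), L.shape).astype(float).copy()
    if np.any(L < w):
        raise ValueError("initial length must be >= width for every cell")
    n = L.size
    Pc = np.full(n, params.Pstar)
    Pr = np.zeros(n)
    gen = np.zeros(n, dtype=int)
    rng = np.random.default_rng(seed)
    proto = Protocol(n_cells=n, k_pre=params.k, duration=duration,
                     record_start=t0, dt=dt, t_shift=t0)
    return _simulate_phases([(t0, t0 + duration, params)], proto, rng,
                            (L, w, Pc, Pr, gen), seed)


def run_protocol(protocol: Protocol, params: Optional[ModelParams] = None,
                 seed: int = 0) -> PopulationTrace:
    """Run a steady-state or nutrient-shift ensemble.

    ``params`` supplies rates and noise; its ``k`` is overridden by the
    protocol's ``k_pre``/``k_post``, and any rate left at its derived default
    (``kP``, ``beta``, ``kb``, ``kd`` = None) re-slaves to the phase's ``k``.
    """
    if params is None:
        params = ModelParams(k=protocol.k_pre)
    rng = np.random.default_rng(seed)
    p_pre = params.with_k(protocol.k_pre)
    p_post = params.with_k(protocol.k_post) if protocol.k_post is not None else p_pre
    burn_h = protocol.burn_in * _LN2 / protocol.k_pre
    t_start = protocol.record_start - burn_h
    t_end = protocol.t_shift + protocol.duration
    init = _init_lineages(p_pre, protocol.n_cells, rng)
    phases = [(t_start, protocol.t_shift, p_pre), (protocol.t_shift, t_end, p_post)]
    return _simulate_phases(phases, protocol, rng, init, seed)


def run_ftsz_knockdown(params: Optional[ModelParams] = None,
                       knockdown_fraction: float = 0.4, seed: int = 0,
                       n_cells: int = 1000, duration: float = 12.0,
                       width: float = 1.0,
                       protocol: Optional[Protocol] = None):
    """Division-protein knockdown at fixed width.

    Width dynamics are switched off and the width pinned (default 1 um);
    at t = 0 the production rate ``kP`` drops to ``knockdown_fraction`` of
    its baseline.  Since the added length per cycle is rho*pi*w*k/kP, the
    steady-state newborn length rises by 1/fraction.  Fraction 0 means no
    division ever fires: the run filaments until the length cap and the
    trace is flagged ``length_capped``.

    Returns
    -------
    (PopulationTrace, pandas.DataFrame)
        The trace and the population-mean S-V curve along the trajectory
        (columns time_h, surface_um2, volume_um3).
    """
    if not (0.0 <= knockdown_fraction <= 1.0):
        raise ValueError(f"knockdown_fraction must be in [0, 1], got {knockdown_fraction}")
    if params is None:
        params = ModelParams()
    base = replace(params, evolve_width=False)
    kP0 = base.kP_eff
    post = replace(base, kP=knockdown_fraction * kP0)
    if protocol is None:
        protocol = Protocol(n_cells=n_cells, k_pre=base.k, duration=duration,
                            perturbation="ftsz_knockdown")
    rng = np.random.default_rng(seed)
    burn_h = protocol.burn_in * _LN2 / protocol.k_pre
    t_start = protocol.record_start - burn_h
    t_end = protocol.t_shift + protocol.duration
    init = _init_lineages(base, protocol.n_cells, rng, w0=width)
    phases = [(t_start, protocol.t_shift, base), (protocol.t_shift, t_end, post)]
    trace = _simulate_phases(phases, protocol, rng, init, seed)
    sv = pd.DataFrame({"time_h": trace.time_h,
                       "surface_um2": trace.mean_surface_um2,
                       "volume_um3": trace.mean_volume_um3})
    return trace, sv


def constant_eta_sweep(params: Optional[ModelParams] = None,
                       target_eta: float = 2.7,
                       width_range: tuple[float, float] = (0.9, 1.8),
                       n_widths: int = 8, n_cells: int = 200, seed: int = 0,
                       burn_in: int = 8, record_generations: float = 1.0,
                       dt: float = 0.0025) -> pd.DataFrame:
    """Steady-state S-V locus at a fixed population-mean aspect ratio.

    For each target width the surface-synthesis rate is set to ``4k/w`` (so
    the width fixed point lands on target) and ``kP`` is co-adjusted to hold
    the newborn aspect ratio at ``target_eta * ln2`` — the time-average of
    exponential growth over one cycle is L_birth/ln2, so the *population
    mean* aspect ratio sits at ``target_eta``.  Each sweep point is a short
    independent ensemble run; the emitted locus is the population-mean
    (S, V, eta) per point and lies on S = gamma(target_eta) * V^(2/3).

    The co-adjustment rule (hold the aspect-ratio target while beta moves the
    width) is a reconstruction of how such quasi-static perturbation curves
    are generated; the underlying data would only pin the endpoint widths
    and the fitted aspect ratio.
    """
    if params is None:
        params = ModelParams()
    lo, hi = width_range
    if not (0.0 < lo <= hi <= 3.0):
        raise ValueError(f"width range must lie within (0, 3] um and be ordered, got {width_range}")
    if target_eta < 1.0:
        raise ValueError(f"target_eta must be >= 1, got {target_eta}")
    eta_birth = target_eta * _LN2
    if eta_birth <= 1.0:
        raise ValueError(
            f"target_eta={target_eta} implies newborn aspect ratio {eta_birth:.2f} <= 1; "
            "unreachable for a spherocylinder"
        )
    k = params.k
    rows = []
    for j, w_t in enumerate(np.linspace(lo, hi, n_widths)):
        beta_j = 4.0 * k / w_t
        kP_j = params.rho * math.pi * k / eta_birth
        p = replace(params, beta=beta_j, kP=kP_j)
        rng = np.random.default_rng([seed, j])
        rec_h = record_generations * _LN2 / k
        proto = Protocol(n_cells=n_cells, burn_in=burn_in, k_pre=k,
                         duration=rec_h, record_start=0.0, dt=dt,
                         sample_every=10)
        burn_h = burn_in * _LN2 / k
        init = _init_lineages(p, n_cells, rng, w0=w_t)
        trace = _simulate_phases([(-burn_h, rec_h, p)], proto, rng, init, seed)
        rows.append({
            "width_um": float(trace.mean_width_um.mean()),
            "surface_um2": float(trace.mean_surface_um2.mean()),
            "volume_um3": float(trace.mean_volume_um3.mean()),
            "eta": float(trace.mean_eta.mean()),
        })
    return pd.DataFrame(rows)


def run_mreb_depletion(params: Optional[ModelParams] = None,
                       width_range: tuple[float, float] = (0.9, 1.8),
                       target_eta: float = 2.7, seed: int = 0,
                       **kw) -> pd.DataFrame:
    """Cytoskeletal (MreB) depletion: wider cells at reduced aspect ratio.

    Sweeps the surface-synthesis rate so the steady-state width spans
    ``width_range`` while the production rate holds the population-mean
    aspect ratio at ``target_eta`` (default 2.7).  Returns the S-V locus.
    """
    return constant_eta_sweep(params=params, target_eta=target_eta,
                              width_range=width_range, seed=seed, **kw)


def run_filamentation(params: Optional[ModelParams] = None,
                      width_range: tuple[float, float] = (0.9, 1.4),
                      target_eta: float = 11.0, seed: int = 0,
                      **kw) -> pd.DataFrame:
    """Division-blocked filamentation: long cells at high aspect ratio.

    Same sweep machinery as :func:`run_mreb_depletion` with default target
    aspect ratio 11.0 over a narrower width range.  The target is a fit
    parameter describing antibiotic-filamented cells, not a model prediction.
    """
    return constant_eta_sweep(params=params, target_eta=target_eta,
                              width_range=width_range, seed=seed, **kw)
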