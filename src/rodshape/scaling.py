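"""Fitting and summarising surface-to-volume scaling in cell-shape tables.

A *shape table* is a pandas DataFrame with one row per condition (or per
cell) and the columns

    condition, length_um, width_um, growth_rate_per_h,
    surface_um2, volume_um3, geometry

where ``geometry`` is ``"rod"`` (spherocylinder) or ``"spheroid"`` (prolate
spheroid).  ``length_um``/``width_um`` are the full pole-to-pole length and
diameter for rods, and the full major/minor axes (2c, 2a) for spheroids.
Each row must carry either (length, width) or (surface, volume); the rest is
filled in by :func:`complete_shape_table`.

The central statistic is the power-law fit S = gamma * V^beta, done by
ordinary least squares in log-log space (the data of interest span about two
decades in volume with multiplicative scatter, so log-space residuals are the
natural error model; weighted alternatives move gamma only in its third
digit).  The ``fixed`` mode pins beta = 2/3 — the geometric value for any
shape family of constant aspect ratio — and fits only the prefactor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from . import geometry as geom

__all__ = [
    "SHAPE_TABLE_COLUMNS",
    "ScalingFit",
    "GrowthLawParams",
    "AspectRatioSummary",
    "read_shape_table",
    "write_shape_table",
    "complete_shape_table",
    "fit_power_law",
    "sv_ratio_prediction",
    "fit_growth_law",
    "aspect_ratio_summary",
    "lineage_autocorrelation",
    "write_fit_results",
]

SHAPE_TABLE_COLUMNS = [
    "condition", "length_um", "width_um", "growth_rate_per_h",
    "surface_um2", "volume_um3", "geometry",
]


@dataclass(frozen=True)
class ScalingFit:
    """Result of fitting S = gamma * V^exponent."""

    gamma: float
    exponent: float
    gamma_se: float
    exponent_se: float
    n: int
    mode: str  # "free" | "fixed"


@dataclass(frozen=True)
class GrowthLawParams:
    """Nutrient growth law V = V0 * exp(alpha * kappa).

    ``V0`` is the extrapolated cell volume at zero growth rate (um^3) and
    ``alpha`` the relative rate of volume increase with growth rate (h).
    """

    V0: float
    alpha: float

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError(f"V0 must be > 0, got {self.V0}")

    def volume(self, kappa):
        """Mean cell volume at growth rate ``kappa`` (h^-1), um^3."""
        return self.V0 * np.exp(self.alpha * np.asarray(kappa, dtype=float))


@dataclass(frozen=True)
class AspectRatioSummary:
    """Moments and log-normal fit of an aspect-ratio sample."""

    mean: float
    cv: float          # SD/mean on the natural scale
    mu_log: float      # mean of log(eta)  (log-normal location)
    sigma_log: float   # SD of log(eta), MLE (ddof=0)
    n: int


# ---------------------------------------------------------------------------
# Shape-table I/O and completion
# ---------------------------------------------------------------------------

def read_shape_table(path) -> pd.DataFrame:
    """Read a shape-table CSV (header row, '.' decimals, '#' comments)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SHAPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shape table {path} is missing columns: {missing}")
    return df


def write_shape_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a shape table as CSV, optionally with a leading '#' comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _eta_from_sv(S: float, V: float, geometry_tag: str) -> float:
    gamma = S / V ** (2.0 / 3.0)
    if geometry_tag == "rod":
        return geom.eta_from_gamma_rod(gamma)
    if gamma < geom.GAMMA_SPHERE:
        if gamma > geom.GAMMA_SPHERE * (1 - 1e-9):
            return 1.0
        raise ValueError(f"gamma={gamma} below the sphere prefactor")
    return brentq(lambda e: geom.gamma_from_eta_spheroid(e) - gamma, 1.0, 1e4,
                  xtol=1e-12, rtol=1e-14)


def complete_shape_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fill in surface, volume and aspect ratio for every row.

    Rows with (length, width) get S, V from their geometry's closed forms
    (existing S, V values are preserved, not overwritten) and eta = L/w.
    Rows with only (S, V) get eta by inverting the prefactor S/V^(2/3) for
    their geometry.  Returns a copy with an added ``aspect_ratio`` column.

    Raises
    ------
    ValueError
        If a row has neither (length, width) nor (surface, volume), or a
        non-positive numeric value; the message names the offending row.
    """
    out = df.copy()
    for col in SHAPE_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col in ("condition", "geometry") else np.nan
    out["geometry"] = out["geometry"].fillna("rod").replace("", "rod")
    if "aspect_ratio" not in out.columns:
        out["aspect_ratio"] = np.nan

    for i, row in out.iterrows():
        has_dims = pd.notna(row["length_um"]) and pd.notna(row["width_um"])
        has_sv = pd.notna(row["surface_um2"]) and pd.notna(row["volume_um3"])
        if not has_dims and not has_sv:
            raise ValueError(
                f"row {i}: needs either (length_um, width_um) or "
                "(surface_um2, volume_um3)"
            )
        tag = str(row["geometry"]).strip().lower()
        if tag not in ("rod", "spheroid"):
            raise ValueError(f"row {i}: unknown geometry tag {tag!r}")
        if has_dims:
            L, w = float(row["length_um"]), float(row["width_um"])
            if L <= 0 or w <= 0:
                raise ValueError(f"row {i}: non-positive dimensions")
            if tag == "rod":
                shape = geom.RodShape(length=L, width=w)
                S, V = geom.rod_surface(shape), geom.rod_volume(shape)
            else:
                sph = geom.SpheroidShape(a=w / 2.0, c=L / 2.0)
                S, V = geom.spheroid_surface(sph), geom.spheroid_volume(sph)
            if pd.isna(row["surface_um2"]):
                out.at[i, "surface_um2"] = S
            if pd.isna(row["volume_um3"]):
                out.at[i, "volume_um3"] = V
            out.at[i, "aspect_ratio"] = L / w
        else:
            S, V = float(row["surface_um2"]), float(row["volume_um3"])
            if S <= 0 or V <= 0:
                raise ValueError(f"row {i}: non-positive surface/volume")
            out.at[i, "aspect_ratio"] = _eta_from_sv(S, V, tag)
    return out


# ---------------------------------------------------------------------------
# Power-law and growth-law fits
# ---------------------------------------------------------------------------

def fit_power_law(df: pd.DataFrame, mode: str = "free") -> ScalingFit:
    """Fit S = gamma * V^beta to a shape table by log-log least squares.

    mode="free": OLS of log S on log V (slope = beta, intercept = log gamma),
    standard errors from the linear model.  mode="fixed": beta is pinned at
    2/3 and log gamma is the mean of log S - (2/3) log V, with the standard
    error of that mean; ``exponent_se`` is reported as 0.  ``gamma_se`` is
    delta-method: gamma * se(log gamma).
    """
    if mode not in ("free", "fixed"):
        raise ValueError(f"mode must be 'free' or 'fixed', got {mode!r}")
    if "surface_um2" not in df.columns or "volume_um3" not in df.columns:
        raise ValueError("table lacks surface/volume columns; run complete_shape_table")
    sub = df[["surface_um2", "volume_um3"]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 rows with surface and volume, got {n}")
    S = sub["surface_um2"].to_numpy(float)
    V = sub["volume_um3"].to_numpy(float)
    if np.any(S <= 0) or np.any(V <= 0):
        raise ValueError("surface and volume must be positive")
    logS, logV = np.log(S), np.log(V)

    if mode == "free":
        if np.ptp(logV) < 1e-12:
            raise ValueError("degenerate design: no spread in volume")
        res = sm.OLS(logS, sm.add_constant(logV)).fit()
        log_gamma, beta = res.params
        se_lg, se_b = res.bse
        gamma = math.exp(log_gamma)
        return ScalingFit(gamma=gamma, exponent=float(beta),
                          gamma_se=gamma * float(se_lg),
                          exponent_se=float(se_b), n=n, mode=mode)
    resid = logS - (2.0 / 3.0) * logV
    log_gamma = float(np.mean(resid))
    se_lg = float(np.std(resid, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    gamma = math.exp(log_gamma)
    return ScalingFit(gamma=gamma, exponent=2.0 / 3.0,
                      gamma_se=gamma * se_lg, exponent_se=0.0, n=n, mode=mode)


def sv_ratio_prediction(kappa, params: GrowthLawParams):
    """Predicted surface-to-volume ratio vs growth rate, um^-1.

    Combining S ~= 2*pi*V^(2/3) (constant aspect ratio ~4) with the nutrient
    growth law V = V0*exp(alpha*kappa) gives

        S/V ~= 2*pi * V0^(-1/3) * exp(-alpha*kappa/3):

    slower-growing cells run at higher surface-to-volume ratio.
    """
    kappa = np.asarray(kappa, dtype=float)
    out = 2.0 * math.pi * params.V0 ** (-1.0 / 3.0) * np.exp(-params.alpha * kappa / 3.0)
    return float(out) if out.ndim == 0 else out


def fit_growth_law(data) -> GrowthLawParams:
    """Fit V = V0*exp(alpha*kappa) by OLS of log V on kappa.

    ``data`` is a sequence of (kappa, V) pairs or a DataFrame with columns
    ``growth_rate_per_h`` and ``volume_um3``.
    """
    if isinstance(data, pd.DataFrame):
        kappa = data["growth_rate_per_h"].to_numpy(float)
        V = data["volume_um3"].to_numpy(float)
    else:
        arr = np.asarray(list(data), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (kappa, V) pairs")
        kappa, V = arr[:, 0], arr[:, 1]
    if np.any(V <= 0):
        raise ValueError("volumes must be positive")
    if len(np.unique(kappa)) < 2:
        raise ValueError("need >= 2 distinct growth rates")
    res = sm.OLS(np.log(V), sm.add_constant(kappa)).fit()
    return GrowthLawParams(V0=math.exp(res.params[0]), alpha=float(res.params[1]))


# ---------------------------------------------------------------------------
# Aspect-ratio distribution and lineage statistics
# ---------------------------------------------------------------------------

def aspect_ratio_summary(etas: Iterable[float], tol: float = 0.05) -> AspectRatioSummary:
    """Mean, CV and log-normal MLE of an aspect-ratio sample.

    The CV is SD/mean on the natural scale.  Log-normal parameters are the
    mean and (ddof=0) SD of log(eta) — the maximum-likelihood fit.  Values
    below 1 - ``tol`` are rejected (aspect ratios cannot be < 1 beyond
    measurement slack); non-positive values always are.
    """
    x = np.asarray(list(etas), dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("aspect ratios must be positive")
    if np.any(x < 1.0 - tol):
        raise ValueError(f"aspect ratios below {1.0 - tol} are not physical")
    mean = float(np.mean(x))
    cv = float(np.std(x, ddof=1) / mean)
    logs = np.log(x)
    return AspectRatioSummary(mean=mean, cv=cv,
                              mu_log=float(np.mean(logs)),
                              sigma_log=float(np.std(logs, ddof=0)),
                              n=int(x.size))


def lineage_autocorrelation(series: Sequence[Sequence[float]], lag: int) -> float:
    """Intergeneration autocorrelation at a given lag, pooled across lineages.

    For each lineage the pairs (x_g, x_{g+lag}) are collected and a single
    Pearson correlation is computed over the pooled pairs.  Lag 0 returns
    exactly 1.  Lineages shorter than lag+1 generations contribute no pairs.
    """
    if lag < 0:
        raise ValueError(f"lag must be >= 0, got {lag}")
    if lag == 0:
        if not any(len(s) >= 1 for s in series):
            raise ValueError("no data")
        return 1.0
    a, b = [], []
    for s in series:
        s = np.asarray(s, dtype=float)
        if s.size >= lag + 1:
            a.append(s[:-lag])
            b.append(s[lag:])
    if not a:
        raise ValueError(f"no lineage provides pairs at lag {lag}")
    x = np.concatenate(a)
    y = np.concatenate(b)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def write_fit_results(fits: dict[str, ScalingFit], path,
                      header_comment: str | None = None) -> None:
    """Write one CSV row per (dataset, mode) fit."""
    rows = [
        {"dataset": name, "mode": f.mode, "gamma": f.gamma, "gamma_se": f.gamma_se,
         "exponent": f.exponent, "exponent_se": f.exponent_se, "n": f.n}
        for name, f in fits.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
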