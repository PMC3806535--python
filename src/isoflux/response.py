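"""Environment sweeps and response-curve diagnostics.

Builds response curves of photosynthesis and isoprene emission along one
driver (PAR, ci or leaf temperature), temperature × PAR surfaces, the
Iso/Agross and Iso/Anet diagnostic ratios, the three-stage segmentation
of a PAR response (light-limited → supply/demand crossing →
Rubisco-limited), and temperature optima with quadratic refinement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .photo import (
    LeafEnvironment,
    PhotoParams,
    assimilation_arrays,
    electron_transport,
    jv_required,
    kinetics_at,
)
from .models import (
    EnergeticIsoParams,
    G93Params,
    IspSParams,
    NiinemetsParams,
    energetic_emission,
    g93_factors,
    isps_activity,
    niinemets_emission,
)
from .fitting import standard_emission

__all__ = [
    "ResponseCurve",
    "StageSegmentation",
    "GridSurface",
    "TemperatureOptimum",
    "DRIVERS",
    "sweep",
    "classify_stages",
    "grid_surface",
    "temperature_optimum",
]

DRIVERS = ("par", "ci", "temperature")
_DRIVER_COLUMNS = {"par": "par", "ci": "ci", "temperature": "t_leaf_c"}


def params_hash(*objs) -> str:
    """Short stable hash of parameter dataclasses, for output metadata."""
    payload = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o
                          for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ResponseCurve:
    """Ordered table of model outputs along one environmental driver.

    ``data`` holds one row per grid point with the full photosynthetic
    state, each requested model's emission (columns ``iso_<model>``), and
    the diagnostic ratios ``iso_<model>_over_agross`` / ``_over_anet``
    (NaN and flagged where the denominator is not positive).
    """

    driver: str
    data: pd.DataFrame
    fixed: dict
    photo: PhotoParams
    models: dict
    metadata: dict = field(default_factory=dict)


@dataclass
class StageSegmentation:
    """Three-stage classification of a PAR response.

    ``labels``: per-point stage (1 light-limited, 3 Rubisco-limited; the
    grid point nearest the crossing is labelled 2).  ``transition_par``:
    PAR at the unique J = Jv crossing (None when Jv >= Jmax and no
    crossing exists).  ``slope_jump``: one-sided finite-difference change
    in d(Iso/Agross)/dQ across the transition.
    """

    labels: np.ndarray
    transition_par: Optional[float]
    slope_jump: Optional[float]
    has_stage3: bool


@dataclass
class GridSurface:
    """Normalized emission and electron excess on a T × PAR grid."""

    t_grid_c: np.ndarray
    par_grid: np.ndarray
    emission_norm: np.ndarray  # shape (nT, nPAR)
    j_minus_jv: np.ndarray
    reference: tuple
    metadata: dict = field(default_factory=dict)


@dataclass
class TemperatureOptimum:
    """Location of the maximum of a series over temperature."""

    t_opt: float
    boundary: bool
    defined: bool = True


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _model_emissions(arr, ci, t_k, par, models, co2_mode="none", ca=None):
    out = {}
    for model_id, params in models.items():
        if model_id == "energetic":
            out[model_id] = np.asarray(
                energetic_emission(arr["j"], arr["jv"], ci, arr["gamma_star"], params)
            )
        elif model_id == "g93":
            c_l, c_t = g93_factors(par, t_k, params)
            out[model_id] = params.i_s * np.asarray(c_l) * np.asarray(c_t)
        elif model_id == "niinemets":
            out[model_id] = np.asarray(
                niinemets_emission(arr["j"], ci, arr["gamma_star"], t_k, params,
                                   co2_mode, ca)
            )
        else:
            raise ValueError(f"unknown model_id {model_id!r}")
    return out


def sweep(
    driver: str,
    grid: Sequence[float],
    fixed: LeafEnvironment,
    photo: PhotoParams,
    models: dict,
    co2_mode: str = "none",
    ca: Optional[float] = None,
    normalize: bool = False,
) -> ResponseCurve:
    """Evaluate photosynthesis and the requested models along one driver.

    ``driver`` is one of ``par``, ``ci`` or ``temperature`` (grid in °C);
    the other two environment values are taken from ``fixed``.  ``models``
    maps model identifiers to their parameter blocks.  With
    ``normalize=True``, per-model columns ``iso_<model>_norm`` divided by
    the standard-condition emission are added.
    """
    if driver not in DRIVERS:
        raise ValueError(f"unknown driver {driver!r}; expected one of {DRIVERS}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("driver grid must be strictly increasing")

    par = np.full_like(grid, fixed.par_absorbed)
    t_c = np.full_like(grid, fixed.t_leaf)
    ci = np.full_like(grid, fixed.ci)
    if driver == "par":
        par = grid
    elif driver == "ci":
        ci = grid
    else:
        t_c = grid
    o2 = np.full_like(grid, fixed.o2)
    t_k = t_c + 273.15

    arr = assimilation_arrays(par, t_c, ci, o2, photo)
    emissions = _model_emissions(arr, ci, t_k, par, models, co2_mode, ca)

    df = pd.DataFrame({
        "driver": _DRIVER_COLUMNS[driver],
        "par": par, "t_leaf_c": t_c, "ci": ci, "o2": o2,
        "j": arr["j"], "jv": arr["jv"], "j_minus_jv": arr["j"] - arr["jv"],
        "aj": arr["aj"], "av": arr["av"],
        "a_gross": arr["a_gross"], "a_net": arr["a_net"],
        "gamma_star": arr["gamma_star"], "km": arr["km"], "rd": arr["rd"],
        "limitation": np.where(arr["light_limited"], "light",
                               np.where(arr["rubisco_limited"], "rubisco",
                                        "co_limited")),
    })
    flagged = np.zeros(grid.size, dtype=bool)
    for model_id, iso in emissions.items():
        df[f"iso_{model_id}"] = iso
        with np.errstate(divide="ignore", invalid="ignore"):
            over_g = np.where(arr["a_gross"] > 0, iso / arr["a_gross"], np.nan)
            over_n = np.where(arr["a_net"] > 0, iso / arr["a_net"], np.nan)
        flagged |= ~(arr["a_gross"] > 0) | ~(arr["a_net"] > 0)
        df[f"iso_{model_id}_over_agross"] = over_g
        df[f"iso_{model_id}_over_anet"] = over_n
        if normalize:
            is_ = standard_emission(model_id, models[model_id], photo,
                                    co2_mode=co2_mode, ca=ca)
            df[f"iso_{model_id}_norm"] = iso / is_
    df["ratio_flagged"] = flagged

    meta = {
        "fixed": {"par_absorbed": fixed.par_absorbed, "t_leaf": fixed.t_leaf,
                  "ci": fixed.ci, "o2": fixed.o2},
        "params_hash": params_hash(photo, *models.values()),
        "normalized": normalize,
        "co2_mode": co2_mode,
    }
    return ResponseCurve(driver=driver, data=df, fixed=meta["fixed"],
                         photo=photo, models=models, metadata=meta)


# ---------------------------------------------------------------------------
# stage classification
# ---------------------------------------------------------------------------


def classify_stages(curve: ResponseCurve, par_resolution: float = 0.1) -> StageSegmentation:
    """Segment a PAR response into the three stages of the electron balance.

    Stage 1: J(Q) < Jv (light-limited assimilation).  Stage 2: the unique
    crossing J(Q) = Jv, located by bisection on Q to ``par_resolution``
    (µmol m⁻² s⁻¹).  Stage 3: J(Q) > Jv (Rubisco-limited).  When Jv is at
    or above Jmax(T) no crossing exists and everything is stage 1.
    """
    if curve.driver != "par":
        raise ValueError("stage classification requires a PAR sweep")
    if "iso_energetic" not in curve.data.columns:
        raise ValueError("stage classification requires energetic-model outputs")
    df = curve.data
    photo = curve.photo
    t_k = df["t_leaf_c"].iloc[0] + 273.15
    ci = df["ci"].iloc[0]
    o2 = df["o2"].iloc[0]
    gamma_star, km = kinetics_at(t_k, o2, photo)
    jv = float(jv_required(photo.vcmax_at(t_k), ci, gamma_star, km))
    jmax = float(photo.jmax_at(t_k))

    q = df["par"].to_numpy()
    labels = np.ones(len(df), dtype=int)
    if jv >= jmax:
        return StageSegmentation(labels=labels, transition_par=None,
                                 slope_jump=None, has_stage3=False)

    def gap(qq):
        return float(electron_transport(qq, jmax, photo.alpha, photo.theta)) - jv

    q_hi = float(q[-1])
    if gap(q_hi) <= 0:  # crossing beyond the measured grid
        return StageSegmentation(labels=labels, transition_par=None,
                                 slope_jump=None, has_stage3=False)
    q_star = float(optimize.brentq(gap, 0.0, q_hi, xtol=par_resolution))

    labels[q > q_star] = 3
    # label the grid point nearest the crossing as the stage-2 transition
    i2 = int(np.argmin(np.abs(q - q_star)))
    labels[i2] = 2

    ratio = df["iso_energetic_over_agross"].to_numpy()
    slope_jump = None
    if 1 <= i2 < len(q) - 1:
        left = (ratio[i2] - ratio[i2 - 1]) / (q[i2] - q[i2 - 1])
        right = (ratio[i2 + 1] - ratio[i2]) / (q[i2 + 1] - q[i2])
        if np.isfinite(left) and np.isfinite(right):
            slope_jump = float(right - left)
    return StageSegmentation(labels=labels, transition_par=q_star,
                             slope_jump=slope_jump, has_stage3=True)


# ---------------------------------------------------------------------------
# temperature × PAR surface
# ---------------------------------------------------------------------------


def grid_surface(
    t_grid_c: Sequence[float],
    par_grid: Sequence[float],
    ci: float,
    photo: PhotoParams,
    model_id: str,
    model_params,
    reference: tuple = (30.0, 1000.0),
    o2: float = 210.0,
    co2_mode: str = "none",
    ca: Optional[float] = None,
) -> GridSurface:
    """Emission (normalized to the reference cell) and J − Jv over T × PAR.

    ``reference`` is (T °C, PAR); both values must be members of their
    grids — the normalization cell is then exactly 1.
    """
    t_grid_c = np.asarray(t_grid_c, dtype=float)
    par_grid = np.asarray(par_grid, dtype=float)
    t_ref, q_ref = reference
    it = np.where(np.isclose(t_grid_c, t_ref))[0]
    iq = np.where(np.isclose(par_grid, q_ref))[0]
    if it.size == 0 or iq.size == 0:
        raise ValueError(f"reference cell {reference} not on the supplied grids")

    tt, qq = np.meshgrid(t_grid_c, par_grid, indexing="ij")
    arr = assimilation_arrays(qq, tt, ci, o2, photo)
    emissions = _model_emissions(arr, np.full_like(tt, ci), tt + 273.15, qq,
                                 {model_id: model_params}, co2_mode, ca)
    emission = emissions[model_id]
    ref_val = emission[it[0], iq[0]]
    if ref_val == 0:
        raise ZeroDivisionError("emission at the reference cell is zero")
    return GridSurface(
        t_grid_c=t_grid_c,
        par_grid=par_grid,
        emission_norm=emission / ref_val,
        j_minus_jv=arr["j"] - arr["jv"],
        reference=reference,
        metadata={"model": model_id, "ci": ci,
                  "params_hash": params_hash(photo, model_params)},
    )


# ---------------------------------------------------------------------------
# temperature optimum
# ---------------------------------------------------------------------------


def temperature_optimum(t_values: Sequence[float], series: Sequence[float]) -> TemperatureOptimum:
    """Locate the maximum of a series over a monotone temperature grid.

    The discrete argmax is refined by the vertex of the parabola through
    the maximum and its two neighbours.  ``boundary`` is set when the
    maximum sits at a grid end (no interior optimum); an all-equal series
    yields ``defined=False``.
    """
    t = np.asarray(t_values, dtype=float)
    y = np.asarray(series, dtype=float)
    if t.size < 5 or t.shape != y.shape:
        raise ValueError("need >= 5 aligned points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if np.ptp(y) == 0:
        return TemperatureOptimum(t_opt=float("nan"), boundary=False, defined=False)
    i = int(np.argmax(y))
    if i == 0 or i == t.size - 1:
        return TemperatureOptimum(t_opt=float(t[i]), boundary=True)
    # quadratic refinement through (t[i-1..i+1], y[i-1..i+1])
    x0, x1, x2 = t[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    t_opt = float(-b / (2 * a)) if a != 0 else float(x1)
    t_opt = min(max(t_opt, float(x0)), float(x2))
    return TemperatureOptimum(t_opt=t_opt, boundary=False)
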