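"""Parameter estimation from leaf gas-exchange + isoprene data.

Two-stage procedure: (1) fit the Farquhar capacities (Vcmax25, Jmax25) to
the assimilation observations by residual-sum-of-squares minimization;
(2) estimate the energetic-model coefficients (a, b) from an ordinary
linear regression of observed isoprene on the modelled electron flux —
on J for a light-response design at fixed ci, or on Jv for a ci-response
design at fixed PAR.  The regression algebra follows from the model

    Iso = a*J + b*(J - Jv)     (f(ci) = 1 for ci > gamma_star)

which is linear in J with slope a+b and intercept -b*Jv when Jv is held
fixed, and linear in Jv with slope -b and intercept (a+b)*J when J is
held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .photo import (
    InvalidParameterError,
    LeafEnvironment,
    PhotoParams,
    assimilation_arrays,
    electron_transport,
    jv_required,
    kinetics_at,
)
from . import models as _models

__all__ = [
    "GasExchangeRecord",
    "FitResult",
    "UndefinedStatisticError",
    "r_squared",
    "fit_ab_from_light_response",
    "fit_ab_from_ci_response",
    "fit_photo_params",
    "standard_emission",
    "STANDARD_CONDITION",
]

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One gas-exchange observation: environment, net assimilation
    (µmol m⁻² s⁻¹), isoprene emission (nmol m⁻² s⁻¹), optional dark
    respiration."""

    env: LeafEnvironment
    a_net_obs: float
    iso_obs: float
    rd_obs: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite([self.a_net_obs, self.iso_obs]).all():
            raise InvalidParameterError("observations must be finite")
        if self.iso_obs < 0:
            raise InvalidParameterError("iso_obs must be >= 0")


@dataclass
class FitResult:
    """Outcome of a fitting procedure."""

    estimates: dict
    rss: float
    r_squared: float
    residuals: np.ndarray
    n_obs: int
    converged: bool
    trace: list = field(default_factory=list)
    seed: Optional[int] = None
    notes: dict = field(default_factory=dict)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    May be negative for models worse than the observed mean.  Raises
    :class:`UndefinedStatisticError` when the observations have zero
    variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("observed series has zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# (a, b) regressions
# ---------------------------------------------------------------------------


def _filter_above_gamma_star(records, photo):
    """Drop records at or below the compensation point (logged)."""
    kept, dropped = [], 0
    for r in records:
        gs, _ = kinetics_at(r.env.t_leaf_k, r.env.o2, photo)
        if r.env.ci > gs:
            kept.append(r)
        else:
            dropped += 1
    if dropped:
        logger.info("excluded %d record(s) with ci <= gamma_star", dropped)
    return kept


def fit_ab_from_light_response(
    records: Sequence[GasExchangeRecord], photo: PhotoParams
) -> FitResult:
    """Estimate (a, b) from a light-response sweep at fixed ci and T.

    Regresses observed isoprene on the modelled electron flux J(Q); with
    Jv fixed by the common (ci, T), slope = a + b and intercept = -b*Jv,
    so b = -intercept/Jv and a = slope + intercept/Jv.
    """
    records = _filter_above_gamma_star(records, photo)
    if len(records) < 3:
        raise ValueError("need at least 3 records above the compensation point")
    ci = np.array([r.env.ci for r in records])
    if np.ptp(ci) > 0.05 * np.mean(ci):
        raise ValueError("light-response design requires fixed ci (spread < 5 %)")
    t_c = np.array([r.env.t_leaf for r in records])
    par = np.array([r.env.par_absorbed for r in records])
    iso = np.array([r.iso_obs for r in records])
    o2 = np.array([r.env.o2 for r in records])

    t_k = t_c.mean() + 273.15
    gamma_star, km = kinetics_at(t_k, o2.mean(), photo)
    jmax = photo.jmax_at(t_k)
    j = np.asarray(electron_transport(par, jmax, photo.alpha, photo.theta))
    if np.ptp(j) < 1e-9 * max(1.0, float(np.max(np.abs(j)))):
        raise np.linalg.LinAlgError("degenerate design: no spread in J")
    jv = float(jv_required(photo.vcmax_at(t_k), ci.mean(), gamma_star, km))
    if jv <= 0:
        raise InvalidParameterError("Jv <= 0 under the supplied photo parameters")

    reg = stats.linregress(j, iso)
    b = -reg.intercept / jv
    a = reg.slope + reg.intercept / jv
    pred = reg.slope * j + reg.intercept
    resid = iso - pred
    if b < 0:
        logger.warning("fitted b = %.4g < 0", b)
    return FitResult(
        estimates={"a": float(a), "b": float(b), "slope": float(reg.slope),
                   "intercept": float(reg.intercept), "jv": jv},
        rss=float(np.sum(resid**2)),
        r_squared=float(reg.rvalue**2),
        residuals=resid,
        n_obs=len(records),
        converged=True,
        notes={"design": "light_response", "regressor": "j"},
    )


def fit_ab_from_ci_response(
    records: Sequence[GasExchangeRecord], photo: PhotoParams
) -> FitResult:
    """Estimate (a, b) from a ci sweep at fixed PAR and T.

    Regresses observed isoprene on the Rubisco electron demand Jv(ci);
    with J fixed by the common (PAR, T), slope = -b and intercept =
    (a+b)*J, so b = -slope and a = intercept/J + slope.
    """
    records = _filter_above_gamma_star(records, photo)
    if len(records) < 3:
        raise ValueError("need at least 3 records above the compensation point")
    par = np.array([r.env.par_absorbed for r in records])
    t_c = np.array([r.env.t_leaf for r in records])
    if np.ptp(par) > 0.05 * max(np.mean(par), 1e-9) or np.ptp(t_c) > 0.5:
        raise ValueError("ci-response design requires fixed PAR and T")
    ci = np.array([r.env.ci for r in records])
    iso = np.array([r.iso_obs for r in records])
    o2 = np.array([r.env.o2 for r in records])

    t_k = t_c.mean() + 273.15
    gamma_star, km = kinetics_at(t_k, o2.mean(), photo)
    j = float(
        electron_transport(par.mean(), photo.jmax_at(t_k), photo.alpha, photo.theta)
    )
    if j <= 0:
        raise InvalidParameterError("J <= 0: ci-response design needs light")
    jv = np.asarray(jv_required(photo.vcmax_at(t_k), ci, gamma_star, km))
    if np.ptp(jv) < 1e-9 * max(1.0, float(np.max(np.abs(jv)))):
        raise np.linalg.LinAlgError("degenerate design: no spread in Jv")

    reg = stats.linregress(jv, iso)
    b = -reg.slope
    a = reg.intercept / j + reg.slope
    pred = reg.slope * jv + reg.intercept
    resid = iso - pred
    if b < 0:
        logger.warning("fitted b = %.4g < 0", b)
    return FitResult(
        estimates={"a": float(a), "b": float(b), "slope": float(reg.slope),
                   "intercept": float(reg.intercept), "j": j},
        rss=float(np.sum(resid**2)),
        r_squared=float(reg.rvalue**2),
        residuals=resid,
        n_obs=len(records),
        converged=True,
        notes={"design": "ci_response", "regressor": "jv"},
    )


# ---------------------------------------------------------------------------
# (Vcmax25, Jmax25) RSS minimization
# ---------------------------------------------------------------------------

DEFAULT_PHOTO_BOUNDS = ((10.0, 250.0), (20.0, 450.0))


def _photo_rss_function(records: Sequence[GasExchangeRecord], base: PhotoParams):
    """Vectorized RSS of modelled vs observed net assimilation."""
    par = np.array([r.env.par_absorbed for r in records])
    t_c = np.array([r.env.t_leaf for r in records])
    ci = np.array([r.env.ci for r in records])
    o2 = np.array([r.env.o2 for r in records])
    a_obs = np.array([r.a_net_obs for r in records])
    rd_obs = np.array(
        [r.rd_obs if r.rd_obs is not None else np.nan for r in records]
    )
    use_obs_rd = np.isfinite(rd_obs).all()

    def rss(x):
        vcmax25, jmax25 = x
        p = _replace_capacities(base, vcmax25, jmax25)
        arr = assimilation_arrays(par, t_c, ci, o2, p)
        a_net = arr["a_gross"] - (rd_obs if use_obs_rd else arr["rd"])
        return float(np.sum((a_net - a_obs) ** 2))

    return rss, use_obs_rd


def _replace_capacities(base: PhotoParams, vcmax25: float, jmax25: float) -> PhotoParams:
    from dataclasses import replace

    return replace(base, vcmax25=float(vcmax25), jmax25=float(jmax25))


def fit_photo_params(
    records: Sequence[GasExchangeRecord],
    base: PhotoParams,
    bounds=DEFAULT_PHOTO_BOUNDS,
) -> FitResult:
    """Fit (Vcmax25, Jmax25) by bounded RSS minimization.

    Deterministic: a fixed 5-point multistart lattice (the four bound
    midpoint corners plus the centre) feeds L-BFGS-B; the reported
    optimum is the best of the five local solutions.  All other Farquhar
    parameters are taken from ``base``.  Warns when the data do not span
    both limitation regimes (Vcmax and Jmax are then weakly identified).
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    rss, use_obs_rd = _photo_rss_function(records, base)

    (v_lo, v_hi), (j_lo, j_hi) = bounds
    q1, q3 = 0.25, 0.75
    starts = [
        (v_lo + q1 * (v_hi - v_lo), j_lo + q1 * (j_hi - j_lo)),
        (v_lo + q1 * (v_hi - v_lo), j_lo + q3 * (j_hi - j_lo)),
        (v_lo + q3 * (v_hi - v_lo), j_lo + q1 * (j_hi - j_lo)),
        (v_lo + q3 * (v_hi - v_lo), j_lo + q3 * (j_hi - j_lo)),
        (0.5 * (v_lo + v_hi), 0.5 * (j_lo + j_hi)),
    ]
    trace = []
    best = None
    for x0 in starts:
        res = optimize.minimize(
            rss, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10},
        )
        trace.append({"start": x0, "x": tuple(res.x), "rss": float(res.fun)})
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish: tightens the optimum well beyond the L-BFGS-B
    # gradient tolerance, which matters for noiseless closure checks
    polish = optimize.minimize(
        rss, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000},
    )
    if polish.fun <= best.fun:
        best = polish
    vcmax25, jmax25 = (float(v) for v in best.x)

    # residuals and r2 at the optimum
    fitted = _replace_capacities(base, vcmax25, jmax25)
    par = np.array([r.env.par_absorbed for r in records])
    t_c = np.array([r.env.t_leaf for r in records])
    ci = np.array([r.env.ci for r in records])
    o2 = np.array([r.env.o2 for r in records])
    a_obs = np.array([r.a_net_obs for r in records])
    arr = assimilation_arrays(par, t_c, ci, o2, fitted)
    if use_obs_rd:
        rd = np.array([r.rd_obs for r in records], dtype=float)
    else:
        rd = arr["rd"]
    pred = arr["a_gross"] - rd
    resid = a_obs - pred

    notes = {"fit_target": "net_with_observed_rd" if use_obs_rd else "net_with_modelled_rd"}
    if not (arr["light_limited"].any() and arr["rubisco_limited"].any()):
        logger.warning("data do not span both limitation regimes; fit may be weak")
        notes["spans_both_regimes"] = False
    else:
        notes["spans_both_regimes"] = True
    if np.ptp(a_obs) < 1e-9:
        logger.warning("all-flat assimilation data: parameters not identifiable")
        notes["non_identifiable"] = True

    try:
        r2 = r_squared(a_obs, pred)
    except UndefinedStatisticError:
        r2 = float("nan")
    return FitResult(
        estimates={"vcmax25": vcmax25, "jmax25": jmax25},
        rss=float(best.fun),
        r_squared=r2,
        residuals=resid,
        n_obs=len(records),
        converged=bool(best.success),
        trace=trace,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# standard-condition normalization
# ---------------------------------------------------------------------------

#: Standard condition used for emission normalization.
STANDARD_CONDITION = LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0)


def standard_emission(
    model_id: str,
    params,
    photo: PhotoParams,
    condition: LeafEnvironment = STANDARD_CONDITION,
    co2_mode: str = "none",
    ca: Optional[float] = None,
) -> float:
    """Emission of the named model at the standard condition.

    Default condition: T = 30 °C, ci = 273 µmol mol⁻¹, PAR = 1000
    µmol m⁻² s⁻¹ (overridable, including a ca-based convention for the
    CO2-modified NADPH-cost variants).  Used as the denominator Is of
    normalized response curves.
    """
    from .photo import assimilation

    if model_id == "energetic":
        state = assimilation(condition, photo)
        is_ = _models.iso_energetic(state, params)
    elif model_id == "g93":
        is_, _, _ = _models.iso_g93(condition, params)
    elif model_id == "niinemets":
        state = assimilation(condition, photo)
        is_ = _models.iso_niinemets(state, condition, params, co2_mode, ca)
    else:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {_models.MODEL_IDS}")
    if is_ == 0:
        raise ZeroDivisionError(
            "standard emission is zero: cannot normalize at this condition"
        )
    return float(is_)
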