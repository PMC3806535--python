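"""Farquhar-type C3 photosynthesis core.

Supplies the quantities every isoprene emission model in this package is
built on: the light-limited (potential) electron flux ``J`` from a
non-rectangular hyperbola of absorbed PAR, the electron flux ``Jv``
required to sustain Rubisco-limited carboxylation, the gross assimilation
rates ``Aj`` / ``Av`` and their minimum, and Arrhenius / peaked-Arrhenius
temperature responses of all kinetic constants.

Units follow leaf gas-exchange convention: photon and electron fluxes and
assimilation in µmol m⁻² s⁻¹, CO2 mole fractions in µmol mol⁻¹, O2 in
mmol mol⁻¹.  Temperatures are Kelvin internally and Celsius at every user
interface; conversion helpers are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "R_GAS",
    "T_REF_K",
    "InvalidParameterError",
    "DomainError",
    "LeafEnvironment",
    "PhotoParams",
    "PhotoState",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "arrhenius_rate",
    "peaked_rate",
    "peaked_topt",
    "kinetics_at",
    "electron_transport",
    "jv_required",
    "j_for_assimilation",
    "assimilation",
    "assimilation_arrays",
]

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Reference temperature (25 °C) for all *25 parameters, K.
T_REF_K = 298.15


class InvalidParameterError(ValueError):
    """A physically meaningless parameter value was supplied."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an expression."""


def celsius_to_kelvin(t_c):
    """Convert °C to K (array-friendly)."""
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    """Convert K to °C (array-friendly)."""
    return np.asarray(t_k, dtype=float) - 273.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafEnvironment:
    """Instantaneous leaf micro-environment: the driver triple of every
    response curve plus the O2 background.

    Parameters
    ----------
    par_absorbed : float
        Absorbed photosynthetically active radiation, µmol photons m⁻² s⁻¹.
        Any leaf-absorptance correction is the caller's responsibility.
    t_leaf : float
        Leaf temperature, °C.
    ci : float
        Leaf-internal CO2 mole fraction, µmol mol⁻¹.
    o2 : float
        O2 mole fraction, mmol mol⁻¹ (default atmospheric 210).
    """

    par_absorbed: float
    t_leaf: float
    ci: float
    o2: float = 210.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.par_absorbed, self.t_leaf, self.ci, self.o2]).all():
            raise InvalidParameterError("environment values must be finite")
        if self.par_absorbed < 0:
            raise InvalidParameterError("par_absorbed must be >= 0")
        if self.ci < 0:
            raise InvalidParameterError("ci must be >= 0")
        if not (-10.0 <= self.t_leaf <= 60.0):
            raise InvalidParameterError("t_leaf must lie in [-10, 60] degC")
        if self.o2 <= 0:
            raise InvalidParameterError("o2 must be > 0")

    @property
    def t_leaf_k(self) -> float:
        return self.t_leaf + 273.15


@dataclass(frozen=True)
class PhotoParams:
    """Farquhar model parameters.

    Capacities (``vcmax25``, ``jmax25``, ``rd25``) are values at 25 °C in
    µmol m⁻² s⁻¹.  ``alpha`` is the quantum yield of electron transport
    (mol e⁻ per mol absorbed photon) and ``theta`` the curvature of the
    light response.  Kinetic constants at 25 °C (``gamma_star25``,
    ``kc25`` in µmol mol⁻¹; ``ko25`` in mmol mol⁻¹) and the activation
    energies ``ea_*`` (J mol⁻¹) default to a standard published
    Bernacchi-type parameterization.  Each capacity supports either a
    plain Arrhenius response (``hd``/``ds`` unset) or a peaked one: by
    default Jmax is peaked (standard Medlyn-type coefficients, giving the
    electron-transport rate its interior temperature optimum) while Vcmax
    is Arrhenius; set ``hd_vcmax``/``ds_vcmax`` (e.g. 149252 / 486) to
    contrast a peaked Rubisco capacity.
    """

    vcmax25: float = 70.0
    jmax25: float = 130.0
    rd25: float = 0.5
    alpha: float = 0.3
    theta: float = 0.9
    gamma_star25: float = 42.75
    kc25: float = 404.9
    ko25: float = 278.4
    ea_vcmax: float = 65_330.0
    ea_jmax: float = 43_540.0
    ea_rd: float = 46_390.0
    ea_gamma_star: float = 37_830.0
    ea_kc: float = 79_430.0
    ea_ko: float = 36_380.0
    hd_vcmax: Optional[float] = None
    ds_vcmax: Optional[float] = None
    hd_jmax: Optional[float] = 152_044.0
    ds_jmax: Optional[float] = 495.0

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "rd25", "gamma_star25", "kc25", "ko25"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0.0 < self.theta <= 1.0):
            raise InvalidParameterError("theta must lie in (0, 1]")
        if not (0.0 < self.alpha <= 0.5):
            raise InvalidParameterError("alpha must lie in (0, 0.5]")
        for cap in ("vcmax", "jmax"):
            hd = getattr(self, f"hd_{cap}")
            ds = getattr(self, f"ds_{cap}")
            if (hd is None) != (ds is None):
                raise InvalidParameterError(
                    f"hd_{cap} and ds_{cap} must be set together"
                )
            if hd is not None and hd <= getattr(self, f"ea_{cap}"):
                raise InvalidParameterError(f"hd_{cap} must exceed ea_{cap}")

    # -- temperature-adjusted capacities -----------------------------------
    def vcmax_at(self, t_k):
        if self.hd_vcmax is None:
            return arrhenius_rate(self.vcmax25, self.ea_vcmax, t_k)
        return peaked_rate(self.vcmax25, self.ea_vcmax, self.hd_vcmax, self.ds_vcmax, t_k)

    def jmax_at(self, t_k):
        if self.hd_jmax is None:
            return arrhenius_rate(self.jmax25, self.ea_jmax, t_k)
        return peaked_rate(self.jmax25, self.ea_jmax, self.hd_jmax, self.ds_jmax, t_k)

    def rd_at(self, t_k):
        return arrhenius_rate(self.rd25, self.ea_rd, t_k)


@dataclass(frozen=True)
class PhotoState:
    """Derived photosynthetic fluxes at one leaf environment.

    ``j`` is the light-limited (potential) electron flux, used throughout
    as the estimate of total linear electron transport; ``jv`` is the
    electron flux that Rubisco-limited carboxylation would consume.  Their
    difference is the electron excess (or deficit) driving the energetic
    isoprene model.  ``limitation`` is ``"light"`` where Aj < Av,
    ``"rubisco"`` where Av < Aj, and ``"co_limited"`` at a tie.
    """

    env: LeafEnvironment
    j: float
    jv: float
    aj: float
    av: float
    a_gross: float
    a_net: float
    gamma_star: float
    km: float
    rd: float
    limitation: str

    @property
    def j_minus_jv(self) -> float:
        return self.j - self.jv


# ---------------------------------------------------------------------------
# temperature responses
# ---------------------------------------------------------------------------


def arrhenius_rate(k25, ea, t):
    """Arrhenius temperature scaling of a rate from its 25 °C value.

    ``k25 * exp(ea * (t - 298.15) / (298.15 * R * t))`` — equals ``k25``
    at 25 °C and is strictly increasing in ``t`` for ``ea > 0``.

    Parameters
    ----------
    k25 : float or ndarray
        Rate at 25 °C (> 0).
    ea : float
        Activation energy, J mol⁻¹.
    t : float or ndarray
        Temperature, K (> 0).
    """
    k25 = np.asarray(k25, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(k25 <= 0):
        raise InvalidParameterError("k25 must be > 0")
    if np.any(t <= 0):
        raise InvalidParameterError("temperature must be > 0 K")
    out = k25 * np.exp(ea * (t - T_REF_K) / (T_REF_K * R_GAS * t))
    return out.item() if out.ndim == 0 else out


def peaked_rate(k25, ea, hd, ds, t):
    """Peaked (deactivating) Arrhenius response, normalized to ``k25`` at 25 °C.

    The Arrhenius numerator is modulated by the standard enzyme
    deactivation term so the response has a single interior maximum at
    ``Topt = hd / (ds - R*ln(ea / (hd - ea)))``.

    Parameters are as for :func:`arrhenius_rate` plus the deactivation
    enthalpy ``hd`` (J mol⁻¹, must exceed ``ea``) and entropy ``ds``
    (J mol⁻¹ K⁻¹).
    """
    if hd <= ea:
        raise InvalidParameterError("hd must exceed ea")
    t = np.asarray(t, dtype=float)
    base = arrhenius_rate(k25, ea, t)
    ref_term = 1.0 + math.exp((T_REF_K * ds - hd) / (T_REF_K * R_GAS))
    t_term = 1.0 + np.exp((t * ds - hd) / (t * R_GAS))
    out = np.asarray(base) * ref_term / t_term
    return out.item() if out.ndim == 0 else out


def peaked_topt(ea, hd, ds) -> float:
    """Closed-form temperature (K) of the :func:`peaked_rate` maximum."""
    if hd <= ea:
        raise InvalidParameterError("hd must exceed ea")
    return hd / (ds - R_GAS * math.log(ea / (hd - ea)))


def kinetics_at(t, o2, params: PhotoParams):
    """Temperature-adjusted Rubisco kinetics.

    Returns ``(gamma_star, km)`` at temperature ``t`` (K): the CO2
    compensation point in the absence of dark respiration (µmol mol⁻¹)
    and the effective Michaelis constant
    ``Km = Kc * (1 + o2 / Ko)`` (µmol mol⁻¹), with Γ*, Kc and Ko each
    Arrhenius-scaled from their 25 °C values.
    """
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise InvalidParameterError("o2 must be >= 0")
    gamma_star = arrhenius_rate(params.gamma_star25, params.ea_gamma_star, t)
    kc = arrhenius_rate(params.kc25, params.ea_kc, t)
    ko = arrhenius_rate(params.ko25, params.ea_ko, t)
    km = kc * (1.0 + o2 / ko)
    if np.ndim(km) == 0:
        km = float(km)
    return gamma_star, km


# ---------------------------------------------------------------------------
# electron fluxes and assimilation
# ---------------------------------------------------------------------------


def electron_transport(par_absorbed, jmax, alpha, theta):
    """Light-limited electron flux J from the non-rectangular hyperbola.

    J is the smaller root of ``theta*J**2 - (alpha*Q + Jmax)*J +
    alpha*Q*Jmax = 0``; it satisfies ``0 <= J <= min(alpha*Q, Jmax)``, is
    continuous and nondecreasing in Q, and for ``theta == 0`` degenerates
    to the rectangular hyperbola ``alpha*Q*Jmax / (alpha*Q + Jmax)``.
    """
    q = np.asarray(par_absorbed, dtype=float)
    jmax = np.asarray(jmax, dtype=float)
    if np.any(q < 0):
        raise InvalidParameterError("par_absorbed must be >= 0")
    if np.any(jmax < 0):
        raise InvalidParameterError("jmax must be >= 0")
    if not (0.0 <= theta <= 1.0):
        raise InvalidParameterError("theta must lie in [0, 1]")
    if alpha < 0:
        raise InvalidParameterError("alpha must be >= 0")
    aq = alpha * q
    if theta == 0.0:
        denom = aq + jmax
        with np.errstate(invalid="ignore", divide="ignore"):
            j = np.where(denom > 0, aq * jmax / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        b = aq + jmax
        disc = b * b - 4.0 * theta * aq * jmax
        disc = np.maximum(disc, 0.0)  # guard tiny negative round-off
        j = (b - np.sqrt(disc)) / (2.0 * theta)
    j = np.minimum(j, np.minimum(aq, jmax))  # clip round-off above the bound
    j = np.maximum(j, 0.0)
    return j.item() if j.ndim == 0 else j


def jv_required(vcmax, ci, gamma_star, km):
    """Electron flux needed to sustain Rubisco-limited carboxylation.

    ``Jv = 4 * Vcmax * (ci + 2*gamma_star) / (ci + km)`` — the demand side
    of the electron balance.  Defined for all ``ci >= 0``, including below
    the compensation point.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(ci + km <= 0):
        raise InvalidParameterError("ci + km must be > 0")
    out = 4.0 * vcmax * (ci + 2.0 * gamma_star) / (ci + km)
    return out.item() if out.ndim == 0 else out


def j_for_assimilation(a_gross, ci, gamma_star):
    """Electron flux required to support a gross assimilation rate.

    ``J = 4 * A * (ci + 2*gamma_star) / (ci - gamma_star)``; singular at
    the compensation point, hence requires ``ci > gamma_star``.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= gamma_star):
        raise DomainError(
            "ci must exceed gamma_star: the electron cost per CO2 diverges "
            "at the compensation point ci = gamma_star"
        )
    out = 4.0 * np.asarray(a_gross, dtype=float) * (ci + 2.0 * gamma_star) / (ci - gamma_star)
    return out.item() if out.ndim == 0 else out


def assimilation_arrays(par_absorbed, t_leaf_c, ci, o2, params: PhotoParams) -> dict:
    """Vectorized assimilation over broadcastable driver arrays.

    Returns a dict of arrays: ``j, jv, aj, av, a_gross, a_net,
    gamma_star, km, rd, light_limited, rubisco_limited``.  Gross rates are
    clamped at zero for ``ci <= gamma_star``.
    """
    par, t_c, ci, o2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (par_absorbed, t_leaf_c, ci, o2))
    )
    t_k = t_c + 273.15
    gamma_star, km = kinetics_at(t_k, o2, params)
    gamma_star = np.asarray(gamma_star, dtype=float)
    km = np.asarray(km, dtype=float)
    vcmax = np.asarray(params.vcmax_at(t_k), dtype=float)
    jmax = np.asarray(params.jmax_at(t_k), dtype=float)
    rd = np.asarray(params.rd_at(t_k), dtype=float)
    j = np.asarray(electron_transport(par, jmax, params.alpha, params.theta))
    co2_factor = (ci - gamma_star) / (ci + 2.0 * gamma_star)
    aj = np.maximum((j / 4.0) * co2_factor, 0.0)
    av = np.maximum(vcmax * (ci - gamma_star) / (ci + km), 0.0)
    jv = np.asarray(jv_required(vcmax, ci, gamma_star, km))
    a_gross = np.minimum(aj, av)
    a_net = a_gross - rd
    # tie tolerance: co-limited when the two gross rates agree to round-off
    tie = np.isclose(aj, av, rtol=1e-9, atol=1e-12)
    return {
        "j": j,
        "jv": jv,
        "aj": aj,
        "av": av,
        "a_gross": a_gross,
        "a_net": a_net,
        "gamma_star": gamma_star + np.zeros_like(t_c),
        "km": km + np.zeros_like(t_c),
        "rd": rd + np.zeros_like(t_c),
        "light_limited": (aj < av) & ~tie,
        "rubisco_limited": (av < aj) & ~tie,
    }


def assimilation(env: LeafEnvironment, params: PhotoParams) -> PhotoState:
    """Full Farquhar evaluation at one leaf environment.

    Computes temperature-adjusted kinetics, J from absorbed PAR, the
    light- and Rubisco-limited gross rates (clamped at zero below the
    compensation point), the Rubisco electron demand Jv, and
    ``Agross = min(Aj, Av)``, ``Anet = Agross - Rd(T)``.
    """
    arr = assimilation_arrays(env.par_absorbed, env.t_leaf, env.ci, env.o2, params)
    if arr["light_limited"]:
        limitation = "light"
    elif arr["rubisco_limited"]:
        limitation = "rubisco"
    else:
        limitation = "co_limited"
    return PhotoState(
        env=env,
        j=float(arr["j"]),
        jv=float(arr["jv"]),
        aj=float(arr["aj"]),
        av=float(arr["av"]),
        a_gross=float(arr["a_gross"]),
        a_net=float(arr["a_net"]),
        gamma_star=float(arr["gamma_star"]),
        km=float(arr["km"]),
        rd=float(arr["rd"]),
        limitation=limitation,
    )
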