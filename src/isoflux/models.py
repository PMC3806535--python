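"""Leaf isoprene emission models.

Three models of instantaneous leaf isoprene emission are implemented over
the same photosynthesis core:

* the **energetic-balance model** — emission proportional to the
  light-limited electron flux J plus the excess of J over the electron
  demand Jv of Rubisco-limited carboxylation, gated by a leaf-internal
  CO2 ramp ``f(ci)``:

  ``Iso = f(ci) * [a*J + b*(J - Jv)]``  (floored at zero);

* the **G93 activity-factor algorithm** — an empirical standard emission
  factor scaled by light (CL) and temperature (CT) factors, with no ci
  dependence;

* the **NADPH-cost (Niinemets-type) model** — a temperature-dependent
  fraction ε of the electron flux routed to isoprene, divided by the
  electron cost of isoprene synthesis, optionally multiplied by an
  empirical CO2 modifier.

Emissions are in nmol isoprene m⁻² s⁻¹; electron fluxes in
µmol e⁻ m⁻² s⁻¹.  The energetic coefficients a, b therefore carry units
of nmol isoprene per µmol e⁻.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .photo import (
    R_GAS,
    T_REF_K,
    InvalidParameterError,
    LeafEnvironment,
    PhotoState,
    peaked_rate,
    peaked_topt,
)

__all__ = [
    "EnergeticIsoParams",
    "G93Params",
    "NiinemetsParams",
    "IspSParams",
    "PathwayStoichiometry",
    "f_ci",
    "iso_energetic",
    "energetic_emission",
    "iso_g93",
    "g93_factors",
    "iso_niinemets",
    "niinemets_emission",
    "isps_activity",
    "apply_isps_modulation",
    "nadph_per_isoprene",
    "nadph_supply_per_electron",
    "MODEL_IDS",
]

MODEL_IDS = ("energetic", "g93", "niinemets")


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergeticIsoParams:
    """Coefficients of the electron-balance emission model.

    ``a`` scales the baseline term a*J active when electron supply equals
    Rubisco demand; ``b`` scales the supply–demand imbalance term
    b*(J - Jv).  Both in nmol isoprene per µmol e⁻.  A fitted ``b < 0``
    is physically suspect but tolerated with a warning so that noisy fits
    can still be inspected.
    """

    a: float = 0.3
    b: float = 0.1

    def __post_init__(self) -> None:
        if self.a < 0:
            raise InvalidParameterError("a must be >= 0")
        if self.b < 0:
            warnings.warn(
                "EnergeticIsoParams.b < 0: imbalance coefficient is expected "
                "to be nonnegative",
                stacklevel=2,
            )


@dataclass(frozen=True)
class G93Params:
    """G93 activity-factor coefficients (canonical published defaults).

    ``i_s`` is the standard emission factor (nmol m⁻² s⁻¹); ``alpha_l``
    and ``cl1`` shape the light factor; ``ct1``/``ct2`` (J mol⁻¹) and
    ``t_s``/``t_m`` (K) shape the temperature factor, whose optimum sits
    near 38 °C with the defaults.
    """

    i_s: float = 30.0
    alpha_l: float = 0.0027
    cl1: float = 1.066
    ct1: float = 95_000.0
    ct2: float = 230_000.0
    t_s: float = 303.0
    t_m: float = 314.0

    def __post_init__(self) -> None:
        if self.i_s < 0:
            raise InvalidParameterError("i_s must be >= 0")
        if not (self.ct2 > self.ct1 > 0):
            raise InvalidParameterError("require ct2 > ct1 > 0")
        if not (self.t_m > self.t_s):
            raise InvalidParameterError("require t_m > t_s")


@dataclass(frozen=True)
class NiinemetsParams:
    """NADPH-cost model coefficients.

    ``eps`` is the fraction of electron flux routed to isoprene at the
    reference temperature ``t_ref_c``; it rises exponentially with
    temperature at rate ``eps_t_coeff`` (K⁻¹), optionally capped at
    ``eps * eps_cap`` (the capped variant used in some global modelling).
    ``cost_ci_coeff`` and ``cost_gs_coeff`` are the electron-cost
    coefficients of the denominator ``6*(cost_ci_coeff*ci +
    cost_gs_coeff*gamma_star)``; defaults are the canonical published
    pair.
    """

    eps: float = 0.02
    eps_t_coeff: float = 0.1
    eps_cap: Optional[float] = None
    cost_ci_coeff: float = 4.67
    cost_gs_coeff: float = 9.33
    t_ref_c: float = 30.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise InvalidParameterError("eps must be > 0")
        if self.eps_cap is not None and self.eps_cap < 1:
            raise InvalidParameterError("eps_cap must be >= 1 when present")
        if self.cost_ci_coeff <= 0 or self.cost_gs_coeff <= 0:
            raise InvalidParameterError("cost coefficients must be > 0")


@dataclass(frozen=True)
class IspSParams:
    """Normalized thermal activity curve of isoprene synthase.

    A peaked-Arrhenius activation/deactivation curve rescaled to a
    maximum of 1 at its optimum; defaults place the optimum near 45.4 °C,
    inside the 45–48 °C window reported for the enzyme.
    """

    ea: float = 83_129.0
    hd: float = 284_600.0
    ds: float = 886.0

    def __post_init__(self) -> None:
        if self.hd <= self.ea:
            raise InvalidParameterError("hd must exceed ea")

    @property
    def t_opt_k(self) -> float:
        return peaked_topt(self.ea, self.hd, self.ds)


@dataclass(frozen=True)
class PathwayStoichiometry:
    """NADPH costs of isoprene synthesis through the MEP pathway.

    Per molecule of isoprene: the Calvin-cycle costs of its two carbon
    precursors (6 NADPH for G3P, 5 for pyruvate) plus the supplementary
    MEP-pathway reduction steps (1 further NADPH and 2 additional
    reducing equivalents counted as NADPH), totalling 14.
    """

    nadph_g3p: int = 6
    nadph_pyruvate: int = 5
    nadph_mep_extra: int = 1
    reducing_equiv_extra: int = 2

    def __post_init__(self) -> None:
        for name in (
            "nadph_g3p",
            "nadph_pyruvate",
            "nadph_mep_extra",
            "reducing_equiv_extra",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise InvalidParameterError(f"{name} must be a nonnegative integer")


# ---------------------------------------------------------------------------
# energetic-balance model
# ---------------------------------------------------------------------------


def f_ci(ci, gamma_star):
    """Leaf-internal CO2 gate of the energetic model.

    A piecewise-linear ramp: ``ci/gamma_star`` for ``ci <= gamma_star``
    and 1 above, continuous at the compensation point.  Encodes the
    requirement of a minimum carbon-skeleton supply — emission ceases as
    ci approaches zero.
    """
    gamma_star = np.asarray(gamma_star, dtype=float)
    if np.any(gamma_star <= 0):
        raise InvalidParameterError("gamma_star must be > 0")
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise InvalidParameterError("ci must be >= 0")
    out = np.minimum(ci / gamma_star, 1.0)
    return out.item() if out.ndim == 0 else out


def energetic_emission(j, jv, ci, gamma_star, params: EnergeticIsoParams):
    """Array core of the energetic-balance model (nmol m⁻² s⁻¹).

    ``f(ci) * [a*J + b*(J - Jv)]`` floored at zero: the bracket can fall
    below a*J (and below zero) under a strong electron deficit J < Jv.
    """
    j = np.asarray(j, dtype=float)
    jv = np.asarray(jv, dtype=float)
    bracket = params.a * j + params.b * (j - jv)
    out = np.maximum(f_ci(ci, gamma_star) * bracket, 0.0)
    return out.item() if out.ndim == 0 else out


def iso_energetic(state: PhotoState, params: EnergeticIsoParams) -> float:
    """Energetic-balance emission at one photosynthetic state."""
    return float(
        energetic_emission(state.j, state.jv, state.env.ci, state.gamma_star, params)
    )


# ---------------------------------------------------------------------------
# G93
# ---------------------------------------------------------------------------


def g93_factors(par_absorbed, t_k, params: G93Params):
    """The G93 light and temperature activity factors (CL, CT)."""
    q = np.asarray(par_absorbed, dtype=float)
    t = np.asarray(t_k, dtype=float)
    c_l = params.alpha_l * params.cl1 * q / np.sqrt(1.0 + params.alpha_l**2 * q * q)
    rts = R_GAS * params.t_s * t
    c_t = np.exp(params.ct1 * (t - params.t_s) / rts) / (
        1.0 + np.exp(params.ct2 * (t - params.t_m) / rts)
    )
    return c_l, c_t


def iso_g93(env: LeafEnvironment, params: G93Params):
    """G93 emission ``i_s * CL * CT`` at one environment.

    Returns ``(emission, c_l, c_t)``.  By construction the emission has no
    ci dependence at all.
    """
    c_l, c_t = g93_factors(env.par_absorbed, env.t_leaf_k, params)
    return float(params.i_s * c_l * c_t), float(c_l), float(c_t)


# ---------------------------------------------------------------------------
# NADPH-cost (Niinemets-type) model
# ---------------------------------------------------------------------------

CO2_MODES = ("none", "f_ci", "f_ca")

#: Reference atmospheric CO2 (µmol mol⁻¹) of the empirical CO2 modifiers.
CA_REF = 390.0

#: Conventional ci at the reference ca (ci/ca ≈ 0.7).
CI_AT_CA_REF = 273.0


def _eps_at(t_k, params: NiinemetsParams):
    t_ref_k = params.t_ref_c + 273.15
    eps = params.eps * np.exp(params.eps_t_coeff * (np.asarray(t_k, float) - t_ref_k))
    if params.eps_cap is not None:
        eps = np.minimum(eps, params.eps * params.eps_cap)
    return eps


def niinemets_emission(
    j,
    ci,
    gamma_star,
    t_k,
    params: NiinemetsParams,
    co2_mode: str = "none",
    ca=None,
):
    """Array core of the NADPH-cost model (nmol m⁻² s⁻¹).

    ``1000 * eps(T) * J * (ci - gamma_star) / (6 * (c1*ci + c2*gamma_star))``
    times the selected CO2 modifier (``none`` → 1, ``f_ci`` → 273/ci,
    ``f_ca`` → 390/ca), clamped at zero for ci at or below the
    compensation point.  The 1000 converts µmol to nmol.
    """
    if co2_mode not in CO2_MODES:
        raise ValueError(f"unknown co2_mode {co2_mode!r}; expected one of {CO2_MODES}")
    j = np.asarray(j, dtype=float)
    ci = np.asarray(ci, dtype=float)
    gamma_star = np.asarray(gamma_star, dtype=float)
    eps = _eps_at(t_k, params)
    denom = 6.0 * (params.cost_ci_coeff * ci + params.cost_gs_coeff * gamma_star)
    core = eps * j * np.maximum(ci - gamma_star, 0.0) / denom
    if co2_mode == "f_ci":
        with np.errstate(divide="ignore"):
            core = core * np.where(ci > 0, CI_AT_CA_REF / np.where(ci > 0, ci, 1.0), 0.0)
    elif co2_mode == "f_ca":
        if ca is None:
            raise ValueError("co2_mode='f_ca' requires ca")
        core = core * (CA_REF / np.asarray(ca, dtype=float))
    out = 1000.0 * core
    return out.item() if out.ndim == 0 else out


def iso_niinemets(
    state: PhotoState,
    env: LeafEnvironment,
    params: NiinemetsParams,
    co2_mode: str = "none",
    ca: Optional[float] = None,
) -> float:
    """NADPH-cost emission at one photosynthetic state."""
    return float(
        niinemets_emission(
            state.j, env.ci, state.gamma_star, env.t_leaf_k, params, co2_mode, ca
        )
    )


# ---------------------------------------------------------------------------
# isoprene synthase thermal activity
# ---------------------------------------------------------------------------


def isps_activity(t_k, params: IspSParams = IspSParams()):
    """Normalized isoprene synthase activity in [0, 1] at temperature t (K).

    A peaked activation/deactivation curve rescaled so the maximum — at
    ``params.t_opt_k`` — is exactly 1.
    """
    peak = peaked_rate(1.0, params.ea, params.hd, params.ds, params.t_opt_k)
    out = np.asarray(peaked_rate(1.0, params.ea, params.hd, params.ds, t_k)) / peak
    out = np.minimum(out, 1.0)
    return out.item() if out.ndim == 0 else out


def apply_isps_modulation(emission_series, activity_series, renormalize_index=None):
    """Elementwise product of an emission series with an activity series.

    Both series must be aligned on the same temperature grid (equal
    length).  When ``renormalize_index`` is given, the product is rescaled
    to equal 1 at that index (the declared reference condition).
    """
    e = np.asarray(emission_series, dtype=float)
    a = np.asarray(activity_series, dtype=float)
    if e.shape != a.shape:
        raise ValueError(
            f"emission and activity grids differ in shape: {e.shape} vs {a.shape}"
        )
    prod = e * a
    if renormalize_index is not None:
        ref = prod[renormalize_index]
        if ref == 0:
            raise ValueError("cannot renormalize: reference value is zero")
        prod = prod / ref
    return prod


# ---------------------------------------------------------------------------
# MEP pathway stoichiometry
# ---------------------------------------------------------------------------


def nadph_per_isoprene(stoich: PathwayStoichiometry = PathwayStoichiometry()) -> int:
    """Total NADPH demand per isoprene molecule (14 with default costs)."""
    return (
        stoich.nadph_g3p
        + stoich.nadph_pyruvate
        + stoich.nadph_mep_extra
        + stoich.reducing_equiv_extra
    )


def nadph_supply_per_electron() -> float:
    """NADPH generated per electron of linear transport (two e⁻ per NADPH)."""
    return 0.5
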