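"""Seeded synthetic gas-exchange + isoprene datasets.

Generates datasets with the statistical structure the fitting procedures
assume: a deterministic truth computed from the photosynthesis core and
the energetic emission model, plus independent multiplicative Gaussian
noise on the assimilation and isoprene channels (observed = truth *
(1 + eps), eps ~ N(0, CV^2)), truncated so observed isoprene stays
nonnegative.  Three designs are supported:

* ``light_response`` — a PAR sweep at fixed ci and T (the classic
  kudzu-type light response);
* ``ci_response`` — a ci sweep at fixed PAR and T (Acacia-type);
* ``tp_grid`` — a factorial temperature × PAR grid at fixed ci.

The master seed is split into two independent substreams (assimilation,
isoprene), so the channels are reproducible and uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .photo import (
    InvalidParameterError,
    LeafEnvironment,
    PhotoParams,
    assimilation_arrays,
)
from .models import EnergeticIsoParams, energetic_emission

__all__ = ["DatasetDesign", "generate_dataset", "demo_fixtures"]

DESIGN_KINDS = ("light_response", "ci_response", "tp_grid")


@dataclass(frozen=True)
class DatasetDesign:
    """Specification of one synthetic dataset.

    ``grid`` is the driver grid (PAR for light_response, ci for
    ci_response); ``tp_grid`` uses ``t_grid`` × ``grid`` (PAR).  ``cv_a``
    and ``cv_iso`` are the relative noise levels of the two channels
    (default 5 %, a realistic repeatability for leaf cuvette work);
    ``replicates`` repeats every grid point.
    """

    kind: str
    grid: Sequence[float]
    photo: PhotoParams
    iso: EnergeticIsoParams
    fixed: LeafEnvironment = LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0)
    t_grid: Optional[Sequence[float]] = None
    cv_a: float = 0.05
    cv_iso: float = 0.05
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.kind not in DESIGN_KINDS:
            problems.append(f"kind must be one of {DESIGN_KINDS}, got {self.kind!r}")
        if self.cv_a < 0 or self.cv_iso < 0:
            problems.append("cv_a and cv_iso must be >= 0")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if len(np.asarray(self.grid)) == 0:
            problems.append("grid must be nonempty")
        if self.kind == "tp_grid" and self.t_grid is None:
            problems.append("tp_grid design requires t_grid")
        if problems:
            raise InvalidParameterError("; ".join(problems))


def _design_drivers(design: DatasetDesign):
    grid = np.asarray(design.grid, dtype=float)
    f = design.fixed
    if design.kind == "light_response":
        par, t_c, ci = grid, np.full_like(grid, f.t_leaf), np.full_like(grid, f.ci)
    elif design.kind == "ci_response":
        par, t_c, ci = np.full_like(grid, f.par_absorbed), np.full_like(grid, f.t_leaf), grid
    else:  # tp_grid
        tt, qq = np.meshgrid(np.asarray(design.t_grid, float), grid, indexing="ij")
        par, t_c = qq.ravel(), tt.ravel()
        ci = np.full_like(par, f.ci)
    o2 = np.full_like(par, f.o2)
    reps = design.replicates
    return (np.tile(par, reps), np.tile(t_c, reps), np.tile(ci, reps), np.tile(o2, reps))


def generate_dataset(design: DatasetDesign):
    """Generate one dataset.

    Returns ``(table, truth)``: a DataFrame with columns ``par,
    t_leaf_c, ci, o2, a_net, iso, a_net_true, iso_true`` and a metadata
    dict embedding the generating parameters and seed, so recovery tests
    can compare estimates against the truth.  Deterministic for a fixed
    seed; at CV = 0 the observed columns equal the truth exactly.
    """
    par, t_c, ci, o2 = _design_drivers(design)
    arr = assimilation_arrays(par, t_c, ci, o2, design.photo)
    a_net_true = arr["a_net"]
    iso_true = np.asarray(
        energetic_emission(arr["j"], arr["jv"], ci, arr["gamma_star"], design.iso)
    )

    ss = np.random.SeedSequence(design.seed)
    rng_a, rng_iso = (np.random.default_rng(s) for s in ss.spawn(2))
    n = par.size
    a_net = a_net_true * (1.0 + (rng_a.normal(0.0, design.cv_a, n) if design.cv_a else 0.0))
    iso = iso_true * (1.0 + (rng_iso.normal(0.0, design.cv_iso, n) if design.cv_iso else 0.0))
    iso = np.maximum(iso, 0.0)  # emissions cannot be negative

    table = pd.DataFrame({
        "par": par, "t_leaf_c": t_c, "ci": ci, "o2": o2,
        "a_net": a_net, "iso": iso,
        "a_net_true": a_net_true, "iso_true": iso_true,
    })
    truth = {
        "design": design.kind,
        "seed": design.seed,
        "cv_a": design.cv_a,
        "cv_iso": design.cv_iso,
        "photo": asdict(design.photo),
        "iso_params": asdict(design.iso),
        "fixed": {"par_absorbed": design.fixed.par_absorbed,
                  "t_leaf": design.fixed.t_leaf,
                  "ci": design.fixed.ci, "o2": design.fixed.o2},
    }
    return table, truth


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

#: Truth parameters of the fixture leaf (capacities of a vigorous
#: broadleaf emitter; emission coefficients giving standard-condition
#: emission of a few tens of nmol m⁻² s⁻¹).
FIXTURE_PHOTO = PhotoParams(vcmax25=70.0, jmax25=130.0, rd25=0.5)
FIXTURE_ISO = EnergeticIsoParams(a=0.3, b=0.1)


def demo_fixtures() -> dict:
    """Deterministic noiseless fixture datasets with documented truth.

    * ``light_response`` — PAR 350–2000 at ci = 273, T = 30 °C, chosen so
      the electron balance spans deficit through excess while the truth
      emission stays strictly positive (no zero-floor censoring);
    * ``ci_response`` — ci 20–800 at PAR = 1000, T = 30 °C, spanning the
      below-compensation ramp, the near-Γ* emission maximum and the
      high-ci decline;
    * ``three_par_ci`` — the same ci grid at PAR 80, 180 and 700.

    Each entry is ``(table, truth)`` as returned by
    :func:`generate_dataset`; regenerated identically on every call.
    """
    light = DatasetDesign(
        kind="light_response",
        grid=np.arange(350.0, 2001.0, 50.0),
        photo=FIXTURE_PHOTO,
        iso=FIXTURE_ISO,
        fixed=LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0),
        cv_a=0.0, cv_iso=0.0, seed=0,
    )
    ci_resp = DatasetDesign(
        kind="ci_response",
        grid=np.arange(20.0, 801.0, 20.0),
        photo=FIXTURE_PHOTO,
        iso=FIXTURE_ISO,
        fixed=LeafEnvironment(par_absorbed=1000.0, t_leaf=30.0, ci=273.0),
        cv_a=0.0, cv_iso=0.0, seed=0,
    )
    out = {
        "light_response": generate_dataset(light),
        "ci_response": generate_dataset(ci_resp),
    }
    frames = []
    for q in (80.0, 180.0, 700.0):
        d = DatasetDesign(
            kind="ci_response",
            grid=np.arange(20.0, 801.0, 20.0),
            photo=FIXTURE_PHOTO,
            iso=FIXTURE_ISO,
            fixed=LeafEnvironment(par_absorbed=q, t_leaf=30.0, ci=273.0),
            cv_a=0.0, cv_iso=0.0, seed=0,
        )
        t, _ = generate_dataset(d)
        frames.append(t)
    out["three_par_ci"] = (
        pd.concat(frames, ignore_index=True),
        {"design": "ci_response", "par_levels": [80.0, 180.0, 700.0],
         "photo": asdict(FIXTURE_PHOTO), "iso_params": asdict(FIXTURE_ISO)},
    )
    return out
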