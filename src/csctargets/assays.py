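"""Nonlinear binding-assay models for antibody characterization.

Three models cover the standard candidate-characterization assays:

* one-site saturation binding, ``Y = Bmax * X / (KD + X)`` — flow-cytometry or
  ELISA titrations; the half-maximal concentration (EC50) coincides with the
  apparent dissociation constant KD,
* the four-parameter logistic (4PL) competition curve,
  ``Y = bottom + (top - bottom) / (1 + (X / IC50)^hill)``,
* the 1:1 (Langmuir) surface-plasmon-resonance kinetic model with association
  rate ka (1/(M*s)), dissociation rate kd (1/s) and affinity KD = kd/ka.

All fits use deterministic multi-start least squares from a log-spaced
parameter grid, so results are reproducible without a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ConfigError, DataError

__all__ = [
    "DoseResponse",
    "Sensorgram",
    "AssayFit",
    "one_site",
    "four_pl",
    "sensorgram_response",
    "fit_one_site",
    "fit_4pl",
    "fit_spr",
    "mass_to_molar",
    "molar_to_mass",
    "serial_dilution",
    "IGG_MW_KDA",
]

#: Default IgG molecular weight (kDa) used for mass <-> molar conversion.
IGG_MW_KDA = 150.0


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------
def mass_to_molar(c_mass: float, mw_kda: float = IGG_MW_KDA):
    """Convert a mass concentration (µg/mL) to molarity (nM).

    nM = µg/mL / kDa * 1000.  E.g. an IgG (150 kDa) at 0.18 µg/mL is 1.2 nM.
    """
    c_mass = np.asarray(c_mass, dtype=float)
    if np.any(c_mass <= 0) or mw_kda <= 0:
        raise ConfigError("mass concentration and molecular weight must be > 0")
    out = c_mass / mw_kda * 1000.0
    return float(out) if out.ndim == 0 else out


def molar_to_mass(c_nm: float, mw_kda: float = IGG_MW_KDA):
    """Inverse of :func:`mass_to_molar`: nM -> µg/mL."""
    c_nm = np.asarray(c_nm, dtype=float)
    if np.any(c_nm <= 0) or mw_kda <= 0:
        raise ConfigError("molar concentration and molecular weight must be > 0")
    out = c_nm * mw_kda / 1000.0
    return float(out) if out.ndim == 0 else out


def serial_dilution(top: float = 30.0, factor: float = 3.0, n: int = 8) -> np.ndarray:
    """Concentration grid of ``n`` points by serial ``1:factor`` dilution from ``top``.

    The default reproduces an 8-point 1:3 series from 30 down to ~0.014 µg/mL.
    Returned ascending.
    """
    if top <= 0 or factor <= 1 or n < 2:
        raise ConfigError("need top > 0, factor > 1, n >= 2")
    return top / factor ** np.arange(n - 1, -1, -1, dtype=float)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------
def one_site(x, bmax, kd):
    """One-site saturation binding ``Bmax * x / (KD + x)``."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def four_pl(x, top, bottom, ic50, hill):
    """Four-parameter logistic ``bottom + (top-bottom)/(1 + (x/IC50)^hill)``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def sensorgram_response(t, conc, ka, kd, rmax, t_assoc):
    """1:1 binding-model response at time(s) ``t`` for analyte concentration ``conc`` (M).

    Association (t <= t_assoc):
        R(t) = C*ka*Rmax/(C*ka + kd) * (1 - exp(-(C*ka + kd) * t))
    Dissociation (t > t_assoc):
        R(t) = R(t_assoc) * exp(-kd * (t - t_assoc))
    """
    t = np.asarray(t, dtype=float)
    kobs = conc * ka + kd
    req = conc * ka * rmax / kobs
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    r = np.where(t <= t_assoc, r_assoc, r_end * np.exp(-kd * (t - t_assoc)))
    return r


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class DoseResponse:
    """Concentration/response table for a titration assay.

    ``concentration`` in µg/mL (or nM — the fits are unit-agnostic), strictly
    positive; ``response`` in arbitrary units (MFI fold-change, A450, % of
    control).  Replicates are rows with repeated concentrations.
    """

    concentration: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    units: str = "ug/mL"

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise DataError("concentration and response must have equal length")
        if np.any(self.concentration <= 0):
            raise DataError("concentrations must be > 0")
        if not np.all(np.isfinite(self.response)):
            raise DataError("responses must be finite")

    @property
    def n_distinct(self) -> int:
        return np.unique(self.concentration).size

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"concentration": self.concentration, "response": self.response}
        )
        if self.replicate is not None:
            df["replicate"] = self.replicate
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(df["concentration"].to_numpy(), df["response"].to_numpy(), rep)


@dataclass
class Sensorgram:
    """Single-concentration SPR trace (reference-subtracted), response in RU."""

    time: np.ndarray
    response: np.ndarray
    concentration: float  # molar
    t_assoc: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise DataError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if self.concentration <= 0:
            raise DataError("analyte concentration must be > 0")


def sensorgrams_to_csv(sensorgrams: list[Sensorgram], path) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time": sg.time,
                    "response": sg.response,
                    "concentration": sg.concentration,
                    "phase": np.where(sg.time <= sg.t_assoc, "association", "dissociation"),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("concentration"):
        t_assoc = grp.loc[grp["phase"] == "association", "time"].max()
        grp = grp.sort_values("time")
        out.append(
            Sensorgram(grp["time"].to_numpy(), grp["response"].to_numpy(), conc, t_assoc)
        )
    return out


@dataclass
class AssayFit:
    """Result of a nonlinear assay fit."""

    model: str
    params: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    flags: list[str] = field(default_factory=list)
    params_nm: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "rss": self.rss,
            "converged": self.converged,
            "flags": self.flags,
            "params_nm": self.params_nm,
        }


def _se_from_jac(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from a least_squares result."""
    n_par = res.x.size
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------
def fit_one_site(dr: DoseResponse, mw_kda: float | None = None) -> AssayFit:
    """Least-squares fit of the one-site binding model.

    Bmax is profiled out in closed form on a log-spaced KD grid, then both
    parameters are polished jointly.  A flat response is flagged as
    non-convergent (KD unidentifiable) and parameters are withheld.
    """
    if dr.n_distinct < 4:
        raise DataError("one-site fit needs >= 4 distinct concentrations")
    x, y = dr.concentration, dr.response
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return AssayFit(model="one_site", converged=False, flags=["flat-response"])

    kd_grid = np.geomspace(x.min() / 100.0, x.max() * 100.0, 81)
    best = None
    for kd in kd_grid:
        f = x / (kd + x)
        bmax = float(f @ y / (f @ f))
        rss = float(np.sum((y - bmax * f) ** 2))
        if best is None or rss < best[0]:
            best = (rss, bmax, kd)
    _, bmax0, kd0 = best

    def resid(p):
        return one_site(x, p[0], np.exp(p[1])) - y

    res = least_squares(resid, x0=[bmax0, np.log(kd0)], method="lm", xtol=1e-14, ftol=1e-14)
    bmax, kd = float(res.x[0]), float(np.exp(res.x[1]))
    se = _se_from_jac(res, x.size)
    fit = AssayFit(
        model="one_site",
        params={"bmax": bmax, "kd": kd, "ec50": kd},
        se={"bmax": float(se[0]), "kd": float(kd * se[1])},
        rss=float(np.sum(resid(res.x) ** 2)),
        converged=bool(res.success),
    )
    if mw_kda is not None:
        fit.params_nm = {"kd": mass_to_molar(kd, mw_kda), "ec50": mass_to_molar(kd, mw_kda)}
    return fit


def fit_4pl(dr: DoseResponse, mw_kda: float | None = None) -> AssayFit:
    """Four-parameter-logistic fit (top, bottom, IC50, hill).

    Hill slope is unconstrained in sign; top/bottom are bounded by the data
    range ± 20%.  Multi-start over an IC50 log-grid and a set of hill slopes.
    """
    if dr.n_distinct < 5:
        raise DataError("4PL fit needs >= 5 distinct concentrations")
    x, y = dr.concentration, dr.response
    yrange = float(np.ptp(y))
    if yrange < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return AssayFit(model="4pl", converged=False, flags=["flat-response"])

    lo = float(y.min() - 0.2 * yrange)
    hi = float(y.max() + 0.2 * yrange)
    bounds = (
        [lo, lo, np.log(x.min() / 1e3), -10.0],
        [hi, hi, np.log(x.max() * 1e3), 10.0],
    )

    def resid(p):
        return four_pl(x, p[0], p[1], np.exp(p[2]), p[3]) - y

    best = None
    for ic50 in np.geomspace(x.min(), x.max(), 13):
        for hill in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
            p0 = [float(y.max()), float(y.min()), np.log(ic50), hill]
            res = least_squares(resid, p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
    res = best
    top, bottom, ic50, hill = res.x[0], res.x[1], float(np.exp(res.x[2])), res.x[3]
    se = _se_from_jac(res, x.size)
    fit = AssayFit(
        model="4pl",
        params={
            "top": float(top),
            "bottom": float(bottom),
            "ic50": ic50,
            "hill": float(hill),
        },
        se={
            "top": float(se[0]),
            "bottom": float(se[1]),
            "ic50": float(ic50 * se[2]),
            "hill": float(se[3]),
        },
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )
    if mw_kda is not None:
        fit.params_nm = {"ic50": mass_to_molar(ic50, mw_kda)}
    return fit


def fit_spr(
    sensorgrams: list[Sensorgram],
    kd_lower: float = 1e-6,
    mw_kda: float | None = None,
) -> AssayFit:
    """Global 1:1 kinetic fit across concentrations: ka, kd, Rmax; KD = kd/ka.

    A kd estimate pinned at the optimizer's lower bound is flagged as
    dissociation below the detection limit (the estimate is reported but
    should be read as an upper bound on kd).
    """
    if len(sensorgrams) < 2:
        raise DataError("SPR fit needs >= 2 analyte concentrations")
    times = [sg.time for sg in sensorgrams]
    resps = [sg.response for sg in sensorgrams]
    concs = [sg.concentration for sg in sensorgrams]
    tas = [sg.t_assoc for sg in sensorgrams]
    y_all = np.concatenate(resps)
    rmax0 = float(np.max(np.abs(y_all))) or 1.0

    def resid(p):
        ka, kd, rmax = 10.0 ** p[0], 10.0 ** p[1], p[2]
        parts = [
            sensorgram_response(t, c, ka, kd, rmax, ta) - r
            for t, r, c, ta in zip(times, resps, concs, tas)
        ]
        return np.concatenate(parts)

    bounds = ([0.0, np.log10(kd_lower), 1e-6], [9.0, 1.0, 10.0 * rmax0])
    best = None
    for lka in (4.0, 5.0, 6.0):
        for lkd in (-4.0, -3.0, -2.0):
            res = least_squares(
                resid, [lka, lkd, rmax0], bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            if best is None or res.cost < best.cost:
                best = res
    res = best
    ka, kd, rmax = 10.0 ** res.x[0], 10.0 ** res.x[1], float(res.x[2])
    se = _se_from_jac(res, y_all.size)
    flags = []
    if res.x[1] <= np.log10(kd_lower) + 0.01:
        flags.append("dissociation below detection")
    kd_m = kd / ka
    fit = AssayFit(
        model="spr_1to1",
        params={"ka": float(ka), "kd": float(kd), "rmax": rmax, "KD": float(kd_m)},
        se={
            "ka": float(ka * np.log(10.0) * se[0]),
            "kd": float(kd * np.log(10.0) * se[1]),
            "rmax": float(se[2]),
        },
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
        flags=flags,
    )
    fit.params_nm = {"KD": float(kd_m * 1e9)}
    return fit
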