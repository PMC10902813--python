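"""Sulfur-to-compound conversion, injected-volume determination,
calibration figures of merit, and recovery.

A peak area from the mass-flow electropherogram is an absolute sulfur
mass in ng.  Dividing by the injected volume gives the sulfur mass
concentration; multiplying by the compound-to-sulfur molar mass ratio
``M_compound / (n_S * AW_S)`` gives the compound concentration.  The
conversion only needs the compound's molar mass and sulfur-atom count —
no compound-specific calibration standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import constants
from .errors import CalibrationError, DomainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundDef",
    "CalibrationResult",
    "QuantResult",
    "s_mass_fraction",
    "determine_injection_volume",
    "quantify_compound",
    "calibrate",
    "recovery",
]

# plausible hydrodynamic CE injection range used only for a log warning
_VINJ_PLAUSIBLE_L = (10e-9, 50e-9)


@dataclass(frozen=True)
class CompoundDef:
    """A sulfur-containing compound: molar mass and S-atom count.

    s_mass_fraction is derived as n_sulfur*AW_S/molar_mass.
    """

    name: str
    molar_mass: float  # g/mol
    n_sulfur: int
    atomic_weight_s: float = constants.ATOMIC_WEIGHT_S

    def __post_init__(self):
        if not self.molar_mass > 0:
            raise ValidationError(f"{self.name}: molar_mass must be > 0")
        if self.n_sulfur < 1:
            raise ValidationError(f"{self.name}: n_sulfur must be >= 1")
        f = self.s_mass_fraction
        if not (0.0 < f <= 1.0):  # 1.0 = elemental sulfur / sulfide ion
            raise ValidationError(
                f"{self.name}: sulfur mass fraction {f:.4g} outside (0, 1]")

    @property
    def s_mass_fraction(self) -> float:
        return self.n_sulfur * self.atomic_weight_s / self.molar_mass


def s_mass_fraction(c: CompoundDef, atomic_weight_s: float | None = None) -> float:
    """Mass fraction of sulfur in the compound (dimensionless)."""
    aw = c.atomic_weight_s if atomic_weight_s is None else atomic_weight_s
    return c.n_sulfur * aw / c.molar_mass


@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration with LOD/LOQ from the residual standard error.

    lod = 3*residual_se/slope and loq = 10*residual_se/slope, both in the
    concentration unit of the x axis (mg/L of sulfur), so loq/lod = 10/3
    by construction.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    residual_se: float
    lod: float
    loq: float
    n_points: int

    def lod_absolute_pg(self, v_inj_l: float) -> float:
        """LOD as an absolute sulfur mass (pg) for a given injected volume."""
        return self.lod * v_inj_l * 1e9  # mg/L * L = mg ... scaled below

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("calibration needs >= 3 points")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one compound from one integrated peak."""

    compound: str
    sulfur_mass: float   # ng
    sulfur_conc: float   # mg/L
    compound_conc: float  # g/L
    recovery: float | None = None  # %, when a prepared value is known


def determine_injection_volume(peak_area_ng: float, known_s_conc_mg_l: float) -> float:
    """Injected volume (L) from a standard of known sulfur concentration.

    V_inj = integrated sulfur mass / known concentration.  The result is
    logged if it leaves the plausible hydrodynamic-injection range.
    """
    if not peak_area_ng > 0:
        raise DomainError("peak area must be > 0")
    if not known_s_conc_mg_l > 0:
        raise DomainError("standard concentration must be > 0")
    v = peak_area_ng * 1e-6 / known_s_conc_mg_l  # ng->mg, then mg/(mg/L) = L
    if not (_VINJ_PLAUSIBLE_L[0] <= v <= _VINJ_PLAUSIBLE_L[1]):
        logger.warning("V_inj = %.3g nL outside the typical hydrodynamic range "
                       "(%.0f-%.0f nL)", v * 1e9,
                       _VINJ_PLAUSIBLE_L[0] * 1e9, _VINJ_PLAUSIBLE_L[1] * 1e9)
    return v


def quantify_compound(peak, c: CompoundDef, v_inj: float,
                      prepared_conc: float | None = None) -> QuantResult:
    """Convert an integrated sulfur peak to compound concentration.

    sulfur_conc [mg/L] = area [ng] / V_inj [L];
    compound_conc [g/L] = sulfur_conc * M_compound/(n_S*AW_S) / 1000.
    """
    if not v_inj > 0:
        raise DomainError("v_inj must be > 0")
    area_ng = peak.area if hasattr(peak, "area") else float(peak)
    s_conc_mg_l = area_ng * 1e-6 / v_inj
    comp_conc_g_l = s_conc_mg_l / c.s_mass_fraction / 1e3
    rec = None if prepared_conc is None else recovery(comp_conc_g_l, prepared_conc)
    return QuantResult(compound=c.name, sulfur_mass=area_ng,
                       sulfur_conc=s_conc_mg_l, compound_conc=comp_conc_g_l,
                       recovery=rec)


def calibrate(levels: Sequence[tuple[float, float]],
              weighted: bool = False) -> CalibrationResult:
    """Ordinary least-squares calibration y-on-x with LOD/LOQ.

    levels : (nominal sulfur concentration mg/L, response) pairs; the
             response may be an integrated area or a measured concentration.
    weighted : optional 1/x weighting (off by default).
    """
    pts = [(float(x), float(y)) for (x, y) in levels]
    if len(pts) < 3:
        raise CalibrationError("calibration needs >= 3 levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise CalibrationError("calibration levels have zero x-variance")

    if weighted:
        w = 1.0 / np.maximum(x, np.finfo(float).tiny)
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        intercept, slope = beta
        resid = y - (intercept + slope * x)
        dof = len(x) - 2
        residual_se = float(np.sqrt(np.sum(w * resid**2) / dof)) if dof else 0.0
        cov = np.linalg.inv(X.T @ W @ X) * residual_se**2
        slope_se, intercept_se = float(np.sqrt(cov[1, 1])), float(np.sqrt(cov[0, 0]))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        slope_se, intercept_se = float(res.stderr), float(res.intercept_stderr)
        resid = y - (intercept + slope * x)
        dof = len(x) - 2
        residual_se = float(np.sqrt(np.sum(resid**2) / dof))
        r2 = float(res.rvalue) ** 2

    if slope == 0:
        raise CalibrationError("calibration slope is zero; LOD undefined")
    lod = 3.0 * residual_se / abs(slope)
    loq = 10.0 * residual_se / abs(slope)
    return CalibrationResult(slope=slope, intercept=intercept, slope_se=slope_se,
                             intercept_se=intercept_se, r_squared=r2,
                             residual_se=residual_se, lod=lod, loq=loq,
                             n_points=len(pts))


def recovery(measured_conc: float, prepared_conc: float) -> float:
    """Recovery in percent: 100 * measured / prepared."""
    if not prepared_conc > 0:
        raise DomainError("prepared concentration must be > 0")
    return 100.0 * measured_conc / prepared_conc
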