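"""Isotope compositions, mass-bias correction and the online
isotope-dilution conversion from ratio traces to sulfur mass flow.

The measurement idea: a constant flow of ³⁴S-enriched spike sulfur is
merged with the CE effluent after the separation.  Wherever only spike
is present the ³²S/³⁴S intensity ratio sits at the spike's own isotope
ratio; wherever natural-abundance analyte sulfur elutes the ratio rises
toward the natural ratio.  Solving the two-source isotope mixing
equation point by point converts the (mass-bias corrected) ratio trace
into an absolute sulfur mass-flow electropherogram in ng/min, whose
peak areas are nanograms of sulfur — no species-specific calibration
needed.

Mass bias is corrected with Russell's exponential law,
``R_true = R_meas * (m32/m34)**beta``, with ``beta`` calibrated against
a certified ³²S/³⁴S ratio measured on a natural-abundance standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from . import constants
from .errors import (
    BlankEstimationError,
    ContractError,
    DegenerateTraceError,
    DomainError,
    RatioRangeError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .signal_io import IsotopeTrace, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "IsotopeComposition",
    "SpikeConfig",
    "MassBiasModel",
    "RatioTrace",
    "MassFlowTrace",
    "ratio_trace",
    "calibrate_mass_bias",
    "correct_ratio",
    "mass_flow_point",
    "mass_flow_trace",
    "standard_area_ratio",
    "forward_ratio",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeComposition:
    """Amount fractions of the four stable sulfur isotopes.

    ``atomic_weight`` is derived as ``sum(x_i * m_i)`` and must land in
    the physically possible window for sulfur.
    """

    x32: float
    x33: float = 0.0
    x34: float = 0.0
    x36: float = 0.0
    masses: dict = field(default_factory=lambda: dict(constants.ISOTOPE_MASSES))

    def __post_init__(self):
        fr = (self.x32, self.x33, self.x34, self.x36)
        if any(not (0.0 <= x <= 1.0) for x in fr):
            raise ValidationError(f"amount fractions must lie in [0, 1], got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"amount fractions must sum to 1, got {sum(fr)!r}")
        aw = self.atomic_weight
        if not (31.9 < aw < 36.0):
            raise ValidationError(f"derived atomic weight {aw} outside (31.9, 36.0)")

    @property
    def atomic_weight(self) -> float:
        """Mole-fraction-weighted atomic weight, g/mol."""
        return (self.x32 * self.masses[32] + self.x33 * self.masses[33]
                + self.x34 * self.masses[34] + self.x36 * self.masses[36])

    @property
    def r32_34(self) -> float:
        """³²S/³⁴S amount ratio of this composition."""
        if self.x34 == 0.0:
            raise DomainError("composition has no 34S; ratio undefined")
        return self.x32 / self.x34

    @classmethod
    def natural(cls) -> "IsotopeComposition":
        """Representative natural terrestrial sulfur (CIAAW defaults)."""
        return cls(x32=constants.NATURAL_X32, x33=constants.NATURAL_X33,
                   x34=constants.NATURAL_X34, x36=constants.NATURAL_X36)

    @classmethod
    def spike_default(cls) -> "IsotopeComposition":
        """The ³⁴S-enriched spike: 99.8 % ³⁴S, 0.2 % ³²S."""
        return cls(x32=constants.SPIKE_X32_DEFAULT, x34=constants.SPIKE_X34_DEFAULT)

    @classmethod
    def from_ratio(cls, r32_34: float, x33: float = constants.NATURAL_X33,
                   x36: float = constants.NATURAL_X36) -> "IsotopeComposition":
        """Composition with a prescribed ³²S/³⁴S ratio (e.g. a certified
        isotopic standard), keeping the minor isotopes at natural levels."""
        if r32_34 <= 0:
            raise DomainError("r32_34 must be > 0")
        rest = 1.0 - x33 - x36
        x34 = rest / (1.0 + r32_34)
        return cls(x32=rest - x34, x33=x33, x34=x34, x36=x36)


@dataclass(frozen=True)
class SpikeConfig:
    """Post-column spike delivery parameters.

    w_spike : mass fraction of the ³⁴S *isotope* in the sheath liquid, kg/kg
    f_spike : sheath-liquid mass flow, kg/min
    composition : isotopic composition of the spike sulfur
    """

    w_spike: float = constants.W_SPIKE_DEFAULT_KG_PER_KG
    f_spike: float = constants.F_SPIKE_DEFAULT_KG_PER_MIN
    composition: IsotopeComposition = field(default_factory=IsotopeComposition.spike_default)

    def __post_init__(self):
        if self.w_spike <= 0:
            raise ValidationError("w_spike must be > 0")
        if self.f_spike <= 0:
            raise ValidationError("f_spike must be > 0")
        if not self.composition.x34 > self.composition.x32:
            raise ValidationError("spike must be enriched in 34S (x34 > x32)")

    @property
    def sulfur_molar_flow(self) -> float:
        """Total spike-sulfur molar flow, mol/min.

        w_spike*f_spike is the ³⁴S mass flow; dividing by m34 gives the
        ³⁴S molar flow and by x34 the total spike sulfur molar flow.
        """
        m34 = self.composition.masses[34]
        return (self.w_spike * self.f_spike * 1e3) / (m34 * self.composition.x34)


@dataclass(frozen=True)
class MassBiasModel:
    """Russell-law mass-bias model calibrated on a certified standard.

    The corrected ratio is ``r * (m32/m34)**beta`` ("exponential" law) or
    ``r * k_linear`` when ``law='linear'`` (k_linear = r_reference / mean
    measured ratio).
    """

    r_reference: float = constants.R_REFERENCE_DEFAULT
    beta: float = 0.0
    m32: float = constants.M32
    m34: float = constants.M34
    n_repetitions: int = 0
    law: str = "exponential"
    k_linear: float = 1.0
    per_run_beta: tuple = ()

    def __post_init__(self):
        if self.r_reference <= 0:
            raise ValidationError("r_reference must be > 0")
        if not self.m32 < self.m34:
            raise ValidationError("m32 must be < m34")
        if not np.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        if self.law not in ("exponential", "linear"):
            raise ValidationError(f"unknown mass-bias law {self.law!r}")

    @property
    def correction_factor(self) -> float:
        """Multiplicative factor applied to a measured ratio."""
        return (self.m32 / self.m34) ** self.beta


@dataclass
class RatioTrace:
    """Per-point ³²S/³⁴S ratio with a mask for unusable points."""

    time: np.ndarray
    r: np.ndarray
    mask: np.ndarray  # True where the point is masked (unusable)
    corrected: bool = False
    run_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.time) == len(self.r) == len(self.mask)):
            raise ValidationError("ratio trace arrays must have equal length")
        valid = self.r[~self.mask]
        if valid.size and not (np.all(np.isfinite(valid)) and np.all(valid >= 0)):
            raise ValidationError("unmasked ratios must be finite and >= 0")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class MassFlowTrace:
    """Blank-corrected sulfur mass flow vs time, ng/min."""

    time: np.ndarray
    mf: np.ndarray
    mf_blank: float = 0.0
    source_run_id: str = ""
    n_masked: int = 0
    n_clipped: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.mf = np.asarray(self.mf, dtype=float)
        if len(self.time) != len(self.mf):
            raise ValidationError("mass-flow trace arrays must have equal length")
        if self.mf_blank < 0:
            raise ValidationError("mf_blank must be >= 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ratio_trace(trace: "IsotopeTrace", i34_floor: float = 0.0) -> RatioTrace:
    """Form the raw ³²S/³⁴S ratio trace.

    Points where the ³⁴S intensity is at or below ``i34_floor`` (or where
    the resulting ratio would be non-positive) are masked rather than set
    to infinity; the post-column spike normally guarantees i34 >> 0.
    """
    if i34_floor < 0:
        raise ValidationError("i34_floor must be >= 0")
    i32 = np.asarray(trace.i32, dtype=float)
    i34 = np.asarray(trace.i34, dtype=float)
    mask = i34 <= i34_floor
    r = np.full_like(i34, np.nan)
    np.divide(i32, i34, out=r, where=~mask)
    mask |= ~np.isfinite(r)  # zero i34 slipped past a zero floor etc.
    r[mask] = np.nan
    if mask.all():
        raise DegenerateTraceError("all points masked; no usable 34S signal")
    return RatioTrace(time=np.asarray(trace.time, dtype=float), r=r, mask=mask,
                      corrected=False, run_id=getattr(trace, "run_id", ""))


def calibrate_mass_bias(measured_ratios: Sequence[float],
                        r_reference: float = constants.R_REFERENCE_DEFAULT,
                        m32: float = constants.M32,
                        m34: float = constants.M34,
                        law: str = "exponential") -> MassBiasModel:
    """Calibrate the Russell exponent from measured standard ratios.

    Each repetition j gives ``beta_j = ln(r_reference/R_j)/ln(m32/m34)``;
    the model carries the mean exponent and the repetition count.
    """
    ratios = np.asarray(list(measured_ratios), dtype=float)
    if ratios.size < 1:
        raise DomainError("at least one measured ratio required")
    if not np.all(ratios > 0):
        raise DomainError("measured ratios must be > 0")
    if r_reference <= 0:
        raise DomainError("r_reference must be > 0")
    betas = np.log(r_reference / ratios) / np.log(m32 / m34)
    k_linear = float(np.mean(r_reference / ratios))
    return MassBiasModel(r_reference=r_reference, beta=float(betas.mean()),
                         m32=m32, m34=m34, n_repetitions=int(ratios.size),
                         law=law, k_linear=k_linear,
                         per_run_beta=tuple(betas.tolist()))


def correct_ratio(rt: RatioTrace, model: MassBiasModel) -> RatioTrace:
    """Apply the mass-bias correction to a raw ratio trace.

    Refuses already-corrected input so the correction cannot be applied
    twice.  Masking is preserved.
    """
    if rt.corrected:
        raise ContractError("ratio trace is already mass-bias corrected")
    factor = model.correction_factor if model.law == "exponential" else model.k_linear
    r = rt.r * factor
    return RatioTrace(time=rt.time, r=r, mask=rt.mask.copy(), corrected=True,
                      run_id=rt.run_id)


def _mass_flow_array(r: np.ndarray, spike: SpikeConfig,
                     sample: IsotopeComposition) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised isotope-dilution equation; returns (mf_ng_min, clipped).

    Ratios outside the open admissible interval (spike ratio, sample
    ratio) are clipped to zero mass flow; ``clipped`` flags them.
    """
    xs32, xs34 = spike.composition.x32, spike.composition.x34
    xa32, xa34 = sample.x32, sample.x34
    n_sp = spike.sulfur_molar_flow  # mol/min
    r = np.asarray(r, dtype=float)
    num = r * xs34 - xs32
    den = xa32 - r * xa34
    with np.errstate(divide="ignore", invalid="ignore"):
        mf = sample.atomic_weight * n_sp * num / den * 1e9  # g/min -> ng/min
    finite = np.isfinite(r)
    clipped = finite & ((num <= 0) | (den <= 0))
    mf = np.where(clipped, 0.0, mf)
    mf = np.where(finite, mf, np.nan)
    return mf, clipped


def mass_flow_point(r_corrected: float, spike: SpikeConfig,
                    sample: IsotopeComposition) -> float:
    """Isotope-dilution mixing equation for one corrected ratio -> ng/min.

    ``MF = AW_sample * n_sp * (r*x_sp34 - x_sp32) / (x_s32 - r*x_s34)``
    with ``n_sp`` the total spike-sulfur molar flow.  The ratio must lie
    strictly between the spike ratio (pure spike, MF -> 0) and the sample
    ratio (sample-dominated, MF -> inf).
    """
    r_lo = spike.composition.r32_34
    r_hi = sample.r32_34
    if not r_corrected > r_lo:
        raise RatioRangeError(
            f"ratio {r_corrected} <= spike ratio {r_lo:.6g}: signal below the "
            "spike baseline", bound="spike")
    if not r_corrected < r_hi:
        raise RatioRangeError(
            f"ratio {r_corrected} >= sample ratio {r_hi:.6g}: sample-dominated "
            "signal, denominator -> 0", bound="sample")
    mf, _ = _mass_flow_array(np.asarray([r_corrected]), spike, sample)
    return float(mf[0])


def mass_flow_trace(trace: "IsotopeTrace", model: MassBiasModel,
                    cfg: "RunConfig", i34_floor: float | None = None) -> MassFlowTrace:
    """Full point-wise conversion: intensities -> blank-corrected MF.

    Pipeline: ratio -> mass-bias correction -> isotope-dilution equation
    per point; the blank mass flow is the median MF over the configured
    blank regions and is subtracted globally.  Out-of-range ratios are
    clipped to MF=0 and counted (baseline noise legitimately dips below
    the spike ratio).
    """
    floor = cfg.i34_floor if i34_floor is None else i34_floor
    rt = correct_ratio(ratio_trace(trace, i34_floor=floor), model)
    mf_raw, clipped = _mass_flow_array(rt.r, cfg.spike, cfg.sample_composition)
    n_clipped = int(clipped.sum())
    if n_clipped:
        logger.info("mass_flow_trace: clipped %d out-of-range ratio points to MF=0",
                    n_clipped)

    t = rt.time
    in_blank = np.zeros(len(t), dtype=bool)
    for (t0, t1) in cfg.blank_regions:
        in_blank |= (t >= t0) & (t <= t1)
    in_blank &= ~rt.mask
    if not in_blank.any():
        raise BlankEstimationError("no trace points fall inside the blank regions")
    mf_blank = float(np.median(mf_raw[in_blank]))
    mf_blank = max(mf_blank, 0.0)
    mf = mf_raw - mf_blank
    return MassFlowTrace(time=t, mf=mf, mf_blank=mf_blank,
                         source_run_id=rt.run_id, n_masked=rt.n_masked,
                         n_clipped=n_clipped)


def standard_area_ratio(trace: "IsotopeTrace", t_start: float | None = None,
                        t_end: float | None = None) -> float:
    """³²S/³⁴S ratio of a standard by the peak-area integration method.

    Integrates both intensity channels over the (optional) window and
    takes the ratio of the areas — the estimator used to determine the
    mass-bias factor from an unspiked natural-abundance standard.
    """
    t = np.asarray(trace.time, dtype=float)
    sel = np.ones(len(t), dtype=bool)
    if t_start is not None:
        sel &= t >= t_start
    if t_end is not None:
        sel &= t <= t_end
    if sel.sum() < 3:
        raise DomainError("area-ratio window contains fewer than 3 points")
    a32 = np.trapezoid(np.asarray(trace.i32, float)[sel], t[sel])
    a34 = np.trapezoid(np.asarray(trace.i34, float)[sel], t[sel])
    if a34 <= 0:
        raise DomainError("34S peak area is non-positive")
    return float(a32 / a34)


def forward_ratio(mf_sample_ng_min: float, spike: SpikeConfig,
                  sample: IsotopeComposition) -> float:
    """Forward mixing model: the ³²S/³⁴S ratio of spike + sample sulfur.

    Bookkeeping of isotope molar flows when a sample sulfur mass flow
    (ng/min, natural composition) merges with the constant spike.  This
    is the exact inverse of :func:`mass_flow_point` and is exposed mainly
    for simulation and self-checks.
    """
    if mf_sample_ng_min < 0:
        raise DomainError("sample mass flow must be >= 0")
    n_sample = mf_sample_ng_min * 1e-9 / sample.atomic_weight  # mol/min
    n_sp = spike.sulfur_molar_flow
    n32 = n_sample * sample.x32 + n_sp * spike.composition.x32
    n34 = n_sample * sample.x34 + n_sp * spike.composition.x34
    return n32 / n34
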