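"""Synthetic dual-isotope CE/ICP-MS traces with known ground truth.

The generator runs the measurement model forward: analyte sulfur elutes
as Gaussian (optionally exponentially-modified-Gaussian) peaks of known
sulfur mass on top of the constant ³⁴S-enriched spike flow delivered by
the sheath liquid.  Isotope molar flows follow from the two isotopic
compositions; ideal intensities are proportional to molar flow with a
single detector sensitivity shared by both isotopes, so the unbiased
intensity ratio equals the amount ratio.  Instrumental mass bias is
applied as the inverse of Russell's law with a configurable true
exponent, and Poisson counting noise acts on counts per dwell interval.
Everything downstream can therefore be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import constants
from .errors import ValidationError
from .isotope_core import IsotopeComposition, SpikeConfig
from .signal_io import IsotopeTrace

__all__ = [
    "SimPeak",
    "SimSpec",
    "SimTruth",
    "simulate_run",
    "simulate_standard",
    "simulate_calibration",
    "simulate_serum_profile",
]

# study-condition defaults: 10 Hz trace, 2 ms dwell per isotope, a
# detector sensitivity giving ~1e6 cps on the spike-dominated 34S channel
SAMPLING_RATE_DEFAULT_HZ = 10.0
SENSITIVITY_DEFAULT = 2.0e5  # cps per ng/min of 32S mass flow


@dataclass(frozen=True)
class SimPeak:
    """One analyte peak: sulfur mass (ng), migration time and width (s).

    tau > 0 switches the shape from Gaussian to an exponentially
    modified Gaussian with tail constant tau (s).
    """

    name: str
    mass_ng: float
    t_mig: float
    sigma: float = 3.0
    tau: float = 0.0

    def __post_init__(self):
        if self.mass_ng < 0:
            raise ValidationError(f"{self.name}: mass must be >= 0")
        if not self.sigma > 0:
            raise ValidationError(f"{self.name}: sigma must be > 0")
        if self.tau < 0:
            raise ValidationError(f"{self.name}: tau must be >= 0")

    @classmethod
    def from_concentration(cls, name: str, s_conc_mg_l: float, v_inj_l: float,
                           t_mig: float, sigma: float = 3.0,
                           tau: float = 0.0) -> "SimPeak":
        """Peak mass from a sulfur concentration and injected volume."""
        return cls(name=name, mass_ng=s_conc_mg_l * v_inj_l * 1e6,
                   t_mig=t_mig, sigma=sigma, tau=tau)

    def profile_ng_min(self, t_s: np.ndarray) -> np.ndarray:
        """Mass-flow profile (ng/min) integrating to mass_ng over time."""
        if self.mass_ng == 0:
            return np.zeros_like(t_s)
        if self.tau > 0:
            pdf = stats.exponnorm.pdf(t_s, K=self.tau / self.sigma,
                                      loc=self.t_mig, scale=self.sigma)
        else:
            pdf = stats.norm.pdf(t_s, loc=self.t_mig, scale=self.sigma)
        return self.mass_ng * 60.0 * pdf  # pdf is per second


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic run."""

    duration: float = 120.0           # s
    sampling_rate: float = SAMPLING_RATE_DEFAULT_HZ  # Hz
    peaks: tuple = ()
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    sample_composition: IsotopeComposition = field(
        default_factory=IsotopeComposition.natural)
    true_beta: float = 0.0
    sensitivity: float = SENSITIVITY_DEFAULT
    blank_mf: float = 0.0             # constant extra natural-S flow, ng/min
    noise: str = "none"               # 'none' | 'poisson'
    dwell: float = constants.DWELL_DEFAULT_S  # s
    seed: int = 0
    run_id: str = "sim"

    def __post_init__(self):
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if not self.sensitivity > 0:
            raise ValidationError("sensitivity must be > 0")
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.blank_mf < 0:
            raise ValidationError("blank_mf must be >= 0")
        for p in self.peaks:
            if not (0.0 <= p.t_mig <= self.duration):
                raise ValidationError(
                    f"peak {p.name!r} migrates outside the run duration")


@dataclass
class SimTruth:
    """Ground truth accompanying a synthetic trace."""

    peak_masses: dict            # name -> ng of sulfur
    peak_windows: dict           # name -> (t_start, t_end) suggestion, s
    mf_profile: np.ndarray       # analyte+blank sulfur mass flow, ng/min
    time: np.ndarray
    blank_mf: float
    true_beta: float
    v_inj: float | None = None
    concentrations: dict = field(default_factory=dict)  # name -> S mg/L


def _ideal_intensities(spec: SimSpec, mf_sample: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free, bias-free intensities from the forward mixing model."""
    sample = spec.sample_composition
    n_sample = mf_sample * 1e-9 / sample.atomic_weight        # mol/min
    n_sp = spec.spike.sulfur_molar_flow
    n32 = n_sample * sample.x32 + n_sp * spec.spike.composition.x32
    n34 = n_sample * sample.x34 + n_sp * spec.spike.composition.x34
    # sensitivity is quoted per ng/min of 32S mass flow; sharing the
    # per-molar-flow constant across isotopes makes i32/i34 the amount ratio
    s_molar = spec.sensitivity * constants.M32 * 1e9          # cps per mol/min
    return s_molar * n32, s_molar * n34


def simulate_run(spec: SimSpec) -> tuple[IsotopeTrace, SimTruth]:
    """Generate one synthetic trace and its ground truth."""
    n = int(round(spec.duration * spec.sampling_rate)) + 1
    t = np.arange(n) / spec.sampling_rate
    mf_sample = np.full(n, float(spec.blank_mf))
    for p in spec.peaks:
        mf_sample = mf_sample + p.profile_ng_min(t)

    i32, i34 = _ideal_intensities(spec, mf_sample)
    # instrumental mass bias: measured ratio = true * (m32/m34)^(-beta),
    # i.e. the exact inverse of the Russell-law correction
    i32 = i32 * (constants.M32 / constants.M34) ** (-spec.true_beta)

    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        i32 = rng.poisson(i32 * spec.dwell) / spec.dwell
        i34 = rng.poisson(i34 * spec.dwell) / spec.dwell

    trace = IsotopeTrace(time=t, i32=i32, i34=i34, dwell=spec.dwell,
                         run_id=spec.run_id)
    windows = {}
    for p in spec.peaks:
        lo = p.t_mig - 4.0 * p.sigma
        hi = p.t_mig + 4.0 * p.sigma + 5.0 * p.tau
        windows[p.name] = (max(lo, 0.0), min(hi, spec.duration))
    truth = SimTruth(peak_masses={p.name: p.mass_ng for p in spec.peaks},
                     peak_windows=windows, mf_profile=mf_sample, time=t,
                     blank_mf=spec.blank_mf, true_beta=spec.true_beta)
    return trace, truth


def simulate_standard(spec: SimSpec | None = None, mass_ng: float = 2.16,
                      t_mig: float = 60.0, **overrides) -> tuple[IsotopeTrace, SimTruth]:
    """Single-peak natural-abundance standard run (mass-bias/calibration use)."""
    base = spec or SimSpec(**overrides)
    peak = SimPeak(name="standard", mass_ng=mass_ng, t_mig=t_mig)
    return simulate_run(replace(base, peaks=(peak,)))


def simulate_calibration(levels: Sequence[float], base: SimSpec | None = None,
                         v_inj: float = 21.6e-9, t_mig: float = 60.0
                         ) -> list[tuple[IsotopeTrace, SimTruth]]:
    """One run per calibration level (sulfur mg/L); peak mass = level*V_inj.

    Seeds are drawn from one stream derived from the base seed so the
    level runs are independent but jointly reproducible.
    """
    base = base or SimSpec()
    out = []
    seeds = np.random.SeedSequence(base.seed).generate_state(max(len(levels), 1))
    for lvl, sd in zip(levels, seeds):
        peak = SimPeak.from_concentration("standard", float(lvl), v_inj, t_mig)
        spec = replace(base, peaks=(peak,), seed=int(sd % (2**31 - 1)),
                       run_id=f"cal_{lvl:g}")
        trace, truth = simulate_run(spec)
        truth.v_inj = v_inj
        truth.concentrations = {"standard": float(lvl)}
        out.append((trace, truth))
    return out


# serum-like preset: an early cluster of partially overlapping protein
# peaks plus a late, baseline-resolved albumin peak
_SERUM_PROTEINS = (
    ("globulin_1", 2.0, 70.0, 4.0),
    ("globulin_2", 1.4, 82.0, 4.5),
    ("globulin_3", 1.0, 92.0, 4.0),
    ("transferrin", 0.6, 103.0, 4.0),
)
_ALBUMIN_T_MIG = 200.0


def simulate_serum_profile(albumin_g_l: float = 28.1,
                           v_inj: float = 21.6e-9,
                           albumin_s_fraction: float = 0.0185,
                           base: SimSpec | None = None
                           ) -> tuple[IsotopeTrace, SimTruth]:
    """Serum-like preset: protein cluster plus resolved albumin peak.

    The albumin sulfur mass follows from the requested albumin mass
    concentration, its sulfur mass fraction and the injected volume;
    setting ``albumin_g_l=0`` emulates an albumin-depleted serum.
    """
    base = base or SimSpec(duration=300.0)
    s_conc = albumin_g_l * 1e3 * albumin_s_fraction            # mg/L of S
    peaks = [SimPeak(name=n, mass_ng=m, t_mig=tm, sigma=sg, tau=2.0)
             for (n, m, tm, sg) in _SERUM_PROTEINS]
    peaks.append(SimPeak.from_concentration("albumin", s_conc, v_inj,
                                            _ALBUMIN_T_MIG, sigma=5.0, tau=3.0))
    spec = replace(base, peaks=tuple(peaks), run_id="serum")
    trace, truth = simulate_run(spec)
    truth.v_inj = v_inj
    truth.concentrations = {"albumin": s_conc}
    return trace, truth
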