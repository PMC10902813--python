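"""Data model and file I/O for dual-isotope transient traces and run
configuration.

Canonical trace file: a TSV with header ``time_s\ti32_cps\ti34_cps``.
Instrument exports in other shapes (different column names, minute time
base, counts instead of counts/s) are absorbed by a :class:`TraceDialect`
column mapping.  The run configuration is a single YAML file whose keys
carry explicit units (e.g. ``w_spike_mg_per_kg``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants
from .errors import FormatError, ValidationError
from .isotope_core import IsotopeComposition, MassBiasModel, SpikeConfig
from .quant import CompoundDef

__all__ = [
    "IsotopeTrace",
    "TraceDialect",
    "RunConfig",
    "read_trace",
    "write_trace",
    "load_config",
]

CANONICAL_COLUMNS = ("time_s", "i32_cps", "i34_cps")


@dataclass
class IsotopeTrace:
    """Paired ³²S/³⁴S intensity time series from one CE run.

    time  : seconds since injection, strictly increasing
    i32   : ³²S intensity, counts/s
    i34   : ³⁴S intensity, counts/s
    dwell : detector integration time per point and isotope, s
    """

    time: np.ndarray
    i32: np.ndarray
    i34: np.ndarray
    dwell: float = constants.DWELL_DEFAULT_S
    run_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.i32 = np.asarray(self.i32, dtype=float)
        self.i34 = np.asarray(self.i34, dtype=float)
        n = len(self.time)
        if not (len(self.i32) == len(self.i34) == n):
            raise ValidationError("time, i32 and i34 must have equal length")
        if n < 2:
            raise ValidationError("a trace needs at least 2 points")
        dt = np.diff(self.time)
        if not np.all(dt > 0):
            idx = int(np.argmax(~(dt > 0)))
            raise ValidationError(
                f"time must be strictly increasing; first violation at index {idx + 1}")
        if np.any(self.i32 < 0) or np.any(self.i34 < 0):
            raise ValidationError("intensities must be >= 0")
        if not self.dwell > 0:
            raise ValidationError("dwell must be > 0")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class TraceDialect:
    """Column mapping for an instrument export.

    time_unit declares the unit of the time column ('s' or 'min');
    intensity_unit declares 'cps' (counts/s) or 'counts' (counts per
    dwell, divided by the dwell time on read).
    """

    time_col: str = "time_s"
    i32_col: str = "i32_cps"
    i34_col: str = "i34_cps"
    time_unit: str = "s"
    intensity_unit: str = "cps"
    sep: str = "\t"

    def __post_init__(self):
        if self.time_unit not in ("s", "min"):
            raise ValidationError(f"unknown time unit {self.time_unit!r}")
        if self.intensity_unit not in ("cps", "counts"):
            raise ValidationError(f"unknown intensity unit {self.intensity_unit!r}")


def read_trace(path, dialect: TraceDialect | None = None,
               dwell: float = constants.DWELL_DEFAULT_S,
               run_id: str | None = None) -> IsotopeTrace:
    """Read a dual-isotope trace from a delimited text export.

    Leading non-numeric lines (banners, comments) before the header are
    skipped; the decimal separator is always the point, regardless of
    locale.  Time is converted to seconds and intensities to counts/s as
    declared by the dialect.
    """
    dialect = dialect or TraceDialect()
    path = Path(path)
    text = path.read_text()

    # drop leading banner lines until the header row is found
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        cells = [c.strip() for c in line.split(dialect.sep)]
        if dialect.time_col in cells and dialect.i32_col in cells and dialect.i34_col in cells:
            header_idx = i
            break
    if header_idx is None:
        # no header at all: check whether required columns were ever named
        raise FormatError(
            f"column(s) {dialect.time_col!r}, {dialect.i32_col!r}, "
            f"{dialect.i34_col!r} not found in {path}")

    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])), sep=dialect.sep,
                     float_precision="round_trip")
    for col in (dialect.time_col, dialect.i32_col, dialect.i34_col):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    t = pd.to_numeric(df[dialect.time_col], errors="coerce").to_numpy(float)
    i32 = pd.to_numeric(df[dialect.i32_col], errors="coerce").to_numpy(float)
    i34 = pd.to_numeric(df[dialect.i34_col], errors="coerce").to_numpy(float)
    keep = ~(np.isnan(t) | np.isnan(i32) | np.isnan(i34))
    t, i32, i34 = t[keep], i32[keep], i34[keep]

    if dialect.time_unit == "min":
        t = t * 60.0
    if dialect.intensity_unit == "counts":
        i32 = i32 / dwell
        i34 = i34 / dwell
    return IsotopeTrace(time=t, i32=i32, i34=i34, dwell=dwell,
                        run_id=run_id if run_id is not None else path.stem)


def write_trace(trace: IsotopeTrace, path) -> None:
    """Write a trace as canonical TSV (full float precision)."""
    df = pd.DataFrame({CANONICAL_COLUMNS[0]: trace.time,
                       CANONICAL_COLUMNS[1]: trace.i32,
                       CANONICAL_COLUMNS[2]: trace.i34})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a quantification run needs besides the trace itself."""

    spike: SpikeConfig = field(default_factory=SpikeConfig)
    sample_composition: IsotopeComposition = field(default_factory=IsotopeComposition.natural)
    mass_bias: MassBiasModel = field(default_factory=MassBiasModel)
    compounds: list = field(default_factory=list)
    injection_volume: float | None = None  # L
    blank_regions: list = field(default_factory=list)  # [(t0, t1), ...] in s
    peak_windows: list = field(default_factory=list)   # [(label, t0, t1), ...]
    i34_floor: float = 0.0  # cps; 0 = no masking

    def __post_init__(self):
        if self.injection_volume is not None and not self.injection_volume > 0:
            raise ValidationError("injection_volume must be > 0")
        _check_disjoint([(t0, t1) for (t0, t1) in self.blank_regions], "blank_regions")
        _check_disjoint([(t0, t1) for (_, t0, t1) in self.peak_windows], "peak_windows")

    def compound(self, name: str) -> CompoundDef:
        for c in self.compounds:
            if c.name == name:
                return c
        raise ValidationError(f"compound {name!r} not in config")


def _check_disjoint(intervals: Sequence[tuple[float, float]], what: str) -> None:
    for (t0, t1) in intervals:
        if not t0 < t1:
            raise ValidationError(f"{what}: interval ({t0}, {t1}) has t_start >= t_end")
    ordered = sorted(intervals)
    for (a, b) in zip(ordered, ordered[1:]):
        if b[0] < a[1]:
            raise ValidationError(f"{what}: intervals {a} and {b} overlap")


_SPIKE_KEYS = {"w_spike_mg_per_kg", "f_spike_mg_per_min", "x32", "x34"}
_COMP_KEYS = {"x32", "x33", "x34", "x36"}
_MB_KEYS = {"r_reference", "beta", "law", "n_repetitions"}
_TOP_KEYS = {"spike", "sample_composition", "mass_bias", "compounds",
             "injection_volume_nl", "blank_regions", "peak_windows",
             "i34_floor_cps"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying documented defaults.

    Missing blocks fall back to the reference operating conditions:
    0.5 mg/kg ³⁴S spike at 10 mg/min sheath flow, 99.8/0.2 % spike
    composition, CIAAW natural sample abundances.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")

    sp = raw.get("spike", {}) or {}
    _reject_unknown(sp, _SPIKE_KEYS, "spike")
    spike_comp = IsotopeComposition(
        x32=float(sp.get("x32", constants.SPIKE_X32_DEFAULT)),
        x34=float(sp.get("x34", constants.SPIKE_X34_DEFAULT)))
    spike = SpikeConfig(
        w_spike=float(sp.get("w_spike_mg_per_kg", 0.5)) * 1e-6,
        f_spike=float(sp.get("f_spike_mg_per_min", 10.0)) * 1e-6,
        composition=spike_comp)

    sc = raw.get("sample_composition", {}) or {}
    _reject_unknown(sc, _COMP_KEYS, "sample_composition")
    if sc:
        sample = IsotopeComposition(
            x32=float(sc.get("x32", 0.0)), x33=float(sc.get("x33", 0.0)),
            x34=float(sc.get("x34", 0.0)), x36=float(sc.get("x36", 0.0)))
    else:
        sample = IsotopeComposition.natural()

    mb = raw.get("mass_bias", {}) or {}
    _reject_unknown(mb, _MB_KEYS, "mass_bias")
    mass_bias = MassBiasModel(
        r_reference=float(mb.get("r_reference", constants.R_REFERENCE_DEFAULT)),
        beta=float(mb.get("beta", 0.0)),
        law=str(mb.get("law", "exponential")),
        n_repetitions=int(mb.get("n_repetitions", 0)))

    compounds = []
    for entry in raw.get("compounds", []) or []:
        _reject_unknown(entry, {"name", "molar_mass_g_mol", "n_sulfur"}, "compounds")
        compounds.append(CompoundDef(name=str(entry["name"]),
                                     molar_mass=float(entry["molar_mass_g_mol"]),
                                     n_sulfur=int(entry["n_sulfur"])))

    v_nl = raw.get("injection_volume_nl")
    blank = [(float(a), float(b)) for (a, b) in raw.get("blank_regions", []) or []]
    windows = []
    for w in raw.get("peak_windows", []) or []:
        _reject_unknown(w, {"label", "t_start_s", "t_end_s"}, "peak_windows")
        windows.append((str(w["label"]), float(w["t_start_s"]), float(w["t_end_s"])))

    return RunConfig(spike=spike, sample_composition=sample, mass_bias=mass_bias,
                     compounds=compounds,
                     injection_volume=None if v_nl is None else float(v_nl) * 1e-9,
                     blank_regions=blank, peak_windows=windows,
                     i34_floor=float(raw.get("i34_floor_cps", 0.0)))
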