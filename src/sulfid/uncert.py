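"""First-order (GUM-style) uncertainty propagation, replicate
combination, and a ranked uncertainty budget.

The measurement model — the isotope-dilution equation composed with the
sulfur-to-compound conversion — is treated as a black-box function of
its uncertain inputs.  Sensitivities are central differences, the
combined standard uncertainty of a single run is the usual
root-sum-of-squares, and replicate runs are combined with the
between-replicate scatter as ``u_c = sqrt(mean(u_i)^2 + s^2/n)``.
Input correlations are taken as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .errors import InsufficientDataError, PropagationError, ValidationError
from .isotope_core import IsotopeComposition, SpikeConfig, mass_flow_point
from .quant import CompoundDef

__all__ = [
    "UncertainInput",
    "UncertaintyBudget",
    "propagate",
    "combine_replicates",
    "budget_report",
    "concentration_model",
]


@dataclass(frozen=True)
class UncertainInput:
    """One uncertain model input.

    type 'A' marks statistically determined uncertainties (repeatability),
    'B' certificate/judgment-based ones.
    """

    name: str
    value: float
    standard_uncertainty: float
    type: str = "B"

    def __post_init__(self):
        if self.standard_uncertainty < 0:
            raise ValidationError(f"{self.name}: standard uncertainty must be >= 0")
        if self.type not in ("A", "B"):
            raise ValidationError(f"{self.name}: type must be 'A' or 'B'")


@dataclass
class UncertaintyBudget:
    """Combined uncertainty of a replicated measurement with its budget."""

    value: float
    u_single: float
    contributions: dict = field(default_factory=dict)  # name -> share in %
    sensitivities: dict = field(default_factory=dict)  # name -> df/dx
    input_types: dict = field(default_factory=dict)    # name -> 'A'|'B'
    s: float = 0.0
    n: int = 1
    u_c: float = 0.0
    k: float = 2.0
    U: float = 0.0


def propagate(model: Callable[[Mapping[str, float]], float],
              inputs: Sequence[UncertainInput],
              rel_step: float = 1e-6) -> tuple[float, float, dict]:
    """First-order GUM propagation through a black-box model.

    Sensitivities c_i = df/dx_i via central differences with step
    max(rel_step*|x_i|, 1e-12); u_single = sqrt(sum (c_i u_i)^2);
    contribution_i = (c_i u_i)^2 / u_single^2 in percent.

    Returns (value, u_single, contributions); use :func:`propagate_full`
    when the raw sensitivities are needed as well.
    """
    value, u, contrib, _ = propagate_full(model, inputs, rel_step)
    return value, u, contrib


def propagate_full(model: Callable[[Mapping[str, float]], float],
                   inputs: Sequence[UncertainInput],
                   rel_step: float = 1e-6
                   ) -> tuple[float, float, dict, dict]:
    names = [i.name for i in inputs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate input names")
    x0 = {i.name: i.value for i in inputs}
    try:
        value = float(model(x0))
    except Exception as exc:  # noqa: BLE001 — black-box model
        raise PropagationError(f"model failed at nominal point: {exc}") from exc

    sens: dict[str, float] = {}
    var_terms: dict[str, float] = {}
    for inp in inputs:
        h = max(rel_step * abs(inp.value), 1e-12)
        xp = dict(x0)
        xm = dict(x0)
        xp[inp.name] = inp.value + h
        xm[inp.name] = inp.value - h
        try:
            fp, fm = float(model(xp)), float(model(xm))
        except Exception as exc:  # noqa: BLE001
            raise PropagationError(
                f"model failed when perturbing {inp.name!r}: {exc}",
                input_name=inp.name) from exc
        c = (fp - fm) / (2.0 * h)
        sens[inp.name] = c
        var_terms[inp.name] = (c * inp.standard_uncertainty) ** 2

    u2 = sum(var_terms.values())
    u_single = float(np.sqrt(u2))
    if u2 > 0:
        contributions = {k: 100.0 * v / u2 for k, v in var_terms.items()}
    else:
        contributions = {k: 0.0 for k in var_terms}
    return value, u_single, contributions, sens


def combine_replicates(u_singles: Sequence[float], measured: Sequence[float],
                       k: float = 2.0, mode: str = "rss") -> UncertaintyBudget:
    """Combine per-replicate GUM uncertainties with replicate scatter.

    s is the sample standard deviation of the measured values and
    ``u_c = sqrt(mean(u_i)^2 + s^2/n)`` (mode 'rss', default) or
    ``max(mean(u_i), s/sqrt(n))`` (mode 'max').  U = k*u_c.
    """
    u = np.asarray(list(u_singles), dtype=float)
    y = np.asarray(list(measured), dtype=float)
    if len(u) != len(y):
        raise ValidationError("u_singles and measured must have equal length")
    n = len(y)
    if n < 2:
        raise InsufficientDataError("replicate combination needs n >= 2")
    if np.any(u < 0):
        raise ValidationError("uncertainties must be >= 0")
    s = float(np.std(y, ddof=1))
    u_bar = float(np.mean(u))
    if mode == "rss":
        u_c = float(np.sqrt(u_bar**2 + s**2 / n))
    elif mode == "max":
        u_c = max(u_bar, s / np.sqrt(n))
    else:
        raise ValidationError(f"unknown combination mode {mode!r}")
    return UncertaintyBudget(value=float(np.mean(y)), u_single=u_bar, s=s, n=n,
                             u_c=u_c, k=k, U=k * u_c)


def build_budget(model: Callable[[Mapping[str, float]], float],
                 inputs: Sequence[UncertainInput],
                 replicates: Sequence[float] | None = None,
                 k: float = 2.0) -> UncertaintyBudget:
    """Propagate one model evaluation and optionally fold in replicates."""
    value, u_single, contrib, sens = propagate_full(model, inputs)
    if replicates is not None and len(replicates) >= 2:
        b = combine_replicates([u_single] * len(replicates), replicates, k=k)
        b.contributions = contrib
        b.sensitivities = sens
        b.input_types = {i.name: i.type for i in inputs}
        return b
    return UncertaintyBudget(value=value, u_single=u_single,
                             contributions=contrib, sensitivities=sens,
                             input_types={i.name: i.type for i in inputs},
                             s=0.0, n=1, u_c=u_single, k=k, U=k * u_single)


def budget_report(b: UncertaintyBudget) -> pd.DataFrame:
    """Ranked, machine-readable budget table (descending shares)."""
    rows = []
    for name, share in sorted(b.contributions.items(), key=lambda kv: -kv[1]):
        rows.append({"input": name, "share_percent": share,
                     "sensitivity": b.sensitivities.get(name, np.nan),
                     "type": b.input_types.get(name, "?")})
    return pd.DataFrame(rows, columns=["input", "share_percent", "sensitivity",
                                       "type"])


# ---------------------------------------------------------------------------
# the composed measurement model
# ---------------------------------------------------------------------------

def concentration_model(compound: CompoundDef,
                        sample: IsotopeComposition | None = None,
                        peak_duration_min: float = 0.5
                        ) -> Callable[[Mapping[str, float]], float]:
    """Build the composed measurement function ratio -> compound g/L.

    The uncertain inputs are the peak-average corrected ratio ``r``, the
    mass-bias exponent ``beta``, the spike parameters ``w_spike`` (kg/kg)
    and ``f_spike`` (kg/min), and the injected volume ``v_inj`` (L).  The
    peak is represented by its average mass flow sustained over a fixed
    effective duration, so the sulfur mass is MF * duration and the
    concentration follows from the stoichiometric conversion.  This is
    the single-measurement model the uncertainty budget is evaluated on.
    """
    sample = sample or IsotopeComposition.natural()

    def model(x: Mapping[str, float]) -> float:
        spike = SpikeConfig(w_spike=x["w_spike"], f_spike=x["f_spike"])
        r_corr = x["r"] * (constants.M32 / constants.M34) ** x["beta"]
        mf = mass_flow_point(r_corr, spike, sample)  # ng/min
        area_ng = mf * peak_duration_min
        s_conc_mg_l = area_ng * 1e-6 / x["v_inj"]
        return s_conc_mg_l / compound.s_mass_fraction / 1e3  # g/L

    return model
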