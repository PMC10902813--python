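"""Isotope masses and default abundances for sulfur.

Values follow the IUPAC Commission on Isotopic Abundances and Atomic
Weights (CIAAW).  Atomic masses are the 2021 AME-based CIAAW values in
g/mol; the default amount fractions are the CIAAW representative
abundances for terrestrial sulfur, which are appropriate for organic
sulfur of animal origin.  Both are overridable through the run
configuration — nothing downstream hard-codes them.
"""

from __future__ import annotations

CIAAW_VERSION = "2021"

# isotope masses, g/mol
M32 = 31.9720711744
M33 = 32.9714589098
M34 = 33.967867004
M36 = 35.96708071

ISOTOPE_MASSES = {32: M32, 33: M33, 34: M34, 36: M36}

# representative terrestrial amount fractions (dimensionless)
NATURAL_X32 = 0.9499
NATURAL_X33 = 0.0075
NATURAL_X34 = 0.0425
NATURAL_X36 = 0.0001

# conventional standard atomic weight of sulfur, g/mol (used for
# stoichiometric sulfur-to-compound conversion)
ATOMIC_WEIGHT_S = 32.06

# certified 32S/34S amount ratio of the mass-bias calibrant
# (sulfate isotopic reference solution, TIMS value)
R_REFERENCE_DEFAULT = 22.555

# spike defaults: 0.5 mg/kg 34S in the sheath liquid, delivered at
# 10 mg/min, spike sulfur 99.8 % 34S / 0.2 % 32S
W_SPIKE_DEFAULT_KG_PER_KG = 0.5e-6
F_SPIKE_DEFAULT_KG_PER_MIN = 10e-6
SPIKE_X34_DEFAULT = 0.998
SPIKE_X32_DEFAULT = 0.002

# detector integration time per isotope, s
DWELL_DEFAULT_S = 0.002
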