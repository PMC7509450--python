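"""Unit conventions and physical constants.

The whole package uses one consistent unit system:

==============  =========
quantity        unit
==============  =========
time            ms
voltage         mV
concentration   mM
current         pA
conductance     nS (densities in mS/cm**2)
capacitance     pF
length          micrometre
volume          micrometre**3
resistance      megaohm
==============  =========

Membrane-bound signalling species (receptor, G protein, PLC and the
phosphoinositides) are tracked as dimensionless surface densities normalised
so that the resting PIP2 density equals 1; the conversion of hydrolysed PIP2
into cytosolic IP3 concentration uses a per-compartment scale factor
proportional to the surface-to-volume ratio (see :mod:`ca1ach.cascade`).
"""

FARADAY = 96485.33212  # C / mol

#: multiply a calcium current in pA and divide by a volume in um^3 to obtain
#: a concentration derivative in mM/ms (divalent ion):
#: dCa[mM/ms] = -I[pA] * CA_CURRENT_TO_FLUX / vol[um^3]
CA_CURRENT_TO_FLUX = 1e3 / (2.0 * FARADAY)

#: 1 mS/cm^2 expressed in nS/um^2
MS_PER_CM2_TO_NS_PER_UM2 = 0.01

#: 1 uF/cm^2 expressed in pF/um^2
UF_PER_CM2_TO_PF_PER_UM2 = 0.01

_SUFFIXES = {
    "M": 1e3,
    "mM": 1.0,
    "uM": 1e-3,
    "nM": 1e-6,
    "pM": 1e-9,
}


def parse_concentration(text: str | float) -> float:
    """Parse a human-friendly concentration string into mM.

    Accepts a bare number (already mM) or a number with one of the suffixes
    M, mM, uM, nM, pM (e.g. ``"100uM"``, ``"14.3nM"``).
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    for suffix in sorted(_SUFFIXES, key=len, reverse=True):
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * _SUFFIXES[suffix]
    return float(s)
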