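"""Unit conventions and physical constants.

Internal units everywhere in the package: nm, ns, pA, mV, kT, degrees.
"""

from __future__ import annotations

import math

#: Elementary charge expressed as pA·ns (1.602176634e-19 C / 1e-9 s, in pA).
#: One net charge crossing per nanosecond equals this many picoamperes.
ELEMENTARY_CHARGE_PA_NS = 160.2176634

#: Molar concentration of pure water at ambient conditions (mol/L).
WATER_MOLARITY = 55.5

#: Ångström → nm conversion (structure readers report Å).
ANGSTROM_TO_NM = 0.1

#: ps → ns conversion (trajectory readers report ps).
PS_TO_NS = 1e-3


def round_sig(x: float, sig: int = 1) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def molar_salt_concentration(n_water: int, n_anion: int, sig: int | None = 1) -> float:
    """Molarity of added salt from solvent/anion counts.

    The added-salt concentration of a simulation box is estimated as the
    anion-to-water mole ratio scaled by the molarity of pure water.  Counting
    anions (rather than cations) excludes the counter-ions that neutralise
    the protein charge.

    Parameters
    ----------
    n_water : number of water molecules in the box.
    n_anion : number of added-salt anions (e.g. Cl-).
    sig : significant figures for the reported value; ``None`` disables
        rounding.
    """
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    if n_anion < 0:
        raise ValueError("n_anion must be non-negative")
    molarity = n_anion / n_water * WATER_MOLARITY
    if sig is None:
        return molarity
    return round_sig(molarity, sig)
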