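"""Carbon equivalents of sedimentary organic matter.

Protein, carbohydrate and lipid concentrations (mg/g dry sediment) are
converted to carbon equivalents with the standard factors 0.49, 0.40 and
0.75 mgC per mg, and summed into biopolymeric carbon (BPC), a proxy for
the trophic resources available to the benthos.  Chlorophyll-a and
phaeopigments (µg/g) sum to total phytopigments.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: carbon conversion factors, mgC per mg of compound
C_PRT = 0.49
C_CHO = 0.40
C_LIP = 0.75


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return arr


def total_phytopigments(chla, pheo):
    """Total phytopigments (µg/g) as the sum of chlorophyll-a and phaeopigments.

    Accepts scalars or arrays; negative inputs raise :class:`ValidationError`.
    """
    chla = _check_nonneg("chla", chla)
    pheo = _check_nonneg("pheo", pheo)
    out = chla + pheo
    return float(out) if out.ndim == 0 else out

def biopolymeric_carbon(prt, cho, lip):
    """Biopolymeric carbon (mgC/g) from protein, carbohydrate and lipid
    concentrations (mg/g), using the 0.49 / 0.40 / 0.75 mgC/mg factors.

    Linear in every argument, so the BPC of mean concentrations equals the
    mean of per-sample BPC values.
    """
    prt = _check_nonneg("prt", prt)
    cho = _check_nonneg("cho", cho)
    lip = _check_nonneg("lip", lip)
    out = C_PRT * prt + C_CHO * cho + C_LIP * lip
    return float(out) if out.ndim == 0 else out
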