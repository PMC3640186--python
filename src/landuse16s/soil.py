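"""Soil chemistry derivations: NH3 speciation and organic matter.

Ammonia is derived from measured NH4+-N and pH by Henderson-Hasselbalch
speciation of total ammoniacal nitrogen with pKa(NH4+/NH3) = 9.23:

    f(pH) = 10^(pH - pKa) / (1 + 10^(pH - pKa))
    NH3-N = NH4-N(measured, treated as total ammoniacal N) * f(pH)

Concentrations stay in mg N per kg soil throughout.  Soil organic matter
is 1.72 x percent organic carbon.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

PKA_NH4 = 9.23
SOM_FACTOR = 1.72


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-printing convention)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def ammonia_fraction(ph):
    """Fraction of total ammoniacal N present as NH3 at a given pH.

    Strictly increasing in pH; equals 0.5 at pH = pKa = 9.23.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    r = np.power(10.0, ph - PKA_NH4)
    f = r / (1.0 + r)
    return float(f) if f.ndim == 0 else f


def nh3_from_nh4(nh4_n, ph):
    """NH3-N (mg/kg) from measured NH4+-N (mg/kg) and pH.

    Returns ``(nh3, log10_nh3)``.  ``log10_nh3`` is NaN when nh4_n == 0.
    """
    nh4 = np.asarray(nh4_n, dtype=float)
    if np.any(nh4 < 0):
        raise ValueError("NH4+-N must be non-negative")
    nh3 = nh4 * ammonia_fraction(ph)
    with np.errstate(divide="ignore"):
        log_nh3 = np.where(nh3 > 0, np.log10(np.where(nh3 > 0, nh3, 1.0)), np.nan)
    if nh3.ndim == 0:
        return float(nh3), float(log_nh3)
    return nh3, log_nh3


def som_from_oc(oc_percent):
    """Percent soil organic matter from percent organic carbon (factor 1.72)."""
    oc = np.asarray(oc_percent, dtype=float)
    if np.any(oc < 0):
        raise ValueError("organic carbon must be non-negative")
    som = SOM_FACTOR * oc
    return float(som) if som.ndim == 0 else som


def annotate_soil_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived ``nh3`` and ``log_nh3`` columns to a soil table.

    Expects ``ph`` and ``nh4_n`` columns; returns a copy.
    """
    for col in ("ph", "nh4_n"):
        if col not in table.columns:
            raise ValueError(f"soil table missing column {col!r}")
    out = table.copy()
    nh3, log_nh3 = nh3_from_nh4(out["nh4_n"].to_numpy(), out["ph"].to_numpy())
    out["nh3"] = np.atleast_1d(nh3)
    out["log_nh3"] = np.atleast_1d(log_nh3)
    return out
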