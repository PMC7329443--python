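"""Vent-fluid endmember chemistry by zero-Mg extrapolation.

High-temperature hydrothermal endmember fluids contain essentially no
magnesium, while seawater carries ~53 mmol/kg, so the Mg concentration of
a fluid sample measures how much seawater was entrained during sampling.
For each chemical species, ordinary least squares of concentration
against Mg over replicate samples, extrapolated to Mg = 0, recovers the
endmember concentration.  pH is never extrapolated: the reported value is
the lowest measured in the samples.  Conservative mixing of endmember and
seawater predicts ``c(phi) = phi*c_sw + (1-phi)*c_em``; depletion of a
measured sample relative to that line indicates (a)biotic consumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "EndmemberEstimate", "extrapolate_endmember", "report_ph",
    "conservative_mixing", "depletion", "measured_composition",
    "SEAWATER_MG", "SEAWATER", "ACTIVE_VENT_ENDMEMBER", "ANALYTICAL_2S",
]

#: background seawater Mg, mmol/kg
SEAWATER_MG = 53.0

#: reference compositions of an active East Pacific Rise vent endmember and
#: background seawater.  Units: mmol/kg for K, Ca, Mg, Cl, SO4 and CO2;
#: mmol/L for H2S and H2; umol/L for CH4.
ACTIVE_VENT_ENDMEMBER = {
    "Mg": 0.0, "K": 18.9, "Ca": 19.7, "Cl": 528.0, "SO4": 0.0,
    "H2S": 6.3, "CO2": 11.5, "CH4": 83.0, "H2": 0.83,
}
SEAWATER = {
    "Mg": SEAWATER_MG, "K": 9.95, "Ca": 9.98, "Cl": 537.0, "SO4": 27.7,
    "H2S": 0.0, "CO2": 2.3, "CH4": 0.0, "H2": 0.0,
}

#: overall analytical uncertainty (2s) as a fraction of the measured value:
#: 10% for dissolved gases, 3% for major ions.
ANALYTICAL_2S = {
    "H2": 0.10, "CH4": 0.10, "H2S": 0.10,
    "Mg": 0.03, "K": 0.03, "Ca": 0.03, "Cl": 0.03, "SO4": 0.03,
    "CO2": 0.03,
}


@dataclass
class EndmemberEstimate:
    species: str
    endmember: float          # intercept at Mg = 0 (clipped at 0)
    slope: float
    intercept_se: float
    n: int
    extrapolated: bool
    clipped: bool = False


def extrapolate_endmember(samples: pd.DataFrame, species: list[str],
                          mg_col: str = "Mg") -> pd.DataFrame:
    """Zero-Mg OLS extrapolation per species over one vent's samples.

    Rows with a missing (NaN) value for a species — the below-detection
    convention — are excluded from that species' regression rather than
    substituted.  If every retained sample has Mg = 0 the regression
    degenerates to the mean; identical nonzero Mg values leave no
    leverage and raise.  Negative intercepts are clipped to 0 and
    flagged.  Returns one row per species.
    """
    if mg_col not in samples.columns:
        raise KeyError(f"missing {mg_col!r} column")
    rows = []
    for sp in species:
        if sp not in samples.columns:
            raise KeyError(f"missing species column {sp!r}")
        sub = samples[[mg_col, sp]].dropna()
        n = len(sub)
        if n < 2:
            raise ValueError(f"{sp}: need >= 2 samples with measurements")
        mg = sub[mg_col].to_numpy(dtype=float)
        c = sub[sp].to_numpy(dtype=float)
        if np.ptp(mg) == 0:
            if np.all(mg == 0):
                est = EndmemberEstimate(sp, float(np.mean(c)), 0.0,
                                        float(np.std(c, ddof=1) / np.sqrt(n)),
                                        n, extrapolated=False)
                rows.append(est)
                continue
            raise ValueError(f"{sp}: no Mg leverage (identical Mg values)")
        fit = stats.linregress(mg, c)
        intercept = float(fit.intercept)
        clipped = intercept < 0
        if clipped:
            log.warning("%s: negative intercept %.4g clipped to 0",
                        sp, intercept)
        rows.append(EndmemberEstimate(
            sp, max(intercept, 0.0), float(fit.slope),
            float(fit.intercept_stderr), n, extrapolated=True,
            clipped=clipped))
    return pd.DataFrame([vars(e) for e in rows])


def report_ph(samples: pd.DataFrame, ph_col: str = "pH") -> float:
    """Reported pH (25 C): the lowest measured value, never regressed."""
    if ph_col not in samples.columns:
        raise ValueError("no pH column in samples")
    vals = samples[ph_col].dropna()
    if vals.empty:
        raise ValueError("no pH measurements")
    return float(vals.min())


def conservative_mixing(endmember: dict[str, float],
                        seawater: dict[str, float],
                        phi: float) -> dict[str, float]:
    """Expected composition of a conservative endmember-seawater mixture.

    ``phi`` is the seawater fraction in [0, 1]; species missing from one
    composition are treated as 0 there.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0,1]")
    species = set(endmember) | set(seawater)
    return {sp: phi * seawater.get(sp, 0.0)
            + (1.0 - phi) * endmember.get(sp, 0.0)
            for sp in species}


def depletion(expected: float, measured: float) -> float:
    """Fractional depletion relative to conservative mixing:
    (expected - measured) / expected."""
    if expected == 0:
        raise ValueError("expected concentration is 0")
    return (expected - measured) / expected


def measured_composition(samples: pd.DataFrame, species: list[str],
                         seawater: dict[str, float] | None = None
                         ) -> pd.DataFrame:
    """Mean measured composition (no extrapolation), for vents whose
    fluids mixed with seawater below the seafloor.  With a seawater
    composition given, adds the enrichment factor measured/seawater."""
    rows = []
    for sp in species:
        vals = samples[sp].dropna()
        if vals.empty:
            raise ValueError(f"{sp}: no measurements")
        row = {"species": sp, "measured": float(vals.mean()), "n": len(vals)}
        if seawater is not None and seawater.get(sp, 0.0) > 0:
            row["vs_seawater"] = row["measured"] / seawater[sp]
        rows.append(row)
    return pd.DataFrame(rows)
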