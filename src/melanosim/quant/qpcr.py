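"""Quantitative real-time PCR transforms.

Absolute quantification converts a mass concentration of standard DNA to
a copy number:

    copies/ul = (X g/ul) / (plasmid length bp * 660 g/mol/bp) * N_A

Relative quantification maps a threshold cycle CT to a normalised
expression value through a dilution-series standard curve (ordinary
least-squares line of CT against log10 template amount, slope S,
intercept I):

    (1) LQ   = (CT - I) / S          log10 quantity
    (2) Q    = 10**LQ                quantity
    (3) GOIP = Q / MNT               normalised to the mean
                                     non-targeted quantity
    (4) GOIP / GP                    relative to the GAPDH reference

At 100% amplification efficiency the slope of CT against log10 template
is -1/log10(2) = -3.3219 (one cycle per doubling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "MASS_PER_BASEPAIR",
    "AVOGADRO",
    "StandardCurve",
    "copies_per_microliter",
    "fit_standard_curve",
    "ct_to_quantity",
    "ct_to_normalized_expression",
]

MASS_PER_BASEPAIR = 660.0          # g/mol per basepair of dsDNA
AVOGADRO = 6.022e23                # molecules per mol


def copies_per_microliter(mass_conc: float, plasmid_length: int) -> float:
    """Copy number of a standard DNA dilution.

    ``mass_conc`` in g/ul, ``plasmid_length`` in basepairs.  Zero mass
    returns 0 (flagged limit case); negative inputs are an error.
    """
    if mass_conc < 0 or plasmid_length <= 0:
        raise ValueError("mass must be >= 0 and plasmid length > 0")
    return mass_conc / (plasmid_length * MASS_PER_BASEPAIR) * AVOGADRO


@dataclass(frozen=True)
class StandardCurve:
    """OLS line CT = S*log10(template) + I for one assay."""

    slope: float
    intercept: float
    r_squared: float
    assay: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be non-zero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    log10_dilution, ct, assay: str = ""
) -> StandardCurve:
    """Fit the dilution-series line; returns slope, intercept and R^2."""
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("dilutions have zero variance")
    res = sps.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        assay=assay,
    )


def ct_to_quantity(ct: float, curve: StandardCurve) -> float:
    """Steps (1)-(2): CT -> quantity Q = 10**((CT - I)/S)."""
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return float("nan")
    lq = (ct - curve.intercept) / curve.slope
    return 10.0**lq


def ct_to_normalized_expression(
    ct: float,
    target_curve: StandardCurve,
    target_mnt: float,
    gapdh_gp: float,
) -> float:
    """Steps (1)-(4): CT -> expression relative to GAPDH.

    ``target_mnt`` is the mean non-targeted quantity of the target
    assay; ``gapdh_gp`` the sample's normalised GAPDH quantity (its own
    Q divided by the GAPDH-assay MNT).  A missing CT yields NaN.
    """
    if target_mnt <= 0 or gapdh_gp <= 0:
        raise ValueError("MNT and GAPDH quantity must be > 0")
    q = ct_to_quantity(ct, target_curve)
    if math.isnan(q):
        return float("nan")
    goip = q / target_mnt
    return goip / gapdh_gp
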