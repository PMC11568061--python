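"""Enzyme-characterization arithmetic.

Covers the quantification math used to validate a screened methioninase
in vitro: an ammonia standard curve (Nessler colorimetry at 420 nm over
0.01-0.4 mM ammonium chloride), the enzyme unit definition (1 U = 1
micromole of L-methionine converted to ammonia per minute), specific
activity in U/mg protein, and the sequence-predicted molecular mass
(average residue masses, matching SDS-PAGE-scale comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio.SeqUtils import molecular_weight

from .errors import (
    AmbiguityError,
    DegenerateDesignError,
    EmptyInputError,
    InsufficientDataError,
    UnusableCurveError,
)
from .io import AMINO_ACIDS


@dataclass
class StandardCurve:
    """OLS line absorbance = slope * conc(mM) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    degenerate: bool = False  # flat response (SS_tot = 0)


@dataclass
class AmmoniaReading:
    """Back-calculated ammonia from one absorbance measurement."""

    conc_mM: float
    umol: float
    extrapolated: bool = False
    clamped: bool = False


@dataclass
class ActivityResult:
    """Enzyme units and specific activity from an ammonia measurement."""

    ammonia_umol: float
    minutes: float
    units: float
    protein_mg: float
    specific_activity: float


def fit_standard_curve(concentrations_mM, absorbances) -> StandardCurve:
    """Least-squares standard curve over >= 3 points.

    ``r_squared = 1 - SS_res/SS_tot``; a flat response (SS_tot = 0) is
    flagged degenerate with r² reported as 0.
    """
    x = np.asarray(concentrations_mM, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("concentrations and absorbances must match")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 standard points")
    if np.allclose(x, x[0]):
        raise DegenerateDesignError("all concentrations identical")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    degenerate = math.isclose(ss_tot, 0.0, abs_tol=1e-30)
    r2 = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(float(x.min()), float(x.max())),
        degenerate=degenerate,
    )


def ammonia_from_absorbance(
    curve: StandardCurve, a420: float, volume_mL: float
) -> AmmoniaReading:
    """Invert the standard curve: mM x mL = µmol.

    Concentrations outside the fitted range are flagged extrapolated;
    negative back-calculated concentrations are clamped to 0.
    """
    if curve.slope == 0:
        raise UnusableCurveError("standard curve has zero slope")
    conc = (a420 - curve.intercept) / curve.slope
    clamped = False
    if conc < 0:
        conc, clamped = 0.0, True
    lo, hi = curve.conc_range
    extrapolated = not (lo <= conc <= hi)
    return AmmoniaReading(
        conc_mM=conc,
        umol=conc * volume_mL,
        extrapolated=extrapolated,
        clamped=clamped,
    )


def specific_activity(
    ammonia_umol: float, minutes: float, protein_mg: float
) -> ActivityResult:
    """Units (µmol ammonia / min) and specific activity (U/mg)."""
    if minutes <= 0:
        raise ValueError("reaction time must be positive")
    if protein_mg <= 0:
        raise ValueError("protein amount must be positive")
    if ammonia_umol < 0:
        raise ValueError("ammonia must be non-negative")
    units = ammonia_umol / minutes
    return ActivityResult(
        ammonia_umol=ammonia_umol,
        minutes=minutes,
        units=units,
        protein_mg=protein_mg,
        specific_activity=units / protein_mg,
    )


def protein_mass(sequence: str) -> float:
    """Average molecular mass in daltons (residue masses + one water)."""
    if not sequence:
        raise EmptyInputError("cannot compute the mass of an empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise AmbiguityError(
            f"mass undefined for residues {sorted(bad)} (ambiguous/unknown)"
        )
    return float(molecular_weight(sequence, seq_type="protein"))


def replicate_stats(values) -> tuple[float, float]:
    """Mean and sample standard deviation of replicate measurements."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("no replicate values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
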