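"""Drug physicochemistry and the sublingual absorption model.

Buprenorphine is an ampholyte (tertiary amine pKa 8.31, phenol pKa 9.62)
that is absorbed transmucosally from the oral cavity; the remainder of a
sublingual dose is swallowed. The fraction absorbed transmucosally falls
with dose (nonlinear absorption) and with salivary pH: more acidic saliva
shifts the ionization equilibrium toward the membrane-impermeant cation,
so a larger share of the dose is recovered in saliva instead of absorbed.
Pregnancy lowers salivary pH (7.01 -> 6.34), which this module converts
into a multiplicative pregnancy factor on the absorbed fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DrugParameters",
    "SalivaryPhModel",
    "AbsorptionModel",
    "DoseSplit",
    "fit_salivary_line",
    "salivary_recovery",
    "pregnancy_scaling_factor",
    "absorbed_fraction",
    "absorbed_fraction_raw",
    "split_dose",
    "BUPRENORPHINE",
    "TABLET",
    "SOLUTION",
]

#: Lower/upper clamp on the absorbed fraction; mirrors the 0.1-99.9% range
#: over which the absorbed fraction is individualized post hoc.
FRACTION_BOUNDS = (0.001, 0.999)


class DegenerateInputError(ValueError):
    """Raised when a fit is requested on degenerate (uninformative) data."""


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical constants and clearance assignments for one drug.

    Parameters
    ----------
    molecular_weight : g/mol
    log_p : octanol-water log partition coefficient (unitless)
    pka_base : pKa of the basic (tertiary amine) group
    pka_acid : pKa of the acidic (phenol) group
    fu_plasma : fraction unbound in maternal plasma, in (0, 1]
    blood_plasma_ratio : whole blood to plasma concentration ratio
    psa : polar surface area, A^2
    hbd : hydrogen-bond donor count (integer >= 0)
    enzyme_fractions : enzyme name -> fraction of hepatic intrinsic
        clearance; values must sum to 1.
    renal_clearance : L/h
    hepatic_clu_int : unbound hepatic intrinsic clearance, L/h (baseline,
        nonpregnant; scaled by enzyme induction multipliers during
        pregnancy).
    """

    molecular_weight: float
    log_p: float
    pka_base: float
    pka_acid: float
    fu_plasma: float
    blood_plasma_ratio: float
    psa: float
    hbd: int
    enzyme_fractions: Mapping[str, float] = field(default_factory=dict)
    renal_clearance: float = 0.0
    hepatic_clu_int: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fu_plasma <= 1.0:
            raise ValueError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        if self.psa < 0:
            raise ValueError(f"psa must be >= 0, got {self.psa}")
        if self.hbd < 0 or int(self.hbd) != self.hbd:
            raise ValueError(f"hbd must be a non-negative integer, got {self.hbd}")
        if self.enzyme_fractions:
            vals = list(self.enzyme_fractions.values())
            if any(v < 0 for v in vals):
                raise ValueError("enzyme_fractions must be non-negative")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(
                    f"enzyme_fractions must sum to 1, got {sum(vals):.12f}"
                )
        if self.renal_clearance < 0:
            raise ValueError("renal_clearance must be >= 0")
        if self.hepatic_clu_int < 0:
            raise ValueError("hepatic_clu_int must be >= 0")


@dataclass(frozen=True)
class SalivaryPhModel:
    """Linear model of salivary recovery (%) as a function of salivary pH.

    ``recovered(%) = intercept_alpha + slope_beta * pH``; recovery is the
    inverse of transmucosal absorption, so absorbed(%) = 100 - recovered(%).
    """

    intercept_alpha: float
    slope_beta: float


def fit_salivary_line(
    anchor_points: Sequence[tuple[float, float]]
) -> SalivaryPhModel:
    """Fit the recovery-vs-pH line through the given (pH, recovery %) points.

    With exactly two points this is the interpolating line; with more it is
    the ordinary least-squares line.
    """
    pts = list(anchor_points)
    if len(pts) < 2:
        raise DegenerateInputError("need at least two (pH, recovery) points")
    ph = np.asarray([p for p, _ in pts], dtype=float)
    rec = np.asarray([r for _, r in pts], dtype=float)
    if np.ptp(ph) == 0.0:
        raise DegenerateInputError("all pH values identical; line is undefined")
    beta, alpha = np.polyfit(ph, rec, 1)
    return SalivaryPhModel(intercept_alpha=float(alpha), slope_beta=float(beta))


def salivary_recovery(model: SalivaryPhModel, ph: float) -> float:
    """Percent of a sublingual dose recovered in saliva at the given pH.

    Clamped to [0, 100] outside the data-supported range.
    """
    return float(np.clip(model.intercept_alpha + model.slope_beta * ph, 0.0, 100.0))


def pregnancy_scaling_factor(
    model: SalivaryPhModel, ph_nonpregnant: float, ph_pregnant: float
) -> float:
    """Multiplicative factor on the absorbed fraction due to pregnancy.

    Returns (100 - recovery_pregnant) / (100 - recovery_nonpregnant), i.e.
    the ratio of absorbed percentages at the two salivary pH values. The
    relative reduction in absorption is 1 minus this factor.
    """
    absorbed_np = 100.0 - salivary_recovery(model, ph_nonpregnant)
    absorbed_p = 100.0 - salivary_recovery(model, ph_pregnant)
    if absorbed_np == 0.0:
        raise ZeroDivisionError(
            "nonpregnant recovery is 100%: absorbed fraction is zero"
        )
    return absorbed_p / absorbed_np


@dataclass(frozen=True)
class AbsorptionModel:
    """Formulation-specific nonlinear sublingual absorption model.

    ``absorbed(%) = intercept + slope * log10(dose_mg)``, multiplied by
    ``pregnancy_factor`` for pregnant subjects.

    ka_transmucosal / ka_oral are first-order absorption rate constants
    (1/h) for the transmucosal depot (straight into systemic plasma) and
    the swallowed depot (through intestinal and hepatic first pass); both
    are inherited literature values, configurable. ``dose_cv`` is the
    between-subject coefficient of variation (%) applied to the dose in
    virtual trials to represent bioavailability variability.
    """

    formulation: str
    intercept: float
    slope: float
    pregnancy_factor: float = 1.0
    ka_transmucosal: float = 2.0
    ka_oral: float = 0.6
    dose_cv: float = 33.9

    def __post_init__(self) -> None:
        if not 0.0 < self.pregnancy_factor <= 1.0:
            raise ValueError("pregnancy_factor must be in (0, 1]")
        if self.dose_cv < 0:
            raise ValueError("dose_cv must be >= 0")
        if self.slope >= 0:
            raise ValueError("slope must be negative (absorption falls with dose)")


def absorbed_fraction_raw(
    model: AbsorptionModel, dose_mg: float, pregnant: bool = False
) -> float:
    """Unclamped absorbed fraction (may fall outside [0, 1] at extreme doses)."""
    if dose_mg <= 0:
        raise ValueError(f"dose must be positive, got {dose_mg}")
    pct = model.intercept + model.slope * math.log10(dose_mg)
    if pregnant:
        pct *= model.pregnancy_factor
    return pct / 100.0


def absorbed_fraction(
    model: AbsorptionModel, dose_mg: float, pregnant: bool = False
) -> float:
    """Fraction of the dose absorbed transmucosally, clamped to [0.001, 0.999]."""
    lo, hi = FRACTION_BOUNDS
    return float(np.clip(absorbed_fraction_raw(model, dose_mg, pregnant), lo, hi))


@dataclass(frozen=True)
class DoseSplit:
    """Partition of a sublingual dose into transmucosal and swallowed parts."""

    dose_mg: float
    fraction_transmucosal: float
    amount_transmucosal: float
    amount_swallowed: float


def split_dose(dose_mg: float, absorbed: float) -> DoseSplit:
    """Split a dose into the transmucosally absorbed and swallowed amounts.

    Mass is conserved exactly: the swallowed amount is computed as the
    complement ``dose - transmucosal``.
    """
    if not 0.0 <= absorbed <= 1.0:
        raise ValueError(f"absorbed fraction must be in [0, 1], got {absorbed}")
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    trans = dose_mg * absorbed
    swallowed = dose_mg - trans
    if trans + swallowed != dose_mg:
        # re-derive the larger part from the dose: that subtraction is exact
        # (Sterbenz), so the two parts then sum to the dose exactly
        if swallowed >= trans:
            trans = dose_mg - swallowed
        else:
            swallowed = dose_mg - trans
    return DoseSplit(
        dose_mg=dose_mg,
        fraction_transmucosal=absorbed,
        amount_transmucosal=trans,
        amount_swallowed=swallowed,
    )


# ---------------------------------------------------------------------------
# Default buprenorphine parameterization.
# Physicochemistry: PSA and HBD from PubChem; pKa values for the tertiary
# amine and phenol; fu and blood:plasma ratio are literature-sourced defaults
# (flagged: not printed in the primary source's main text). The hepatic
# enzyme split reflects CYP3A4- and CYP2C8-mediated N-dealkylation plus
# UGT1A1/UGT2B7 glucuronidation; hepatic_clu_int is set so the well-stirred
# hepatic clearance of ~57 L/h reproduces buprenorphine's high extraction.
# ---------------------------------------------------------------------------

BUPRENORPHINE = DrugParameters(
    molecular_weight=467.64,
    # log P 3.8 (ChemAxon / experimental range 3.8-5.0): the high ALOGPS
    # estimate over-attributes blood-cell uptake to neutral lipid and drives
    # the back-calculated acidic-phospholipid affinity negative
    log_p=3.8,
    pka_base=8.31,
    pka_acid=9.62,
    fu_plasma=0.04,
    blood_plasma_ratio=1.0,
    psa=62.2,
    hbd=2,
    enzyme_fractions={"CYP3A4": 0.45, "CYP2C8": 0.25, "UGT1A1": 0.10, "UGT2B7": 0.20},
    renal_clearance=0.2,
    hepatic_clu_int=5100.0,
)

#: Sublingual tablet: absorbed(%) = 38.1 - 19.7 * log10(dose_mg)
TABLET = AbsorptionModel(
    formulation="tablet", intercept=38.1, slope=-19.7, pregnancy_factor=0.754
)

#: Sublingual solution: absorbed(%) = 53.3 - 25.6 * log10(dose_mg)
SOLUTION = AbsorptionModel(
    formulation="solution", intercept=53.3, slope=-25.6, pregnancy_factor=0.754
)

#: Salivary recovery anchors: (pH, % recovered) in nonpregnant (7.01) and
#: pregnant (6.34) women.
SALIVARY_ANCHORS: tuple[tuple[float, float], ...] = ((7.01, 54.5), (6.34, 65.7))

#: Two-point recovery line through the anchors.
DEFAULT_SALIVARY_MODEL = fit_salivary_line(SALIVARY_ANCHORS)
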