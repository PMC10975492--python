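"""Gestational-age-dependent physiology.

Placental geometry (villous surface area and placental volume) follows
gestational-age polynomials; transplacental passive permeability is
predicted from polar surface area and hydrogen-bond donor count; and their
combination yields the placental diffusion clearance (CL_PD) that couples
the maternal and fetal circulations. Pregnancy-associated enzyme induction
is represented as configurable piecewise-linear fold-change trajectories
with structural aliasing: hepatic CYP2C8 and intestinal CYP3A4 copy the
hepatic CYP3A4 trajectory, and hepatic UGT2B7 copies hepatic UGT1A1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GA_SIMULATION_RANGE",
    "GestationalState",
    "PlacentaTransfer",
    "InductionModel",
    "predict_peff",
    "pvsa",
    "placenta_volume",
    "placental_diffusion_clearance",
    "induction_multiplier",
    "salivary_ph",
    "fetal_weight_kg",
    "default_induction",
]

log = logging.getLogger(__name__)

#: Gestational-age range (weeks) over which the fetal model is valid.
GA_SIMULATION_RANGE = (15.0, 40.0)

SALIVARY_PH_NONPREGNANT = 7.01
SALIVARY_PH_PREGNANT = 6.34

# Villous-surface-area polynomial coefficients (GA in weeks -> m^2).
# The quartic coefficient is -2e-5: the commonly quoted -2e-4 drives the
# surface area to -447 m^2 at term, whereas -2e-5 gives 13.4 m^2 and
# reproduces the term diffusion clearance of 0.1166 L/h/mL placenta exactly,
# so the larger magnitude is treated as a misprint.
_PVSA_COEFFS = (0.135, -0.023, 0.0015, -0.00002)

# Placental volume polynomial (GA in weeks -> mL).
_VOLUME_COEFFS = (1.0, 0.51, -0.0028)

_pvsa_notice_emitted = False


class GARangeError(ValueError):
    """Gestational age outside the supported range."""


def _check_ga(ga_weeks: float, lo: float = 0.0, hi: float = 40.0) -> None:
    if not lo < ga_weeks <= hi:
        raise GARangeError(
            f"gestational age {ga_weeks} weeks outside ({lo}, {hi}]"
        )


def predict_peff(psa: float, hbd: int) -> float:
    """Transplacental passive permeability, in 1e-4 cm/s.

    ``Peff = 10^(1.454 - 0.011 * PSA - 0.278 * HBD)``: permeability falls
    with polar surface area and hydrogen-bond donor count. The correlation
    was originally derived for intestinal permeability and is applied to the
    placental membrane, a common practice for passively diffusing drugs.
    """
    if psa < 0 or hbd < 0:
        raise ValueError("psa and hbd must be non-negative")
    return 10.0 ** (1.454 - 0.011 * psa - 0.278 * hbd)


def pvsa(ga_weeks: float) -> float:
    """Placental villous surface area (m^2) at the given gestational age."""
    global _pvsa_notice_emitted
    _check_ga(ga_weeks)
    if not _pvsa_notice_emitted:
        log.info(
            "PVSA polynomial uses quartic coefficient -2e-5; the frequently "
            "quoted -2e-4 yields a negative surface area at term."
        )
        _pvsa_notice_emitted = True
    a, b, c, d = _PVSA_COEFFS
    ga = float(ga_weeks)
    return a * ga + b * ga**2 + c * ga**3 + d * ga**4


def placenta_volume(ga_weeks: float) -> float:
    """Placental volume (mL) at the given gestational age."""
    _check_ga(ga_weeks)
    a, b, c = _VOLUME_COEFFS
    ga = float(ga_weeks)
    return a * ga + b * ga**2 + c * ga**3


@dataclass(frozen=True)
class PlacentaTransfer:
    """Placental diffusion clearance at one gestational age.

    ``cl_pd_per_ml`` is in L/h per mL placenta; ``cl_pd_total`` (L/h) is the
    whole-organ bidirectional passive exchange clearance between maternal and
    fetal plasma.
    """

    peff: float
    pvsa_m2: float
    placenta_volume_ml: float
    cl_pd_per_ml: float
    cl_pd_total: float


def placental_diffusion_clearance(peff: float, ga_weeks: float) -> PlacentaTransfer:
    """CL_PD = Peff * 3.6 * PVSA / Volume_placenta (L/h/mL placenta).

    The 3.6 scalar converts Peff (1e-4 cm/s) times surface area (m^2) into
    L/h: 1e-4 cm/s = 1e-6 m/s, times m^2 gives 1e-6 m^3/s = 1e-3 L/s =
    3.6 L/h.
    """
    lo, hi = GA_SIMULATION_RANGE
    _check_ga(ga_weeks, lo=lo - 1e-12, hi=hi)
    if peff <= 0:
        raise ValueError("peff must be positive")
    surface = pvsa(ga_weeks)
    volume = placenta_volume(ga_weeks)
    per_ml = peff * 3.6 * surface / volume
    return PlacentaTransfer(
        peff=peff,
        pvsa_m2=surface,
        placenta_volume_ml=volume,
        cl_pd_per_ml=per_ml,
        cl_pd_total=per_ml * volume,
    )


# -- enzyme induction ---------------------------------------------------------

#: (enzyme, site) pairs that structurally copy another trajectory.
INDUCTION_ALIASES: dict[tuple[str, str], tuple[str, str]] = {
    ("CYP2C8", "hepatic"): ("CYP3A4", "hepatic"),
    ("CYP3A4", "intestinal"): ("CYP3A4", "hepatic"),
    ("UGT2B7", "hepatic"): ("UGT1A1", "hepatic"),
}


class UnknownEnzymeError(KeyError):
    """Requested enzyme has no induction trajectory and no alias."""


@dataclass(frozen=True)
class InductionModel:
    """Piecewise-linear pregnancy induction trajectories, fold-change vs GA.

    ``profiles`` maps (enzyme, site) to (ga_grid, multipliers); every
    trajectory must start at fold-change 1.0 at GA 0 (nonpregnant baseline).
    Aliased enzymes resolve structurally through :data:`INDUCTION_ALIASES`
    and may not carry their own trajectory.
    """

    profiles: Mapping[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...]]]

    def __post_init__(self) -> None:
        for key, (grid, mult) in self.profiles.items():
            if key in INDUCTION_ALIASES:
                raise ValueError(
                    f"{key} is aliased to {INDUCTION_ALIASES[key]} and cannot "
                    "carry its own trajectory"
                )
            if len(grid) != len(mult) or len(grid) < 2:
                raise ValueError(f"malformed trajectory for {key}")
            if any(np.diff(grid) <= 0):
                raise ValueError(f"GA grid must be strictly increasing for {key}")
            if grid[0] != 0.0 or mult[0] != 1.0:
                raise ValueError(f"trajectory for {key} must start at (0, 1.0)")
            if any(m < 0 for m in mult):
                raise ValueError(f"negative multiplier for {key}")

    def multiplier(self, enzyme: str, ga_weeks: float, site: str = "hepatic") -> float:
        """Fold-change in enzyme abundance at the given gestational age."""
        key = INDUCTION_ALIASES.get((enzyme, site), (enzyme, site))
        if key not in self.profiles:
            raise UnknownEnzymeError(
                f"no induction trajectory for enzyme {enzyme!r} at site {site!r}"
            )
        grid, mult = self.profiles[key]
        return float(np.interp(ga_weeks, grid, mult))


def induction_multiplier(
    model: InductionModel, enzyme: str, ga_weeks: float, site: str = "hepatic"
) -> float:
    """Functional form of :meth:`InductionModel.multiplier`."""
    return model.multiplier(enzyme, ga_weeks, site=site)


def default_induction() -> InductionModel:
    """Default pregnancy induction trajectories.

    Hepatic CYP3A4 rises linearly to 1.6-fold at term (CYP3A substrate
    clearance increases of 50-100% are reported in pregnancy); hepatic
    UGT1A1 rises to 1.5-fold (clearance of UGT2B7 substrates morphine and
    zidovudine increases by about 1.5-fold). CYP2C8, intestinal CYP3A4 and
    UGT2B7 follow by aliasing.
    """
    return InductionModel(
        profiles={
            ("CYP3A4", "hepatic"): ((0.0, 40.0), (1.0, 1.6)),
            ("UGT1A1", "hepatic"): ((0.0, 40.0), (1.0, 1.5)),
        }
    )


def salivary_ph(pregnant: bool) -> float:
    """Salivary pH: 6.34 during pregnancy, 7.01 otherwise (incl. postpartum).

    Salivary pH returns to pre-pregnancy values quickly after delivery, so a
    step function on pregnancy status is used rather than a GA-continuous
    trajectory; :class:`GestationalState` keeps a per-state value as a hook
    for GA-dependent refinements.
    """
    return SALIVARY_PH_PREGNANT if pregnant else SALIVARY_PH_NONPREGNANT


def fetal_fraction_unbound(
    fu_maternal: float, ga_weeks: float, protein_ratio_at_term: float = 0.34
) -> float:
    """Fetal plasma fraction unbound from binding-protein ontogeny.

    Fetal plasma binding proteins (notably alpha-1-acid glycoprotein) rise
    roughly linearly across gestation, reaching about one third of the
    maternal concentration at term. Assuming the same binding affinity on
    both sides, fu_fetal = 1 / (1 + (1 - fu_m)/fu_m * r(GA)) with
    r(GA) = protein_ratio_at_term * GA / 40. Lower fetal binding early in
    gestation means less total drug is held in cord plasma; as the proteins
    accumulate, total cord concentration rises toward maternal levels even
    though the unbound concentrations equilibrate across the placenta.
    """
    if not 0 < fu_maternal <= 1:
        raise ValueError("fu_maternal must be in (0, 1]")
    _check_ga(ga_weeks)
    ratio = protein_ratio_at_term * ga_weeks / 40.0
    return 1.0 / (1.0 + (1.0 - fu_maternal) / fu_maternal * ratio)


def fetal_weight_kg(ga_weeks: float) -> float:
    """Fetal weight (kg) from a log-quadratic growth curve.

    ln(weight in g) = 0.578 + 0.332 GA - 0.00354 GA^2 (Hadlock-type growth
    standard); about 0.12 kg at 15 weeks and 3.6 kg at term.
    """
    _check_ga(ga_weeks)
    return math.exp(0.578 + 0.332 * ga_weeks - 0.00354 * ga_weeks**2) / 1000.0


@dataclass(frozen=True)
class GestationalState:
    """Snapshot of gestational physiology at one gestational age."""

    ga_weeks: float
    pvsa_m2: float
    placenta_volume_ml: float
    induction: InductionModel
    salivary_ph: float
    fetal_weight: float

    @classmethod
    def at(
        cls, ga_weeks: float, induction: InductionModel | None = None
    ) -> "GestationalState":
        """Build the state for a pregnant subject at ``ga_weeks`` (15-40)."""
        lo, hi = GA_SIMULATION_RANGE
        if not lo <= ga_weeks <= hi:
            raise GARangeError(
                f"simulation requires gestational age in [{lo}, {hi}] weeks, "
                f"got {ga_weeks}"
            )
        return cls(
            ga_weeks=float(ga_weeks),
            pvsa_m2=pvsa(ga_weeks),
            placenta_volume_ml=placenta_volume(ga_weeks),
            induction=induction if induction is not None else default_induction(),
            salivary_ph=salivary_ph(pregnant=True),
            fetal_weight=fetal_weight_kg(ga_weeks),
        )
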