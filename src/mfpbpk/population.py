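"""Virtual-trial machinery and verification statistics.

Virtual mother-fetus dyads share a template (age, gestational age, regimen)
and differ by a lognormally distributed dose multiplier that represents
between-subject bioavailability variability. Trials are summarized per time
point by the geometric mean and the 5th/95th percentiles over all subjects
pooled across trials.

Post hoc individualization fits a single subject-level parameter -- the
fraction of the dose absorbed transmucosally -- to that subject's observed
maternal concentration, then predicts the companion fetal (umbilical cord)
concentration. Predictive performance is summarized as the geometric mean
ratio (GMR) of predicted to observed concentrations with a t-based 95% CI on
the log scale, the proportions within the 1.25- and 2-fold prediction error
ranges, and a Shapiro-Wilk normality check of the log fold-differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .drug import AbsorptionModel, DrugParameters, absorbed_fraction
from .gestation import GestationalState
from .simulator import (
    DyadModel,
    PKMetrics,
    Physiology,
    Regimen,
    SimulationResult,
    build_dyad_model,
    compute_pk_metrics,
    default_physiology,
    simulate,
)

__all__ = [
    "Dyad",
    "TrialConfig",
    "PopulationSummary",
    "ObservationRecord",
    "PosthocFit",
    "FoldDifferenceStats",
    "PORatio",
    "sample_dyads",
    "simulate_dyad",
    "run_virtual_trial",
    "posthoc_optimize_absorption",
    "predict_dyad_concentrations",
    "fold_difference_stats",
    "po_ratio",
    "verification_table",
    "FRACTION_SEARCH_BOUNDS",
]

#: Search range for the post hoc absorbed fraction (0.1% to 99.9%).
FRACTION_SEARCH_BOUNDS = (0.001, 0.999)


@dataclass(frozen=True)
class Dyad:
    """One virtual mother-fetus pair.

    ``ga_weeks=None`` denotes a nonpregnant/postpartum subject (no fetal
    compartments). ``dose_multiplier`` scales the administered amounts;
    ``absorbed_fraction_override`` bypasses the dose-dependent absorption
    model when set (post hoc individualization, synthetic ground truth).
    """

    dyad_id: str
    maternal_age: float
    ga_weeks: float | None
    regimen: Regimen
    dose_multiplier: float = 1.0
    absorbed_fraction_override: float | None = None

    def __post_init__(self) -> None:
        if self.dose_multiplier <= 0:
            raise ValueError("dose_multiplier must be positive")
        if self.absorbed_fraction_override is not None and not (
            FRACTION_SEARCH_BOUNDS[0]
            <= self.absorbed_fraction_override
            <= FRACTION_SEARCH_BOUNDS[1]
        ):
            raise ValueError("absorbed_fraction_override outside [0.001, 0.999]")


@dataclass(frozen=True)
class TrialConfig:
    """Virtual trial layout: ``n_trials`` trials of ``n_subjects_per_trial``."""

    n_subjects_per_trial: int = 10
    n_trials: int = 10
    duration_h: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_trial < 1 or self.n_trials < 1:
            raise ValueError("subject and trial counts must be >= 1")


def _lognormal_multipliers(rng: np.random.Generator, n: int, cv_pct: float) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given CV (%), truncated at
    +/- 3 SD on the log scale so sampled doses stay positive and bounded."""
    if cv_pct == 0:
        return np.ones(n)
    cv = cv_pct / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = -0.5 * sigma * sigma  # E[exp(N(mu, sigma^2))] = 1
    z = rng.standard_normal(n)
    z = np.clip(z, -3.0, 3.0)
    return np.exp(mu + sigma * z)


def sample_dyads(
    config: TrialConfig,
    template: Dyad,
    absorption: AbsorptionModel,
    rng: np.random.Generator | int | None = None,
) -> list[Dyad]:
    """Cohort of ``n_subjects * n_trials`` dyads copied from the template,
    with dose multipliers sampled lognormally at the absorption model's CV."""
    if not 18 <= template.maternal_age <= 45:
        raise ValueError("standard population requires maternal age in [18, 45]")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    n = config.n_subjects_per_trial * config.n_trials
    mults = _lognormal_multipliers(rng, n, absorption.dose_cv)
    return [
        replace(template, dyad_id=f"{template.dyad_id}-{i:03d}", dose_multiplier=m)
        for i, m in enumerate(mults)
    ]


def _dyad_model(
    dyad: Dyad,
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None,
) -> DyadModel:
    pregnant = dyad.ga_weeks is not None
    state = GestationalState.at(dyad.ga_weeks) if pregnant else None
    if dyad.absorbed_fraction_override is not None:
        frac = dyad.absorbed_fraction_override
    else:
        frac = absorbed_fraction(absorption, dyad.regimen.dose_mg, pregnant=pregnant)
    return build_dyad_model(
        drug,
        dyad.regimen,
        frac,
        absorption=absorption,
        gestational_state=state,
        physiology=physiology,
    )


def simulate_dyad(
    dyad: Dyad,
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None = None,
    duration_h: float = 180.0,
    grid_step_h: float | None = 0.1,
    extra_times: Sequence[float] | None = None,
) -> SimulationResult:
    """Simulate one dyad. The transmucosal fraction comes from the
    dose-dependent absorption model (nominal dose) unless overridden; the
    dose multiplier scales the administered amounts."""
    model = _dyad_model(dyad, drug, absorption, physiology)
    return simulate(
        model,
        duration_h,
        grid_step_h=grid_step_h,
        extra_times=extra_times,
        dose_multiplier=dyad.dose_multiplier,
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Per-time geometric mean and 5th/95th percentile bands, pooled over
    all subjects, plus geometric-mean PK metrics over the last interval."""

    times: np.ndarray
    maternal_geomean: np.ndarray
    maternal_p5: np.ndarray
    maternal_p95: np.ndarray
    fetal_geomean: np.ndarray
    fetal_p5: np.ndarray
    fetal_p95: np.ndarray
    pk_geomean: PKMetrics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "maternal_geomean_ng_ml": self.maternal_geomean,
                "maternal_p5_ng_ml": self.maternal_p5,
                "maternal_p95_ng_ml": self.maternal_p95,
                "fetal_geomean_ng_ml": self.fetal_geomean,
                "fetal_p5_ng_ml": self.fetal_p5,
                "fetal_p95_ng_ml": self.fetal_p95,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _geomean_cols(mat: np.ndarray) -> np.ndarray:
    """Column geometric means; any zero in a column makes that mean zero."""
    out = np.zeros(mat.shape[1])
    pos = (mat > 0).all(axis=0)
    if pos.any():
        out[pos] = np.exp(np.mean(np.log(mat[:, pos]), axis=0))
    return out


class TrialExecutionError(RuntimeError):
    """One or more dyad simulations failed; carries per-dyad diagnostics."""


def run_virtual_trial(
    cohort: Sequence[Dyad],
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None = None,
    duration_h: float = 180.0,
    grid_step_h: float = 0.1,
) -> PopulationSummary:
    """Simulate every dyad and pool subjects across trials.

    PK metrics are evaluated on the last full dosing interval of the run and
    summarized as geometric means.
    """
    maternal, fetal, metrics = [], [], []
    failures = []
    for dyad in cohort:
        try:
            res = simulate_dyad(
                dyad,
                drug,
                absorption,
                physiology,
                duration_h=duration_h,
                grid_step_h=grid_step_h,
            )
        except Exception as exc:  # aggregate, then report all failures
            failures.append((dyad.dyad_id, repr(exc)))
            continue
        maternal.append(res.profile.maternal_plasma)
        fetal.append(res.profile.fetal_plasma)
        reg = dyad.regimen
        # PK metrics on the last dosing interval the run actually covers
        k_last = min(
            reg.n_doses - 1,
            int(math.floor((duration_h - reg.start_time_h) / reg.interval_h)),
        )
        t_last = reg.start_time_h + reg.interval_h * k_last
        if t_last >= duration_h - 1e-9 and k_last > 0:
            t_last -= reg.interval_h
        t_end = min(t_last + reg.interval_h, duration_h)
        metrics.append(
            compute_pk_metrics(
                res.profile, t_last, t_end, reg.dose_mg * dyad.dose_multiplier
            )
        )
        times = res.profile.times
    if failures:
        raise TrialExecutionError(f"{len(failures)} dyad(s) failed: {failures}")

    m = np.vstack(maternal)
    f = np.vstack(fetal)
    pk = PKMetrics(
        auc=float(stats.gmean([x.auc for x in metrics])),
        cl_over_f=float(stats.gmean([x.cl_over_f for x in metrics])),
        cmax=float(stats.gmean([x.cmax for x in metrics])),
        tmax=float(stats.gmean([max(x.tmax, 1e-12) for x in metrics])),
    )
    return PopulationSummary(
        times=times,
        maternal_geomean=_geomean_cols(m),
        maternal_p5=np.percentile(m, 5, axis=0),
        maternal_p95=np.percentile(m, 95, axis=0),
        fetal_geomean=_geomean_cols(f),
        fetal_p5=np.percentile(f, 5, axis=0),
        fetal_p95=np.percentile(f, 95, axis=0),
        pk_geomean=pk,
    )


# -- post hoc individualization ------------------------------------------------


@dataclass(frozen=True)
class ObservationRecord:
    """One observed concentration pair for a dyad, timed since the last dose."""

    dyad_id: str
    time_since_last_dose_h: float
    maternal_conc: float | None = None
    fetal_conc: float | None = None

    def __post_init__(self) -> None:
        if self.maternal_conc is None and self.fetal_conc is None:
            raise ValueError("at least one concentration must be present")
        if self.time_since_last_dose_h < 0:
            raise ValueError("time_since_last_dose_h must be >= 0")


@dataclass(frozen=True)
class PosthocFit:
    """Result of the bounded search for the absorbed fraction."""

    absorbed_fraction_hat: float
    objective_value: float
    converged: bool
    hit_bound: bool


class ObservationDataError(ValueError):
    """Observed concentrations unusable for fitting."""


def _observation_time_abs(dyad: Dyad, observation: ObservationRecord) -> float:
    reg = dyad.regimen
    return (
        reg.start_time_h
        + reg.interval_h * (reg.n_doses - 1)
        + observation.time_since_last_dose_h
    )


def _basis_concentrations(
    dyad: Dyad,
    t_obs: float,
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Maternal/fetal concentrations at t_obs for fractions 0 and 1.

    The disposition matrix does not depend on the split, so the predicted
    concentration is affine in the transmucosal fraction f:
    ``c(f) = c0 + f * (c1 - c0)``. Dose events only (no output grid) keeps
    each basis run cheap.
    """
    model = _dyad_model(dyad, drug, absorption, physiology)
    out = []
    for f in (0.0, 1.0):
        res = simulate(
            model,
            t_obs,
            grid_step_h=None,
            extra_times=[t_obs],
            fraction=f,
            dose_multiplier=dyad.dose_multiplier,
        )
        out.append(
            np.array(
                [res.profile.maternal_plasma[-1], res.profile.fetal_plasma[-1]]
            )
        )
    return out[0], out[1]


def posthoc_optimize_absorption(
    dyad: Dyad,
    observation: ObservationRecord,
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None = None,
    xatol: float = 1e-4,
) -> PosthocFit:
    """Individualize the transmucosal fraction against the observed maternal
    concentration.

    Minimizes |log(predicted) - log(observed)| at the observation time with a
    bounded scalar (Brent) search over [0.001, 0.999]; the objective is
    smooth and monotone in the fraction for this linear system. Returns
    ``hit_bound=True`` when the observation lies outside the attainable
    concentration range and the optimum sits at a bound.
    """
    if observation.maternal_conc is None:
        raise ObservationDataError("a maternal concentration is required")
    obs = observation.maternal_conc
    if obs <= 0:
        raise ObservationDataError("observed maternal concentration must be > 0")
    t_obs = _observation_time_abs(dyad, observation)
    c0, c1 = _basis_concentrations(dyad, t_obs, drug, absorption, physiology)
    lo, hi = FRACTION_SEARCH_BOUNDS

    def predicted_maternal(f: float) -> float:
        return float(c0[0] + f * (c1[0] - c0[0]))

    # the predicted maternal concentration is increasing in f; observations
    # outside the attainable range pin the estimate to a bound
    if obs >= predicted_maternal(hi):
        return PosthocFit(hi, abs(math.log(predicted_maternal(hi) / obs)), True, True)
    if obs <= predicted_maternal(lo):
        return PosthocFit(lo, abs(math.log(predicted_maternal(lo) / obs)), True, True)

    res = optimize.minimize_scalar(
        lambda f: abs(math.log(predicted_maternal(f)) - math.log(obs)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    f_hat = float(res.x)
    hit = f_hat <= lo + 2 * xatol or f_hat >= hi - 2 * xatol
    return PosthocFit(
        absorbed_fraction_hat=f_hat,
        objective_value=float(res.fun),
        converged=bool(res.success),
        hit_bound=hit,
    )


def predict_dyad_concentrations(
    dyad: Dyad,
    observation: ObservationRecord,
    fraction: float,
    drug: DrugParameters,
    absorption: AbsorptionModel,
    physiology: Physiology | None = None,
) -> tuple[float, float]:
    """(maternal, fetal) concentrations at the observation time for a given
    transmucosal fraction (typically the post hoc estimate)."""
    t_obs = _observation_time_abs(dyad, observation)
    c0, c1 = _basis_concentrations(dyad, t_obs, drug, absorption, physiology)
    c = c0 + fraction * (c1 - c0)
    return float(c[0]), float(c[1])


# -- fold-difference statistics -------------------------------------------------


@dataclass(frozen=True)
class FoldDifferenceStats:
    """GMR of predicted/observed pairs with t-based 95% CI on the log scale,
    fold-range proportions (inclusive boundaries) and Shapiro-Wilk p."""

    n: int
    geometric_mean_ratio: float
    ci95_low: float
    ci95_high: float
    prop_within_2fold: float
    prop_within_1p25fold: float
    shapiro_p: float


def fold_difference_stats(
    pairs: Sequence[tuple[float, float]]
) -> FoldDifferenceStats:
    """Summarize predicted-vs-observed concentration fold-differences."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (predicted, observed) pairs")
    if np.any(arr <= 0):
        raise ObservationDataError("concentrations must be positive")
    ratios = arr[:, 0] / arr[:, 1]
    logs = np.log(ratios)
    n = len(logs)
    mean = logs.mean()
    gmr = math.exp(mean)
    if np.ptp(logs) == 0.0:
        ci_lo = ci_hi = gmr
        shapiro_p = float("nan")
    else:
        se = logs.std(ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.975, df=n - 1)
        ci_lo, ci_hi = math.exp(mean - tcrit * se), math.exp(mean + tcrit * se)
        shapiro_p = float(stats.shapiro(logs).pvalue)
    within = lambda bound: float(
        np.mean((ratios >= 1.0 / bound - 1e-12) & (ratios <= bound + 1e-12))
    )
    return FoldDifferenceStats(
        n=n,
        geometric_mean_ratio=gmr,
        ci95_low=ci_lo,
        ci95_high=ci_hi,
        prop_within_2fold=within(2.0),
        prop_within_1p25fold=within(1.25),
        shapiro_p=shapiro_p,
    )


@dataclass(frozen=True)
class PORatio:
    """Predicted-over-observed ratio of one PK metric."""

    metric: str
    predicted: float
    observed: float
    ratio: float
    within_1p25fold: bool


def po_ratio(predicted: PKMetrics, observed: PKMetrics) -> list[PORatio]:
    """Elementwise P/O ratios for AUC, CL/F, Cmax and Tmax, with the
    1.25-fold acceptance flag (inclusive boundaries)."""
    out = []
    for name in ("auc", "cl_over_f", "cmax", "tmax"):
        o = getattr(observed, name)
        if o <= 0:
            raise ValueError(f"observed {name} must be positive")
        p = getattr(predicted, name)
        r = p / o
        out.append(
            PORatio(
                metric=name,
                predicted=p,
                observed=o,
                ratio=r,
                within_1p25fold=bool(1.0 / 1.25 - 1e-12 <= r <= 1.25 + 1e-12),
            )
        )
    return out


def verification_table(
    dyad_ids: Sequence[str],
    predicted: Sequence[float],
    observed: Sequence[float],
) -> pd.DataFrame:
    """One row per dyad (predicted, observed, fold-difference) plus a summary
    row carrying the GMR, its 95% CI and the fold-range proportions."""
    stats_ = fold_difference_stats(list(zip(predicted, observed)))
    rows = [
        {
            "dyad_id": d,
            "predicted_ng_ml": p,
            "observed_ng_ml": o,
            "fold_difference": p / o,
        }
        for d, p, o in zip(dyad_ids, predicted, observed)
    ]
    rows.append(
        {
            "dyad_id": "summary",
            "predicted_ng_ml": float("nan"),
            "observed_ng_ml": float("nan"),
            "fold_difference": stats_.geometric_mean_ratio,
            "gmr_ci95_low": stats_.ci95_low,
            "gmr_ci95_high": stats_.ci95_high,
            "prop_within_2fold": stats_.prop_within_2fold,
            "prop_within_1p25fold": stats_.prop_within_1p25fold,
            "shapiro_p": stats_.shapiro_p,
        }
    )
    return pd.DataFrame(rows)
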