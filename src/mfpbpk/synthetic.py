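"""Synthetic mother-fetus observation sets.

Stands in for delivery-time clinical datasets: each synthetic dyad receives
a sublingual tablet regimen (dose drawn log-uniformly over the study dose
range), is simulated to pseudo-steady state (14 days), and contributes one
maternal and one fetal concentration drawn at a random time within a day of
the last dose, perturbed by lognormal observation noise. The generating
("true") absorbed fractions and noise-free concentrations are emitted in a
separate ground-truth table that the estimation path never reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug import AbsorptionModel, BUPRENORPHINE, DrugParameters, TABLET
from .gestation import GA_SIMULATION_RANGE
from .population import (
    Dyad,
    ObservationRecord,
    fold_difference_stats,
    posthoc_optimize_absorption,
    predict_dyad_concentrations,
    simulate_dyad,
)
from .simulator import Physiology, Regimen

__all__ = [
    "SyntheticStudySpec",
    "generate_synthetic_study",
    "run_recovery_study",
    "OBSERVATION_COLUMNS",
]

OBSERVATION_COLUMNS = [
    "dyad_id",
    "dose_mg",
    "interval_h",
    "ga_weeks",
    "maternal_age",
    "time_since_last_dose_h",
    "maternal_ng_ml",
    "fetal_ng_ml",
]

TRUTH_COLUMNS = [
    "dyad_id",
    "true_absorbed_fraction",
    "true_maternal_ng_ml",
    "true_fetal_ng_ml",
]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a synthetic delivery study.

    Doses are drawn log-uniformly from ``dose_range_mg`` (daily sublingual
    tablets, emulating a 1-28 mg/day maintenance population); gestational
    ages uniformly from ``ga_range_weeks`` (near-term by default, since the
    observations emulate delivery samples). ``true_fraction_range`` draws the
    generating transmucosal fraction uniformly; ``None`` uses the
    dose-dependent absorption model instead. ``obs_noise_cv_pct`` is the
    lognormal CV of the observation noise.
    """

    n_dyads: int = 21
    dose_range_mg: tuple[float, float] = (1.0, 28.0)
    ga_range_weeks: tuple[float, float] = (36.0, 40.0)
    true_fraction_range: tuple[float, float] | None = (0.1, 0.9)
    obs_noise_cv_pct: float = 15.0
    maternal_age_range: tuple[float, float] = (18.0, 45.0)
    interval_h: float = 24.0
    n_doses: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.dose_range_mg
        if not 1.0 <= lo <= hi <= 32.0:
            raise ValueError("dose range must lie within [1, 32] mg")
        glo, ghi = self.ga_range_weeks
        if not GA_SIMULATION_RANGE[0] <= glo <= ghi <= GA_SIMULATION_RANGE[1]:
            raise ValueError("GA range must lie within [15, 40] weeks")
        if self.obs_noise_cv_pct < 0:
            raise ValueError("obs_noise_cv_pct must be >= 0")
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")


def _noise(rng: np.random.Generator, cv_pct: float, size: int) -> np.ndarray:
    if cv_pct == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p((cv_pct / 100.0) ** 2))
    return np.exp(rng.standard_normal(size) * sigma - 0.5 * sigma * sigma)


def generate_synthetic_study(
    spec: SyntheticStudySpec,
    drug: DrugParameters = BUPRENORPHINE,
    absorption: AbsorptionModel = TABLET,
    physiology: Physiology | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the study and return (observations, ground_truth) tables."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_dyads
    doses = np.exp(
        rng.uniform(math.log(spec.dose_range_mg[0]), math.log(spec.dose_range_mg[1]), n)
    )
    gas = rng.uniform(*spec.ga_range_weeks, n)
    ages = rng.uniform(*spec.maternal_age_range, n)
    t_since = rng.uniform(0.0, 24.0, n)
    if spec.true_fraction_range is not None:
        fractions = rng.uniform(*spec.true_fraction_range, n)
    else:
        fractions = np.full(n, np.nan)
    noise_m = _noise(rng, spec.obs_noise_cv_pct, n)
    noise_f = _noise(rng, spec.obs_noise_cv_pct, n)

    obs_rows, truth_rows = [], []
    for i in range(n):
        regimen = Regimen(
            dose_mg=float(doses[i]),
            interval_h=spec.interval_h,
            n_doses=spec.n_doses,
            formulation=absorption.formulation,
        )
        dyad = Dyad(
            dyad_id=f"syn-{i:03d}",
            maternal_age=float(ages[i]),
            ga_weeks=float(gas[i]),
            regimen=regimen,
            absorbed_fraction_override=(
                float(fractions[i]) if spec.true_fraction_range is not None else None
            ),
        )
        t_obs = (
            regimen.start_time_h
            + regimen.interval_h * (regimen.n_doses - 1)
            + float(t_since[i])
        )
        res = simulate_dyad(
            dyad,
            drug,
            absorption,
            physiology,
            duration_h=t_obs,
            grid_step_h=None,
            extra_times=[t_obs],
        )
        c_m = float(res.profile.maternal_plasma[-1])
        c_f = float(res.profile.fetal_plasma[-1])
        obs_rows.append(
            {
                "dyad_id": dyad.dyad_id,
                "dose_mg": regimen.dose_mg,
                "interval_h": regimen.interval_h,
                "ga_weeks": dyad.ga_weeks,
                "maternal_age": dyad.maternal_age,
                "time_since_last_dose_h": float(t_since[i]),
                "maternal_ng_ml": c_m * float(noise_m[i]),
                "fetal_ng_ml": c_f * float(noise_f[i]),
            }
        )
        truth_rows.append(
            {
                "dyad_id": dyad.dyad_id,
                "true_absorbed_fraction": (
                    float(fractions[i])
                    if spec.true_fraction_range is not None
                    else float("nan")
                ),
                "true_maternal_ng_ml": c_m,
                "true_fetal_ng_ml": c_f,
            }
        )
    return (
        pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS),
        pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
    )


def dyads_from_observations(
    observations: pd.DataFrame, spec_n_doses: int = 14
) -> list[tuple[Dyad, ObservationRecord]]:
    """Reconstruct (dyad, observation) pairs from an observation table.

    Only the observation columns are used; ground truth never enters here.
    """
    out = []
    for _, row in observations.iterrows():
        regimen = Regimen(
            dose_mg=float(row["dose_mg"]),
            interval_h=float(row["interval_h"]),
            n_doses=spec_n_doses,
        )
        ga = row.get("ga_weeks")
        dyad = Dyad(
            dyad_id=str(row["dyad_id"]),
            maternal_age=float(row["maternal_age"]),
            ga_weeks=float(ga) if pd.notna(ga) else None,
            regimen=regimen,
        )
        m = row.get("maternal_ng_ml")
        f = row.get("fetal_ng_ml")
        record = ObservationRecord(
            dyad_id=dyad.dyad_id,
            time_since_last_dose_h=float(row["time_since_last_dose_h"]),
            maternal_conc=float(m) if pd.notna(m) else None,
            fetal_conc=float(f) if pd.notna(f) else None,
        )
        out.append((dyad, record))
    return out


def run_recovery_study(
    n_dyads: int = 50,
    obs_noise_cv_pct: float = 15.0,
    seed: int = 0,
    drug: DrugParameters = BUPRENORPHINE,
    absorption: AbsorptionModel = TABLET,
    physiology: Physiology | None = None,
) -> dict:
    """Parameter-recovery experiment on synthetic dyads.

    Generates ``n_dyads`` dyads with true transmucosal fractions drawn
    U[0.1, 0.9] and noisy delivery observations, individualizes the fraction
    against each noisy maternal concentration, and compares the resulting
    fetal predictions with the noisy fetal observations. Returns recovered
    fractions, errors against truth, and the fetal fold-difference summary.
    """
    spec = SyntheticStudySpec(
        n_dyads=n_dyads,
        true_fraction_range=(0.1, 0.9),
        obs_noise_cv_pct=obs_noise_cv_pct,
        seed=seed,
    )
    observations, truth = generate_synthetic_study(
        spec, drug=drug, absorption=absorption, physiology=physiology
    )
    fits, fetal_pred = [], []
    for dyad, record in dyads_from_observations(observations, spec.n_doses):
        fit = posthoc_optimize_absorption(
            dyad, record, drug, absorption, physiology
        )
        fits.append(fit)
        _, c_f = predict_dyad_concentrations(
            dyad, record, fit.absorbed_fraction_hat, drug, absorption, physiology
        )
        fetal_pred.append(c_f)

    recovered = np.array([f.absorbed_fraction_hat for f in fits])
    true_f = truth["true_absorbed_fraction"].to_numpy(float)
    errors = recovered - true_f
    fetal_obs = observations["fetal_ng_ml"].to_numpy(float)
    stats_ = fold_difference_stats(list(zip(fetal_pred, fetal_obs)))
    return {
        "recovered_fractions": recovered,
        "true_fractions": true_f,
        "errors": errors,
        "median_abs_error": float(np.median(np.abs(errors))),
        "fetal_predicted": np.asarray(fetal_pred),
        "fetal_observed": fetal_obs,
        "fold_stats": stats_,
        "observations": observations,
        "truth": truth,
    }
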