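"""Study configuration: a YAML file with unit-suffixed keys.

One file carries the drug block (physicochemistry plus clearance
assignments), the absorption block per formulation, the physiology block
(including enzyme-induction trajectories), and the virtual-trial block.
Unknown keys are rejected and all validation problems are reported in a
single error. A written configuration reads back to an identical structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .drug import AbsorptionModel, BUPRENORPHINE, DrugParameters, SOLUTION, TABLET
from .gestation import InductionModel, default_induction
from .population import TrialConfig
from .simulator import Physiology

__all__ = ["StudyConfig", "ConfigError", "default_config", "load_config", "save_config"]


class ConfigError(ValueError):
    """All configuration problems, collected into one message."""


@dataclass(frozen=True)
class StudyConfig:
    drug: DrugParameters
    absorption: dict  # formulation name -> AbsorptionModel
    physiology: Physiology
    induction: InductionModel
    trial: TrialConfig
    seed: int = 0

    def content_hash(self) -> str:
        """Stable hash of the full configuration (logged with every run)."""
        payload = yaml.safe_dump(_to_mapping(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config() -> StudyConfig:
    return StudyConfig(
        drug=BUPRENORPHINE,
        absorption={"tablet": TABLET, "solution": SOLUTION},
        physiology=Physiology(),
        induction=default_induction(),
        trial=TrialConfig(),
        seed=0,
    )


# -- schema -------------------------------------------------------------------

_DRUG_KEYS = {
    "molecular_weight_g_mol": "molecular_weight",
    "log_p": "log_p",
    "pka_base": "pka_base",
    "pka_acid": "pka_acid",
    "fu_plasma": "fu_plasma",
    "blood_plasma_ratio": "blood_plasma_ratio",
    "psa_A2": "psa",
    "hbd_count": "hbd",
    "renal_clearance_L_h": "renal_clearance",
    "hepatic_clu_int_L_h": "hepatic_clu_int",
    "enzyme_fractions": "enzyme_fractions",
}

_FORMULATION_KEYS = {
    "intercept_pct": "intercept",
    "slope_pct_per_log10_mg": "slope",
}

_ABSORPTION_SHARED_KEYS = {
    "pregnancy_factor": "pregnancy_factor",
    "ka_transmucosal_per_h": "ka_transmucosal",
    "ka_oral_per_h": "ka_oral",
    "dose_cv_pct": "dose_cv",
}

_PHYSIOLOGY_KEYS = {
    "body_weight_kg": "body_weight_kg",
    "cardiac_output_L_h": "cardiac_output_l_h",
    "plasma_volume_L_kg": "plasma_volume_l_kg",
    "hematocrit": "hematocrit",
    "tissue_volumes_L_kg": "tissue_volumes_l_kg",
    "tissue_flow_fractions": "tissue_flow_fractions",
    "fa_oral": "fa_oral",
    "fg_baseline": "fg_baseline",
    "target_vss_L_kg": "target_vss_l_kg",
    "fu_fetal": "fu_fetal",
    "fetal_protein_ratio_term": "fetal_protein_ratio_term",
    "clu_fetal_L_h": "clu_fetal_l_h",
    "fetal_plasma_L_kg": "fetal_plasma_l_kg",
    "fetal_tissue_L_kg": "fetal_tissue_l_kg",
    "fetal_tissue_flow_L_h_kg": "fetal_tissue_flow_l_h_kg",
    "placenta_flow_L_h_ml": "placenta_flow_l_h_ml",
}

_TRIAL_KEYS = {
    "n_subjects_per_trial": "n_subjects_per_trial",
    "n_trials": "n_trials",
    "duration_h": "duration_h",
    "seed": "seed",
}

_TOP_KEYS = {"drug", "absorption", "physiology", "trial", "seed"}


def _map_block(
    block: dict, keymap: dict[str, str], where: str, errors: list[str]
) -> dict:
    out = {}
    for key, value in block.items():
        if key not in keymap:
            errors.append(f"{where}: unknown key {key!r}")
            continue
        out[keymap[key]] = value
    return out


def _to_mapping(cfg: StudyConfig) -> dict:
    inv = lambda m: {v: k for k, v in m.items()}
    drug = {k: getattr(cfg.drug, v) for k, v in _DRUG_KEYS.items()}
    drug["enzyme_fractions"] = dict(cfg.drug.enzyme_fractions)
    absorption: dict = {
        k: getattr(cfg.absorption["tablet"], v)
        for k, v in _ABSORPTION_SHARED_KEYS.items()
    }
    for form, model in cfg.absorption.items():
        absorption[form] = {
            k: getattr(model, v) for k, v in _FORMULATION_KEYS.items()
        }
    physiology = {k: getattr(cfg.physiology, v) for k, v in _PHYSIOLOGY_KEYS.items()}
    physiology["tissue_volumes_L_kg"] = dict(cfg.physiology.tissue_volumes_l_kg)
    physiology["tissue_flow_fractions"] = dict(cfg.physiology.tissue_flow_fractions)
    physiology["induction"] = {
        f"{enzyme}_{site}": {"ga_weeks": list(grid), "multiplier": list(mult)}
        for (enzyme, site), (grid, mult) in cfg.induction.profiles.items()
    }
    trial = {k: getattr(cfg.trial, v) for k, v in _TRIAL_KEYS.items()}
    return {
        "drug": drug,
        "absorption": absorption,
        "physiology": physiology,
        "trial": trial,
        "seed": cfg.seed,
    }


def _from_mapping(data: dict) -> StudyConfig:
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in data:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")

    drug_kwargs = _map_block(data.get("drug", {}), _DRUG_KEYS, "drug", errors)

    absorption_block = dict(data.get("absorption", {}))
    shared = {}
    formulations = {}
    for key, value in absorption_block.items():
        if key in _ABSORPTION_SHARED_KEYS:
            shared[_ABSORPTION_SHARED_KEYS[key]] = value
        elif isinstance(value, dict):
            formulations[key] = _map_block(
                value, _FORMULATION_KEYS, f"absorption.{key}", errors
            )
        else:
            errors.append(f"absorption: unknown key {key!r}")

    phys_block = dict(data.get("physiology", {}))
    induction_block = phys_block.pop("induction", None)
    phys_kwargs = _map_block(phys_block, _PHYSIOLOGY_KEYS, "physiology", errors)
    trial_kwargs = _map_block(data.get("trial", {}), _TRIAL_KEYS, "trial", errors)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")

    def build(factory, kwargs, where):
        try:
            return factory(**kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}: {exc}")
            return None

    drug = build(DrugParameters, drug_kwargs, "drug")
    absorption = {}
    for form, kwargs in formulations.items():
        model = build(
            AbsorptionModel,
            {"formulation": form, **kwargs, **shared},
            f"absorption.{form}",
        )
        if model is not None:
            absorption[form] = model
    physiology = build(Physiology, phys_kwargs, "physiology")
    trial = build(TrialConfig, trial_kwargs, "trial")

    induction = default_induction()
    if induction_block is not None:
        profiles = {}
        for name, traj in induction_block.items():
            enzyme, _, site = name.rpartition("_")
            if not enzyme or site not in ("hepatic", "intestinal"):
                errors.append(
                    f"physiology.induction: key {name!r} must be "
                    "'<ENZYME>_hepatic' or '<ENZYME>_intestinal'"
                )
                continue
            try:
                profiles[(enzyme, site)] = (
                    tuple(float(x) for x in traj["ga_weeks"]),
                    tuple(float(x) for x in traj["multiplier"]),
                )
            except (KeyError, TypeError) as exc:
                errors.append(f"physiology.induction.{name}: {exc}")
        if not errors:
            induction = build(InductionModel, {"profiles": profiles}, "induction")

    if errors:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(sorted(errors))
        )
    return StudyConfig(
        drug=drug,
        absorption=absorption,
        physiology=physiology,
        induction=induction,
        trial=trial,
        seed=seed,
    )


def load_config(path) -> StudyConfig:
    """Read and fully validate a study configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return _from_mapping(data)


def save_config(cfg: StudyConfig, path) -> None:
    """Write the configuration; reading it back yields an equal StudyConfig."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_mapping(cfg), fh, sort_keys=True)
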