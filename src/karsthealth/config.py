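"""YAML configuration for scene parameters, weights and coefficient tables.

Keeps the tunable tables of the assessment (indicator weights and
directions, per-class coefficients, ecological levels, banded
rocky-desertification rules, scene parameters) in plain configuration files
rather than code.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .composite import WeightEntry, WeightScheme
from .indicators import CoefficientTable, RdsRule
from .lulc import EcoLevelTable
from .scene import SceneParams


def load_scene_params(path: str | Path) -> SceneParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "extent" in raw:
        raw["extent"] = tuple(raw["extent"])
    if "transition_regimes" in raw and raw["transition_regimes"] is not None:
        raw["transition_regimes"] = [np.asarray(m, dtype=float)
                                     for m in raw["transition_regimes"]]
    if "mining_belts" in raw and raw["mining_belts"] is not None:
        raw["mining_belts"] = [tuple(b) for b in raw["mining_belts"]]
    return SceneParams(**raw)


def save_scene_params(params: SceneParams, path: str | Path) -> None:
    raw = {
        "extent": list(params.extent),
        "cell_size_m": params.cell_size_m,
        "epochs": list(params.epochs),
        "n_urban_centers": params.n_urban_centers,
        "n_mines": params.n_mines,
        "transition_regimes": [m.tolist() for m in params.transition_regimes],
        "relief_amplitude_m": params.relief_amplitude_m,
        "carbonate_fraction": params.carbonate_fraction,
        "pop_growth": params.pop_growth,
        "gdp_growth": params.gdp_growth,
        "urban_boost": params.urban_boost,
        "urban_kernel_m": params.urban_kernel_m,
        "mining_belts": ([list(b) for b in params.mining_belts]
                         if params.mining_belts else None),
        "n_patch_nuclei": params.n_patch_nuclei,
        "class_mix": dict(params.class_mix),
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_weight_scheme(path: str | Path) -> WeightScheme:
    """Read a weight scheme from YAML: a list of
    {indicator, layer, direction, weight} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return WeightScheme([WeightEntry(**row) for row in raw])


def save_weight_scheme(scheme: WeightScheme, path: str | Path) -> None:
    rows = [{"indicator": e.indicator, "layer": e.layer,
             "direction": e.direction, "weight": e.weight}
            for e in scheme.entries]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def load_coefficient_table(path: str | Path) -> CoefficientTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CoefficientTable(purpose=raw["purpose"], coeff=raw["coeff"])


def load_eco_levels(path: str | Path) -> EcoLevelTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return EcoLevelTable(level=raw)


def load_rds_rule(path: str | Path) -> RdsRule:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RdsRule(**{k: tuple(v) for k, v in raw.items()})
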