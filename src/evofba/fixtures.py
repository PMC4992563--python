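"""Packaged models, substrate aliases, configuration files and presets."""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy import sparse

from .experiment import SimulationConfig
from .model import StoichiometricModel, load_model

__all__ = [
    "make_toy_model",
    "load_ancestor_model",
    "get_model",
    "alias_resolver",
    "load_config",
    "scale_preset",
    "ALIASES",
]

#: Common substrate names -> exchange reaction ids, per model id.
ALIASES: dict[str, dict[str, str]] = {
    "e_coli_core": {
        "acetate": "EX_ac_e",
        "acetaldehyde": "EX_acald_e",
        "alpha_ketoglutarate": "EX_akg_e",
        "ethanol": "EX_etoh_e",
        "formate": "EX_for_e",
        "fructose": "EX_fru_e",
        "fumarate": "EX_fum_e",
        "glucose": "EX_glc__D_e",
        "glutamine": "EX_gln__L_e",
        "glutamate": "EX_glu__L_e",
        "lactate": "EX_lac__D_e",
        "malate": "EX_mal__L_e",
        "oxygen": "EX_o2_e",
        "pyruvate": "EX_pyr_e",
        "succinate": "EX_succ_e",
    },
    "toy_overflow": {
        "glucose": "EX_glc",
        "acetate": "EX_ac",
        "oxygen": "EX_o2",
    },
}


def alias_resolver(model: StoichiometricModel) -> Callable[[str], str]:
    """Return a function mapping common names or exact ids to exchange ids."""
    table = ALIASES.get(model.model_id, {})
    known = set(model.reactions)

    def resolve(name: str) -> str:
        if name in table:
            return table[name]
        if name in known:
            return name
        raise KeyError(
            f"unknown substrate {name!r} for model {model.model_id!r}; "
            f"use an exchange id or one of {sorted(table)}"
        )

    return resolve


def make_toy_model() -> StoichiometricModel:
    """A four-metabolite overflow-metabolism model, tractable by hand.

    Metabolites: glucose (glc), acetate (ac), oxygen (o2) and a biomass
    precursor (prec).  Internal reactions:

    * ``RESP``    glc + o2 -> 3 prec      (efficient respiration)
    * ``OVER``    glc -> prec + ac        (overflow: partial oxidation)
    * ``ACRESP``  ac + o2 -> 0.8 prec     (acetate respiration)
    * ``BIOMASS`` 100 prec -> growth      (yield 0.01 per precursor)

    plus exchanges for glc, ac, o2 and prec (the precursor exchange is
    secretion-only and never carries flux at a parsimonious optimum).
    Respiration yields strictly more precursor per glucose (3) than the
    overflow + acetate-respiration route (1.8), so the parsimonious
    optimum is unique for generic uptake caps.  Carbon contents (glc 6,
    ac 2, prec 2, biomass 200 per unit growth flux) support closed carbon
    accounting in tests.
    """
    metabolites = ["glc", "ac", "o2", "prec"]
    reactions = ["RESP", "OVER", "ACRESP", "BIOMASS", "EX_glc", "EX_ac", "EX_o2", "EX_prec"]
    S = np.zeros((4, 8))
    # RESP: glc + o2 -> 3 prec
    S[0, 0], S[2, 0], S[3, 0] = -1.0, -1.0, 3.0
    # OVER: glc -> prec + ac
    S[0, 1], S[3, 1], S[1, 1] = -1.0, 1.0, 1.0
    # ACRESP: ac + o2 -> 0.8 prec
    S[1, 2], S[2, 2], S[3, 2] = -1.0, -1.0, 0.8
    # BIOMASS: 100 prec ->
    S[3, 3] = -100.0
    # exchanges (toolchain convention: A_external <- nothing, coef -1)
    S[0, 4] = -1.0
    S[1, 5] = -1.0
    S[2, 6] = -1.0
    S[3, 7] = -1.0
    lb = np.zeros(8)
    ub = np.full(8, 1000.0)
    return StoichiometricModel(
        model_id="toy_overflow",
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=sparse.csc_matrix(S),
        lower_bounds=lb,
        upper_bounds=ub,
        exchange_reactions=["EX_glc", "EX_ac", "EX_o2", "EX_prec"],
        biomass_reaction="BIOMASS",
        unlimited_exchanges=frozenset(),
        carbon_content={"glc": 6.0, "ac": 2.0, "prec": 2.0, "o2": 0.0},
        default_mutable_exchanges=["EX_glc", "EX_ac", "EX_o2"],
    )


def ancestor_model_path() -> Path:
    return Path(importlib.resources.files("evofba").joinpath("data/e_coli_core.json"))


def load_ancestor_model() -> StoichiometricModel:
    """The packaged E. coli core reconstruction (95 reactions, 20 exchanges)."""
    model = load_model(ancestor_model_path(), format="json")
    model.model_id = "e_coli_core"
    return model


def get_model(name_or_path: str) -> StoichiometricModel:
    """Resolve a model by fixture name (``ecoli_core``, ``toy``) or file path."""
    if name_or_path in {"ecoli_core", "e_coli_core", "core"}:
        return load_ancestor_model()
    if name_or_path in {"toy", "toy_overflow"}:
        return make_toy_model()
    return load_model(name_or_path)


class ConfigError(ValueError):
    """A configuration file is malformed or violates an invariant."""


def read_config_dict(path: str | Path) -> dict:
    """Parse a YAML/JSON config file into a validated field dict."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml", ""} else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse {path.name}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path.name}: expected a mapping at the top level")
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"{path.name}: unknown config fields {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML/JSON configuration, filling defaults for absent fields."""
    config = SimulationConfig(**read_config_dict(path))
    try:
        config.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return config


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


#: Named scale presets.  ``paper`` is the full-scale protocol;
#: ``desk`` shrinks the reactor 100-fold for an hours-scale run;
#: ``smoke`` exercises the whole pipeline on the toy model in seconds.
_PRESETS: dict[str, dict] = {
    "paper": {},
    "desk": {"volume": 1e-4, "cycles": 150, "founding_cells": 10_000},
    "smoke": {
        "model": "toy",
        "volume": 1e-6,
        "cycles": 10,
        "dt_min": 5.0,
        "founding_cells": 100,
        "mutation_rate": 1e-3,
    },
}


def scale_preset(name: str) -> dict:
    """Configuration overrides for a named scale preset."""
    try:
        return dict(_PRESETS[name])
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; known presets: {sorted(_PRESETS)}"
        ) from None


def preset_config(name: str, **overrides) -> SimulationConfig:
    merged = {**scale_preset(name), **overrides}
    config = SimulationConfig(**merged)
    config.validate()
    return config
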