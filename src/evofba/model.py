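"""Stoichiometric model container and loaders.

A :class:`StoichiometricModel` is the fixed metabolic "chassis" shared by
every genotype in a simulation: the stoichiometric matrix, default flux
bounds, the biomass objective and the set of exchange (boundary) reactions.
Genotypes differ only in their maximum uptake rates over a subset of the
exchanges; the chassis itself never mutates.

Parsing of standard formats (SBML Level 3 + FBC, and the JSON dialect used
by constraint-based toolchains) is delegated to COBRApy.  Whatever the
on-disk convention, the loader produces one fixed internal convention:
fluxes follow the toolchain sign (negative exchange flux = uptake) and the
simulator-facing uptake-positive view is produced in exactly one place, the
solver's exchange-flux adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "StoichiometricModel",
    "ModelFormatError",
    "ModelConfigError",
    "load_model",
    "from_cobra",
    "DEFAULT_UNLIMITED_EXCHANGES",
]

#: Exchanges that carry no uptake limit in the serial-transfer medium:
#: phosphate, ammonia, water, protons and CO2 are never growth-limiting.
DEFAULT_UNLIMITED_EXCHANGES = frozenset(
    {"EX_pi_e", "EX_nh4_e", "EX_h2o_e", "EX_h_e", "EX_co2_e"}
)

#: Magnitude used for "unbounded" fluxes.
BIG_BOUND = 1000.0


class ModelFormatError(ValueError):
    """The file could not be parsed under the named standard."""


class ModelConfigError(ValueError):
    """The model parsed but is unusable (e.g. no biomass objective)."""


@dataclass
class StoichiometricModel:
    """An immutable constraint-based metabolic model.

    Attributes
    ----------
    model_id:
        Identifier of the model (e.g. ``"e_coli_core"``).
    metabolites, reactions:
        Ordered identifier lists; rows and columns of ``stoichiometry``.
    stoichiometry:
        Sparse metabolites x reactions coefficient matrix.
    lower_bounds, upper_bounds:
        Default per-reaction flux bounds in mmol/gDW/h (biomass in 1/h),
        in the toolchain sign convention (negative exchange flux = uptake).
    exchange_reactions:
        Reactions crossing the system boundary (single nonzero coefficient).
    biomass_reaction:
        Reaction whose flux is the growth rate (1/h).
    unlimited_exchanges:
        Exchanges left unbounded in both directions.
    carbon_content:
        Optional metabolite -> carbon-atom count map, used for carbon
        accounting on fixtures where biomass composition is defined.
    """

    model_id: str
    metabolites: list[str]
    reactions: list[str]
    stoichiometry: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    exchange_reactions: list[str]
    biomass_reaction: str
    unlimited_exchanges: frozenset[str] = frozenset()
    carbon_content: dict[str, float] | None = None
    #: exchanges open to mutation by default (None: all limited exchanges)
    default_mutable_exchanges: list[str] | None = None
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def mutable_exchanges(self) -> list[str]:
        if self.default_mutable_exchanges is not None:
            return list(self.default_mutable_exchanges)
        return [ex for ex in self.exchange_reactions if ex not in self.unlimited_exchanges]

    def __post_init__(self) -> None:
        self._rxn_index = {r: j for j, r in enumerate(self.reactions)}
        self.validate()

    # -- introspection -------------------------------------------------
    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def exchanged_metabolite(self, exchange_id: str) -> str:
        """The single metabolite moved by an exchange reaction."""
        j = self.reaction_index(exchange_id)
        col = self.stoichiometry.getcol(j).tocoo()
        if col.nnz != 1:
            raise ValueError(f"{exchange_id!r} is not an exchange reaction")
        return self.metabolites[int(col.row[0])]

    def validate(self) -> None:
        nm, nr = self.stoichiometry.shape
        if nr != len(self.reactions) or nm != len(self.metabolites):
            raise ModelConfigError(
                f"stoichiometry shape {self.stoichiometry.shape} does not match "
                f"{len(self.metabolites)} metabolites x {len(self.reactions)} reactions"
            )
        if self.biomass_reaction not in self._rxn_index:
            raise ModelConfigError(
                f"biomass reaction {self.biomass_reaction!r} is not in the model"
            )
        missing = [r for r in self.exchange_reactions if r not in self._rxn_index]
        if missing:
            raise ModelConfigError(f"exchange reactions not in model: {missing}")
        if not self.unlimited_exchanges <= set(self.exchange_reactions):
            extra = self.unlimited_exchanges - set(self.exchange_reactions)
            raise ModelConfigError(f"unlimited exchanges are not exchanges: {sorted(extra)}")
        if len(self.lower_bounds) != nr or len(self.upper_bounds) != nr:
            raise ModelConfigError("bound vectors do not match reaction count")


def _detect_exchanges(S: sparse.csc_matrix, reactions: list[str]) -> list[str]:
    """Boundary reactions: exactly one nonzero stoichiometric coefficient."""
    nnz_per_col = np.diff(S.indptr)
    return [reactions[j] for j in np.nonzero(nnz_per_col == 1)[0]]


def from_cobra(
    cobra_model,
    model_id: str | None = None,
    unlimited: Iterable[str] | None = None,
    carbon_content: Mapping[str, float] | None = None,
) -> StoichiometricModel:
    """Convert a ``cobra.Model`` to a :class:`StoichiometricModel`.

    Exchange bounds are normalised: uptake is forbidden by default (lower
    bound 0) so that all uptake capacity comes from the per-step kinetic
    caps, except for the unlimited exchanges which are free in both
    directions.  Internal reaction bounds (including maintenance fluxes)
    are taken from the model as published.
    """
    from cobra.util.array import create_stoichiometric_matrix

    S = sparse.csc_matrix(create_stoichiometric_matrix(cobra_model, array_type="lil"))
    reactions = [r.id for r in cobra_model.reactions]
    metabolites = [m.id for m in cobra_model.metabolites]
    lb = np.array([float(r.lower_bound) for r in cobra_model.reactions])
    ub = np.array([float(r.upper_bound) for r in cobra_model.reactions])

    biomass = [r.id for r in cobra_model.reactions if r.objective_coefficient]
    if len(biomass) != 1:
        raise ModelConfigError(
            f"expected exactly one biomass (objective) reaction, found {biomass!r}"
        )

    exchange = _detect_exchanges(S, reactions)
    if unlimited is None:
        unlimited_set = frozenset(DEFAULT_UNLIMITED_EXCHANGES) & set(exchange)
    else:
        unlimited_set = frozenset(unlimited)

    rxn_index = {r: j for j, r in enumerate(reactions)}
    for ex in exchange:
        j = rxn_index[ex]
        if ex in unlimited_set:
            lb[j], ub[j] = -BIG_BOUND, BIG_BOUND
        else:
            lb[j] = 0.0  # uptake only through explicit kinetic caps
            ub[j] = max(ub[j], BIG_BOUND)  # secretion unconstrained

    return StoichiometricModel(
        model_id=model_id or cobra_model.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        exchange_reactions=exchange,
        biomass_reaction=biomass[0],
        unlimited_exchanges=unlimited_set,
        carbon_content=dict(carbon_content) if carbon_content else None,
    )


def load_model(
    path: str | Path,
    format: str | None = None,
    unlimited: Iterable[str] | None = None,
) -> StoichiometricModel:
    """Load an SBML (Level 3 + FBC) or constraint-based JSON model file.

    Parameters
    ----------
    path:
        Model file.  If ``format`` is omitted it is inferred from the
        suffix (``.xml``/``.sbml`` -> sbml, ``.json`` -> json).
    unlimited:
        Exchange ids with no uptake limit; defaults to the phosphate /
        ammonia / water / proton / CO2 exchanges when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {"xml": "sbml", "sbml": "sbml", "json": "json"}.get(
            path.suffix.lstrip(".").lower(), ""
        )
    if format not in {"sbml", "json"}:
        raise ModelFormatError(f"unknown model format for {path.name!r}; use sbml or json")

    import cobra.io

    try:
        if format == "sbml":
            cobra_model = cobra.io.read_sbml_model(str(path))
        else:
            cobra_model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"could not parse {path.name} as {format}: {exc}") from exc
    return from_cobra(cobra_model, unlimited=unlimited)
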