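"""Applying allometric models: stem-level prediction, plot totals, upscaling.

Palm AGB comes from a log-linear allometric model with its correction
factor; hardwood tree AGB from the pantropical moist-forest equation
AGB = 0.0673 (rho D^2 H)^0.976 (rho in g cm^-3, D in cm, H in m, AGB in
kg). Plot totals are reported per hectare with and without palms, and a
per-hectare carbon density times a mapped regional area gives the
regional carbon stock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_model_io import AllometricModel, PlotInventory
from .errors import DomainError

log = logging.getLogger(__name__)

#: default fraction of dry biomass that is carbon
DEFAULT_CARBON_FRACTION = 0.47


def predict_palm_agb(model: AllometricModel, predictors: Mapping[str, float]) -> float:
    """Predict one palm's AGB in kg: CF * exp(a + sum(slope * ln(P))).

    Every predictor the model uses must be supplied and strictly positive.
    """
    total = model.intercept
    for name, slope in zip(model.predictors, model.slopes):
        if name not in predictors:
            raise DomainError(f"model {model.model_id} requires predictor {name!r}")
        value = predictors[name]
        if value is None or value <= 0:
            raise DomainError(f"predictor {name!r} must be > 0, got {value}")
        total += slope * np.log(value)
    return float(model.CF * np.exp(total))


def chave_tree_agb(wood_density: float, D: float, H: float) -> float:
    """Pantropical moist-forest tree AGB (kg): 0.0673 (rho D^2 H)^0.976."""
    if wood_density <= 0 or H <= 0:
        raise DomainError("wood density and height must be > 0")
    if D < 10:
        raise DomainError(f"tree D must be >= 10 cm, got {D}")
    return 0.0673 * (wood_density * D**2 * H) ** 0.976


@dataclass
class PlotResult:
    """Per-hectare AGB totals of one plot, with the palm share broken out.

    ``exclusion_difference_pct`` is the percent increase of the full total
    over the tree-only total, i.e. 100 * palm / tree.
    """

    plot_id: str
    tree_agb_kg: float
    palm_agb_kg: float
    total_kg: float
    palm_contribution_pct: float
    exclusion_difference_pct: float
    n_trees: int
    n_palms: int


def plot_totals(
    inventory: PlotInventory,
    palm_model: AllometricModel,
    include_palms: bool = True,
) -> PlotResult:
    """Per-hectare AGB totals for one plot inventory.

    Palms whose supplied predictors fall below the model's fitted subset
    (small individuals under an Npf-only >=5 cm model, say) are still
    predicted, with a logged extrapolation note, since the published
    application used the model plot-wide.
    """
    inventory.validate()
    tree_total = sum(chave_tree_agb(t.wood_density, t.D, t.H) for t in inventory.trees)

    palm_total = 0.0
    if include_palms:
        missing: list[str] = []
        for p in inventory.palms:
            values = {"Npf": p.Npf, "SDp": p.SDp, "H": p.H, "TD": p.TD}
            lacking = [
                name for name in palm_model.predictors
                if values.get(name) is None
            ]
            if lacking:
                missing.append(p.palm_id)
                continue
            palm_total += predict_palm_agb(palm_model, values)
        if missing:
            raise DomainError(
                f"palms missing predictors {palm_model.predictors} for model "
                f"{palm_model.model_id}: {', '.join(missing)}"
            )
        if inventory.palms and palm_model.subset.startswith("5"):
            small = sum(1 for p in inventory.palms if p.Npf is not None and p.Npf < 3)
            if small:
                log.info("%d palm(s) below the %s fitted range (extrapolated)",
                         small, palm_model.subset)

    area = inventory.area_ha
    tree_ha, palm_ha = tree_total / area, palm_total / area
    total = tree_ha + palm_ha
    contribution = 100.0 * palm_ha / total if total > 0 else 0.0
    exclusion = 100.0 * palm_ha / tree_ha if tree_ha > 0 else 0.0
    return PlotResult(
        plot_id=inventory.plot_id,
        tree_agb_kg=tree_ha,
        palm_agb_kg=palm_ha,
        total_kg=total,
        palm_contribution_pct=contribution,
        exclusion_difference_pct=exclusion,
        n_trees=len(inventory.trees),
        n_palms=len(inventory.palms) if include_palms else 0,
    )


def agb_to_carbon(agb_kg: float, carbon_fraction: float = DEFAULT_CARBON_FRACTION) -> float:
    """Convert dry biomass to carbon mass (kg C) with a carbon fraction."""
    if not 0 < carbon_fraction < 1:
        raise DomainError(f"carbon fraction must be in (0, 1), got {carbon_fraction}")
    return agb_kg * carbon_fraction


def upscale_regional_carbon(carbon_density_mg_ha: float, area_km2: float) -> float:
    """Regional carbon stock in Pg C from Mg C ha^-1 and mapped km^2.

    1 km^2 = 100 ha; 1 Pg = 1e9 Mg.
    """
    if carbon_density_mg_ha <= 0 or area_km2 <= 0:
        raise DomainError("carbon density and area must be > 0")
    return carbon_density_mg_ha * area_km2 * 100.0 / 1e9
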