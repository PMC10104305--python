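"""Synthetic destructive-sampling datasets and plot inventories.

The field campaign this package models was a stratified destructive
sample: six mean-petiole-diameter classes (2-4, >4-5, >5-6, >6-7, >7-8,
>8 cm), fifteen palms per class, ninety in total. No raw data were
deposited, so this module generates datasets with the same statistical
structure: petiole diameters drawn around a class-stratified mean, frond
count and stem diameter increasing with palm size, height linked
log-linearly to the summed petiole diameter, tissue density varying
mildly around 0.24 g cm^-3, and AGB generated from a true log-linear
allometric model with multiplicative log-normal error. Component masses
follow a Dirichlet split whose mean shares mirror the published
partitioning (stem 14.8%, sheath 13.8%, petiole 30.2%, rachis 16.0%,
leaflet 25.2%).

Every draw flows from an explicit integer seed; identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model_io import (
    COMPONENTS,
    AllometricModel,
    ComponentSample,
    Palm,
    PalmRecord,
    PlotInventory,
    Tree,
    get_model,
)
from .errors import ConfigError

#: the six stratified sampling classes; the open top class ">8 cm" is
#: closed at 12.6 cm, just above the largest mean petiole diameter observed
DEFAULT_CLASS_BOUNDS = ((2.0, 4.0), (4.0, 5.0), (5.0, 6.0), (6.0, 7.0),
                        (7.0, 8.0), (8.0, 12.6))

DEFAULT_PARTITION_MEANS = {
    "stem": 0.1483, "sheath": 0.1383, "petiole": 0.3017,
    "rachis": 0.1600, "leaflet": 0.2517,
}

DEFAULT_RATIO_MEANS = {
    "stem": 0.22, "sheath": 0.30, "petiole": 0.42, "rachis": 0.48,
    "leaflet": 0.45,
}

#: component tissue-density offsets from the palm-level mean (g cm^-3);
#: they average to zero so the per-palm mean density is preserved
_TD_OFFSETS = {"stem": -0.03, "sheath": 0.02, "petiole": -0.03, "rachis": 0.04}

_H_RANGE = (5.13, 21.20)
_TD_RANGE = (0.15, 0.38)
_D_RANGE = (8.2, 35.4)
_NPF_RANGE = (3, 11)


@dataclass
class SimConfig:
    """Generative parameters for a synthetic destructive sample."""

    class_bounds: tuple[tuple[float, float], ...] = DEFAULT_CLASS_BOUNDS
    n_per_class: int = 15
    true_model: AllometricModel | None = None  # defaults to published m11
    sigma_log: float = 0.18
    partition_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION_MEANS))
    partition_concentration: float = 100.0
    ratio_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_MEANS))
    petiole_cv: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.partition_means.values()) - 1.0) > 1e-9:
            raise ConfigError("partition means must sum to 1")
        if self.sigma_log < 0:
            raise ConfigError("sigma_log must be >= 0")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        prev_hi = -np.inf
        for lo, hi in self.class_bounds:
            if not lo < hi or lo < prev_hi:
                raise ConfigError("class bounds must be ordered and non-overlapping")
            prev_hi = hi
        for comp, r in self.ratio_means.items():
            if not 0 < r <= 1:
                raise ConfigError(f"ratio mean for {comp} outside (0, 1]")

    def resolved_model(self) -> AllometricModel:
        return self.true_model if self.true_model is not None else get_model("m11")


def _class_label(lo: float, hi: float, top: bool) -> str:
    return f">{lo:g} cm" if top else f"{lo:g}-{hi:g} cm"


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo, hi))


def simulate_palm_dataset(
    config: SimConfig | None = None,
) -> tuple[list[PalmRecord], list[ComponentSample]]:
    """Generate one stratified destructive sample plus its lab-sample table.

    Returns records (n_per_class palms per petiole-diameter class) and the
    per-palm component samples (3 stem discs, 3 fronds x 5 pieces, 1
    leaflet bulk sample = 19 rows per palm).
    """
    config = config or SimConfig()
    config.validate()
    model = config.resolved_model()
    rng = np.random.default_rng(config.seed)

    records: list[PalmRecord] = []
    samples: list[ComponentSample] = []
    alpha = np.array(
        [config.partition_means[c] for c in COMPONENTS]) * config.partition_concentration

    idx = 0
    for ci, (lo, hi) in enumerate(config.class_bounds):
        top = ci == len(config.class_bounds) - 1
        label = _class_label(lo, hi, top)
        for _ in range(config.n_per_class):
            idx += 1
            palm_id = f"SYN{idx:03d}"
            target_mdp = rng.uniform(lo, hi)
            npf = int(np.clip(round(1.5 + 0.7 * target_mdp + rng.normal(0, 1.0)),
                              *_NPF_RANGE))
            diams = rng.normal(target_mdp, config.petiole_cv * target_mdp, size=npf)
            diams = np.clip(diams, 0.5, None)
            sdp = float(diams.sum())
            mdp = sdp / npf  # exact, so the stored fields stay consistent
            d_stem = float(np.clip(3.5 * mdp + rng.normal(0, 2.0), *_D_RANGE))
            h = float(np.clip(
                np.exp(0.956 + 0.45 * np.log(sdp) + rng.normal(0, 0.18)), *_H_RANGE))
            td = _truncated_normal(rng, 0.24, 0.036, *_TD_RANGE)

            values = {"SDp": sdp, "D": d_stem, "MDp": mdp, "H": h,
                      "Npf": npf, "TD": td}
            ln_agb = model.intercept + sum(
                s * np.log(values[p]) for s, p in zip(model.slopes, model.predictors)
            )
            if config.sigma_log > 0:
                ln_agb += rng.normal(0, config.sigma_log)
            agb = float(np.exp(ln_agb))

            fractions = rng.dirichlet(alpha)
            comp_kg = {c: float(f * agb) for c, f in zip(COMPONENTS, fractions)}
            records.append(
                PalmRecord(
                    palm_id=palm_id, class_label=label, D=d_stem, MDp=mdp,
                    SDp=sdp, H=h, Npf=npf, TD=td,
                    stem_kg=comp_kg["stem"], sheath_kg=comp_kg["sheath"],
                    petiole_kg=comp_kg["petiole"], rachis_kg=comp_kg["rachis"],
                    leaflet_kg=comp_kg["leaflet"],
                    agb_kg=sum(comp_kg.values()),
                )
            )
            samples.extend(_lab_samples(rng, palm_id, td, config.ratio_means))
    for rec in records:
        rec.validate()
    for s in samples:
        s.validate()
    return records, samples


def _lab_samples(rng, palm_id: str, palm_td: float, ratio_means) -> list[ComponentSample]:
    """19 lab samples for one palm: 3 stem discs, 3x5 frond pieces, 1 leaflet."""
    plan = [("stem", 3)] + [(c, 3) for c in ("sheath", "petiole")] + [("rachis", 9)]
    out: list[ComponentSample] = []
    for comp, count in plan:
        dens_c = float(np.clip(
            palm_td + _TD_OFFSETS[comp] + rng.normal(0, 0.008), 0.12, 0.40))
        for _ in range(count):
            dry = rng.uniform(50.0, 600.0)
            ratio = _truncated_normal(rng, ratio_means[comp], 0.03, 0.05, 0.95)
            out.append(ComponentSample(palm_id, comp, dry / ratio, dry, dry / dens_c))
    dry = rng.uniform(180.0, 400.0)
    ratio = _truncated_normal(rng, ratio_means["leaflet"], 0.03, 0.05, 0.95)
    out.append(ComponentSample(palm_id, "leaflet", dry / ratio, dry, None))
    return out


def simulate_plot_inventory(
    n_trees: int,
    n_palms: int,
    seed: int = 0,
    plot_id: str = "SYN-PLOT",
    area_ha: float = 1.0,
) -> PlotInventory:
    """A synthetic 1-ha stem inventory: trees with D >= 10 cm, Npf-only palms."""
    if n_trees < 0 or n_palms < 0:
        raise ConfigError("stem counts must be >= 0")
    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n_trees):
        d = float(np.clip(10.0 + rng.exponential(15.0), 10.0, 150.0))
        wd = float(rng.uniform(0.25, 0.85))
        h = float(np.clip(np.exp(0.6 + 0.65 * np.log(d) + rng.normal(0, 0.15)),
                          5.0, 50.0))
        trees.append(Tree(f"T{i + 1:03d}", d, wd, h))
    palms = [
        Palm(f"P{i + 1:03d}", Npf=int(rng.integers(_NPF_RANGE[0], _NPF_RANGE[1] + 1)))
        for i in range(n_palms)
    ]
    inv = PlotInventory(plot_id=plot_id, area_ha=area_ha, trees=trees, palms=palms)
    inv.validate()
    return inv


def replicate_configs(base: SimConfig, seeds: Sequence[int]) -> list[SimConfig]:
    """The same generative conditions under a sequence of seeds."""
    return [replace(base, seed=int(s)) for s in seeds]
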