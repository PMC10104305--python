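"""Tissue properties, dry-mass conversion, AGB partitioning and rank tests.

Lab samples give each component's tissue density (oven-dry mass over
displaced volume, g cm^-3) and dry/fresh mass ratio; the ratios convert
field fresh masses to dry mass, which summed over the five components
(stem, sheath, petiole, rachis, leaflet) gives each palm's aboveground
biomass. Partitioning summaries and the nonparametric group comparisons
(Kruskal-Wallis, Dunn's post hoc) live here too.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import COMPONENTS, FROND_COMPONENTS, ComponentSample, PalmRecord
from .errors import DomainError, InvariantError

log = logging.getLogger(__name__)

#: components with a hydrostatic volume, hence a tissue density
DENSITY_COMPONENTS = ("stem", "sheath", "petiole", "rachis")


def tissue_density(dry_g: float, volume_cm3: float) -> float:
    """Tissue density in g cm^-3: oven-dry mass divided by displaced volume."""
    if volume_cm3 <= 0:
        raise DomainError(f"volume must be > 0, got {volume_cm3}")
    return dry_g / volume_cm3


def dry_fresh_ratio(dry_g: float, fresh_g: float) -> float:
    """Dry/fresh mass fraction in (0, 1]; dry > fresh signals mislabeled masses."""
    if fresh_g <= 0:
        raise DomainError(f"fresh mass must be > 0, got {fresh_g}")
    if dry_g > fresh_g:
        raise InvariantError(f"dry mass {dry_g} g exceeds fresh mass {fresh_g} g")
    return dry_g / fresh_g


def convert_fresh_to_dry(fresh_kg: float, mean_ratio: float) -> float:
    """Convert a field fresh mass to dry mass with a component mean ratio."""
    if not 0 < mean_ratio <= 1:
        raise DomainError(f"dry/fresh ratio must be in (0, 1], got {mean_ratio}")
    return fresh_kg * mean_ratio


def assemble_palm_agb(
    stem_kg: float, sheath_kg: float, petiole_kg: float,
    rachis_kg: float, leaflet_kg: float,
) -> tuple[float, float]:
    """Total AGB and frond (non-stem) AGB from the five component dry masses."""
    parts = (stem_kg, sheath_kg, petiole_kg, rachis_kg, leaflet_kg)
    if any(m < 0 for m in parts):
        raise DomainError(f"component masses must be >= 0, got {parts}")
    total = sum(parts)
    return total, total - stem_kg


def individual_tissue_density(component_densities: dict[str, float]) -> float:
    """Per-palm TD: the equally weighted mean of the four component densities.

    Leaflets have no volume and contribute no density. Equal weighting is
    used because the published overall TD mean equals the plain mean of
    the component means.
    """
    vals = [component_densities[c] for c in DENSITY_COMPONENTS if c in component_densities]
    if not vals:
        raise DomainError("no component densities supplied")
    return float(np.mean(vals))


@dataclass
class TissueSummary:
    """Per-component mean/SD of tissue density and dry/fresh ratio."""

    component: str
    mean_TD: float | None
    sd_TD: float | None
    mean_ratio: float
    sd_ratio: float
    n: int


@dataclass
class PartitionSummary:
    """Mean per-individual share of AGB in each component for one class.

    ``fractions`` sum to 1; ``frond_fraction`` is the non-stem share.
    """

    class_label: str
    fractions: dict[str, float]
    frond_fraction: float
    n: int


def summarise_tissue(samples: Iterable[ComponentSample]) -> list[TissueSummary]:
    """Component-level tissue density and dry/fresh-ratio summaries."""
    df = pd.DataFrame(
        [(s.component, s.dry_g, s.fresh_g, s.volume_cm3) for s in samples],
        columns=["component", "dry_g", "fresh_g", "volume_cm3"],
    )
    out = []
    for comp in COMPONENTS:
        sub = df[df["component"] == comp]
        if sub.empty:
            continue
        ratios = sub["dry_g"] / sub["fresh_g"]
        if comp in DENSITY_COMPONENTS:
            dens = sub["dry_g"] / sub["volume_cm3"]
            mean_td, sd_td = float(dens.mean()), float(dens.std(ddof=1))
        else:
            mean_td = sd_td = None
        out.append(
            TissueSummary(comp, mean_td, sd_td, float(ratios.mean()),
                          float(ratios.std(ddof=1)), len(sub))
        )
    return out


def partition_fractions(
    palms: Sequence[PalmRecord], by_class: bool = False
) -> list[PartitionSummary]:
    """Mean component shares of AGB, pooled or per petiole-diameter class.

    Shares are means of per-individual fractions (individual-first), not
    ratios of mean masses — small and large palms weigh equally.
    """
    if not palms:
        raise DomainError("no palms supplied")
    usable = []
    for p in palms:
        if p.agb_kg == 0:
            log.warning("palm %s has zero AGB; excluded from partitioning", p.palm_id)
            continue
        usable.append(p)
    if not usable:
        raise DomainError("all palms have zero AGB")

    def summary(label: str, group: Sequence[PalmRecord]) -> PartitionSummary:
        fracs = {
            c: float(np.mean([p.component_masses()[c] / p.agb_kg for p in group]))
            for c in COMPONENTS
        }
        total = sum(fracs.values())
        fracs = {c: v / total for c, v in fracs.items()}  # guard rounding drift
        return PartitionSummary(
            class_label=label,
            fractions=fracs,
            frond_fraction=sum(fracs[c] for c in FROND_COMPONENTS),
            n=len(group),
        )

    if not by_class:
        return [summary("all", usable)]
    labels = sorted({p.class_label for p in usable})
    return [summary(lb, [p for p in usable if p.class_label == lb]) for lb in labels]


# ---------------------------------------------------------------------------
# nonparametric group comparisons


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p value.

    All-tied input returns H = 0, p = 1 (no rank variation) rather than
    the 0/0 the raw formula would give.
    """
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise DomainError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


_ADJUSTMENTS = ("none", "bonferroni", "sidak")


def dunn_test(
    groups: Sequence[Sequence[float]], adjustment: str = "none"
) -> pd.DataFrame:
    """Dunn's post hoc rank comparison for every pair of groups.

    z = (mean-rank difference) / sqrt((N(N+1)/12 - tie term)(1/ni + 1/nj))
    with the tie term sum(t^3 - t)/(12(N-1)); p values are two-sided and
    optionally multiplicity-adjusted ("bonferroni" or "sidak").
    """
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    if adjustment not in _ADJUSTMENTS:
        raise DomainError(f"unknown adjustment {adjustment!r}; use one of {_ADJUSTMENTS}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        denom = math.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * stats.norm.sf(abs(z))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * n_pairs)
        elif adjustment == "sidak":
            p_adj = 1.0 - (1.0 - p) ** n_pairs
        else:
            p_adj = p
        rows.append((i, j, z, p, p_adj))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p", "p_adj"])
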