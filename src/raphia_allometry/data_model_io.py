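"""Domain records and CSV input/output.

Tables are UTF-8 comma-separated CSV with a mandatory header and "."
decimal mark. Numeric columns carry unit suffixes (``D_cm``, ``H_m``,
``TD_g_cm3`` ...) so that a file in the wrong units cannot be read
silently. Four schemas are used:

``palms.csv``
    one destructively sampled individual per row (:class:`PalmRecord`);
``samples.csv``
    one lab sample per row (:class:`ComponentSample`);
``inventory.csv``
    one stem per row, trees and palms mixed, distinguished by a ``kind``
    column (:class:`PlotInventory`);
``published_models.csv``
    the packaged coefficient fixture with the 22 published allometric
    models (:class:`AllometricModel`).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    IntegrityError,
    InvariantError,
    ModelNotFoundError,
    ParseError,
    SchemaError,
)

log = logging.getLogger(__name__)

COMPONENTS = ("stem", "sheath", "petiole", "rachis", "leaflet")
FROND_COMPONENTS = ("sheath", "petiole", "rachis", "leaflet")
PREDICTOR_NAMES = ("SDp", "D", "MDp", "H", "Npf", "TD")

#: the published symbol "TDp" (total petiole diameter) is the same quantity
#: as SDp (sum of petiole diameters); SDp is canonical everywhere.
PREDICTOR_ALIASES = {"TDp": "SDp", "MDf": "MDp"}

_MASS_TOL = 1e-9
_MDP_TOL = 1e-6

_FIXTURE_NAME = "published_models.csv"
_FIXTURE_SHA256 = "05244d9d71545df2c55ad9db29fb66c60f1d945ad7db3c925c4291271403f687"


# ---------------------------------------------------------------------------
# domain records


@dataclass
class PalmRecord:
    """One destructively sampled palm: predictors plus component dry masses.

    Units: diameters in cm, height in m, tissue density in g cm^-3,
    masses in kg. ``agb_kg`` must equal the sum of the five component
    masses; ``Npf`` is the live frond count (every sampled palm had at
    least three fronds).
    """

    palm_id: str
    class_label: str
    D: float
    MDp: float
    SDp: float
    H: float
    Npf: int
    TD: float
    stem_kg: float
    sheath_kg: float
    petiole_kg: float
    rachis_kg: float
    leaflet_kg: float
    agb_kg: float

    def component_masses(self) -> dict[str, float]:
        return {
            "stem": self.stem_kg,
            "sheath": self.sheath_kg,
            "petiole": self.petiole_kg,
            "rachis": self.rachis_kg,
            "leaflet": self.leaflet_kg,
        }

    def predictor(self, name: str) -> float:
        name = PREDICTOR_ALIASES.get(name, name)
        if name not in PREDICTOR_NAMES:
            raise KeyError(name)
        return float(getattr(self, name))

    def validate(self) -> None:
        masses = self.component_masses()
        if any(m < 0 for m in masses.values()) or self.agb_kg < 0:
            raise InvariantError(f"palm {self.palm_id}: negative mass")
        if abs(sum(masses.values()) - self.agb_kg) > _MASS_TOL:
            raise InvariantError(
                f"palm {self.palm_id}: agb_kg={self.agb_kg} does not equal "
                f"component sum {sum(masses.values())}"
            )
        if self.Npf < 3:
            raise InvariantError(f"palm {self.palm_id}: Npf={self.Npf} < 3")
        if self.SDp < self.MDp:
            raise InvariantError(f"palm {self.palm_id}: SDp < MDp")
        if abs(self.SDp / self.Npf - self.MDp) > _MDP_TOL:
            raise InvariantError(
                f"palm {self.palm_id}: SDp/Npf = {self.SDp / self.Npf:.6f} "
                f"inconsistent with MDp = {self.MDp}"
            )
        if self.H <= 0:
            raise InvariantError(f"palm {self.palm_id}: H must be > 0")
        if self.TD <= 0:
            raise InvariantError(f"palm {self.palm_id}: TD must be > 0")


@dataclass
class ComponentSample:
    """One lab sample of a palm component (fresh/dry mass, displaced volume).

    Leaflets have no hydrostatic volume; ``volume_cm3`` is None for them.
    """

    palm_id: str
    component: str
    fresh_g: float
    dry_g: float
    volume_cm3: float | None = None

    def validate(self) -> None:
        if self.component not in COMPONENTS:
            raise SchemaError(f"unknown component {self.component!r}")
        if self.fresh_g <= 0:
            raise InvariantError(f"sample {self.palm_id}/{self.component}: fresh_g <= 0")
        if self.dry_g > self.fresh_g:
            raise InvariantError(
                f"sample {self.palm_id}/{self.component}: dry mass "
                f"{self.dry_g} g exceeds fresh mass {self.fresh_g} g"
            )
        if self.volume_cm3 is not None and self.volume_cm3 <= 0:
            raise InvariantError(f"sample {self.palm_id}/{self.component}: volume <= 0")


@dataclass
class AllometricModel:
    """A log-linear allometric equation ln(AGB) = a + sum(slope * ln(P)).

    ``coefficients`` holds the intercept ``a`` followed by one slope per
    predictor in order; ``CF`` = exp(RSE^2/2) corrects the systematic
    underestimation of the back-transformed prediction; ``subset`` is the
    mean-petiole-diameter range the model was fitted on.
    """

    model_id: str
    predictors: tuple[str, ...]
    intercept: float
    slopes: tuple[float, ...]
    RSE: float
    CF: float
    n: int
    subset: str = ""
    metrics: dict[str, float] = field(default_factory=dict)
    best_single: bool = False
    best_multiple: bool = False

    def validate(self) -> None:
        if self.CF < 1:
            raise InvariantError(f"model {self.model_id}: CF < 1")
        if len(self.slopes) != len(self.predictors):
            raise InvariantError(
                f"model {self.model_id}: {len(self.slopes)} slopes for "
                f"{len(self.predictors)} predictors"
            )
        if self.n <= len(self.slopes) + 1:
            raise InvariantError(f"model {self.model_id}: n too small")

    @property
    def formula(self) -> str:
        terms = " + ".join(
            f"{s:+.3f}*ln({p})".lstrip("+") for s, p in zip(self.slopes, self.predictors)
        )
        return f"ln(AGB) = {self.intercept:.3f} + {terms}"


@dataclass
class Tree:
    stem_id: str
    D: float
    wood_density: float
    H: float


@dataclass
class Palm:
    palm_id: str
    Npf: int
    SDp: float | None = None
    H: float | None = None
    TD: float | None = None


@dataclass
class PlotInventory:
    """All stems of one forest plot: hardwood trees (DBH >= 10 cm) and palms."""

    plot_id: str
    area_ha: float
    trees: list[Tree] = field(default_factory=list)
    palms: list[Palm] = field(default_factory=list)

    def validate(self) -> None:
        if self.area_ha <= 0:
            raise InvariantError(f"plot {self.plot_id}: area_ha must be > 0")
        for t in self.trees:
            if t.D < 10:
                raise InvariantError(f"tree {t.stem_id}: D {t.D} cm < 10 cm")


# ---------------------------------------------------------------------------
# CSV schemas

PALM_COLUMNS = [
    "palm_id", "class_label", "D_cm", "MDp_cm", "SDp_cm", "H_m", "Npf",
    "TD_g_cm3", "stem_kg", "sheath_kg", "petiole_kg", "rachis_kg",
    "leaflet_kg", "agb_kg",
]
SAMPLE_COLUMNS = ["palm_id", "component", "fresh_g", "dry_g", "volume_cm3"]
INVENTORY_COLUMNS = [
    "plot_id", "area_ha", "kind", "stem_id", "D_cm", "wood_density_g_cm3",
    "H_m", "Npf", "SDp_cm", "TD_g_cm3",
]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _as_float(value, row: int, column: str):
    if pd.isna(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: column {column!r} is not numeric: {value!r}")


def read_palm_table(path: str | Path, skip_invalid: bool = False) -> list[PalmRecord]:
    """Read ``palms.csv``; invariant violations name the offending row.

    With ``skip_invalid`` bad rows are dropped and counted instead of
    aborting (field data are messy).
    """
    df = _read_csv(path, PALM_COLUMNS)
    records: list[PalmRecord] = []
    skipped = 0
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based with header
        try:
            rec = PalmRecord(
                palm_id=str(row["palm_id"]),
                class_label=str(row["class_label"]),
                D=_as_float(row["D_cm"], rowno, "D_cm"),
                MDp=_as_float(row["MDp_cm"], rowno, "MDp_cm"),
                SDp=_as_float(row["SDp_cm"], rowno, "SDp_cm"),
                H=_as_float(row["H_m"], rowno, "H_m"),
                Npf=int(row["Npf"]),
                TD=_as_float(row["TD_g_cm3"], rowno, "TD_g_cm3"),
                stem_kg=_as_float(row["stem_kg"], rowno, "stem_kg"),
                sheath_kg=_as_float(row["sheath_kg"], rowno, "sheath_kg"),
                petiole_kg=_as_float(row["petiole_kg"], rowno, "petiole_kg"),
                rachis_kg=_as_float(row["rachis_kg"], rowno, "rachis_kg"),
                leaflet_kg=_as_float(row["leaflet_kg"], rowno, "leaflet_kg"),
                agb_kg=_as_float(row["agb_kg"], rowno, "agb_kg"),
            )
            rec.validate()
        except (InvariantError, ParseError, ValueError) as exc:
            if skip_invalid:
                skipped += 1
                log.warning("skipping row %d: %s", rowno, exc)
                continue
            if isinstance(exc, (InvariantError, ParseError)):
                raise type(exc)(f"row {rowno}: {exc}") from None
            raise ParseError(f"row {rowno}: {exc}") from None
        records.append(rec)
    if skipped:
        log.warning("%d invalid row(s) skipped in %s", skipped, path)
    return records


def write_palm_table(records: Iterable[PalmRecord], path: str | Path) -> None:
    rows = [
        [r.palm_id, r.class_label, r.D, r.MDp, r.SDp, r.H, r.Npf, r.TD,
         r.stem_kg, r.sheath_kg, r.petiole_kg, r.rachis_kg, r.leaflet_kg,
         r.agb_kg]
        for r in records
    ]
    pd.DataFrame(rows, columns=PALM_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_component_samples(path: str | Path) -> list[ComponentSample]:
    """Read ``samples.csv``; samples are retrievable by palm_id and component."""
    df = _read_csv(path, SAMPLE_COLUMNS)
    samples: list[ComponentSample] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        vol = _as_float(row["volume_cm3"], rowno, "volume_cm3")
        s = ComponentSample(
            palm_id=str(row["palm_id"]),
            component=str(row["component"]),
            fresh_g=_as_float(row["fresh_g"], rowno, "fresh_g"),
            dry_g=_as_float(row["dry_g"], rowno, "dry_g"),
            volume_cm3=vol,
        )
        try:
            s.validate()
        except (SchemaError, InvariantError) as exc:
            raise type(exc)(f"row {rowno}: {exc}") from None
        samples.append(s)
    return samples


def write_component_samples(samples: Iterable[ComponentSample], path: str | Path) -> None:
    rows = [[s.palm_id, s.component, s.fresh_g, s.dry_g, s.volume_cm3] for s in samples]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def group_samples(samples: Iterable[ComponentSample]) -> dict[str, dict[str, list[ComponentSample]]]:
    """Group samples by palm_id, then by component."""
    out: dict[str, dict[str, list[ComponentSample]]] = {}
    for s in samples:
        out.setdefault(s.palm_id, {}).setdefault(s.component, []).append(s)
    return out


def read_inventory(path: str | Path) -> PlotInventory:
    """Read a one-plot stems table; sub-threshold trees are dropped with a warning."""
    df = _read_csv(path, ["plot_id", "area_ha", "kind", "stem_id"])
    plot_ids = df["plot_id"].unique()
    if len(plot_ids) != 1:
        raise SchemaError(f"expected one plot per file, found {list(plot_ids)}")
    area = float(df["area_ha"].iloc[0])
    inv = PlotInventory(plot_id=str(plot_ids[0]), area_ha=area)
    if area <= 0:
        raise InvariantError(f"plot {inv.plot_id}: area_ha must be > 0")
    n_small = 0
    for i, row in df.iterrows():
        rowno = int(i) + 2
        kind = str(row["kind"]).strip().lower()
        if kind == "tree":
            d = _as_float(row.get("D_cm"), rowno, "D_cm")
            wd = _as_float(row.get("wood_density_g_cm3"), rowno, "wood_density_g_cm3")
            h = _as_float(row.get("H_m"), rowno, "H_m")
            if d is None or wd is None or h is None:
                raise SchemaError(f"row {rowno}: tree requires D_cm, wood_density_g_cm3, H_m")
            if d < 10:
                n_small += 1
                continue
            inv.trees.append(Tree(str(row["stem_id"]), d, wd, h))
        elif kind == "palm":
            npf = row.get("Npf")
            if pd.isna(npf):
                raise SchemaError(f"row {rowno}: palm lacks Npf")
            inv.palms.append(
                Palm(
                    palm_id=str(row["stem_id"]),
                    Npf=int(npf),
                    SDp=_as_float(row.get("SDp_cm"), rowno, "SDp_cm"),
                    H=_as_float(row.get("H_m"), rowno, "H_m"),
                    TD=_as_float(row.get("TD_g_cm3"), rowno, "TD_g_cm3"),
                )
            )
        else:
            raise SchemaError(f"row {rowno}: unknown kind {row['kind']!r}")
    if n_small:
        log.warning("%d tree(s) with D < 10 cm excluded from plot %s", n_small, inv.plot_id)
    inv.validate()
    return inv


def write_inventory(inv: PlotInventory, path: str | Path) -> None:
    rows = []
    for t in inv.trees:
        rows.append([inv.plot_id, inv.area_ha, "tree", t.stem_id, t.D,
                     t.wood_density, t.H, None, None, None])
    for p in inv.palms:
        rows.append([inv.plot_id, inv.area_ha, "palm", p.palm_id, None, None,
                     p.H, p.Npf, p.SDp, p.TD])
    pd.DataFrame(rows, columns=INVENTORY_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# packaged coefficient fixture


def _fixture_path() -> Path:
    return Path(str(resources.files("raphia_allometry") / "data" / _FIXTURE_NAME))


def load_published_models(path: str | Path | None = None, verify: bool = True) -> list[AllometricModel]:
    """Load the 22 published allometric models from the packaged fixture.

    Models m1-m11 were fitted on the full 2-15 cm mean-petiole-diameter
    range (n=90), m12-m22 on the >=5 cm subset (n=60). ``verify`` checks
    the fixture file against its recorded SHA-256 digest.
    """
    p = Path(path) if path is not None else _fixture_path()
    if verify and path is None:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise IntegrityError(
                f"coefficient fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )
    df = pd.read_csv(p)
    models: list[AllometricModel] = []
    for _, row in df.iterrows():
        predictors = tuple(
            PREDICTOR_ALIASES.get(t, t) for t in str(row["predictors"]).split("+")
        )
        slopes = tuple(
            float(row[c]) for c in ("b", "c", "d")[: len(predictors)]
            if not pd.isna(row[c])
        )
        m = AllometricModel(
            model_id=str(row["model_id"]),
            predictors=predictors,
            intercept=float(row["a"]),
            slopes=slopes,
            RSE=float(row["RSE"]),
            CF=float(row["CF"]),
            n=int(row["n"]),
            subset=str(row["subset"]),
            metrics={
                "R2adj": float(row["R2adj"]),
                "AIC": float(row["AIC"]),
                "RMSE": float(row["RMSE"]),
                "BiasPct": float(row["BiasPct"]),
            },
            best_single=bool(row["best_single"]),
            best_multiple=bool(row["best_multiple"]),
        )
        m.validate()
        if abs(m.CF - math.exp(m.RSE**2 / 2)) > 0.005:
            raise IntegrityError(
                f"model {m.model_id}: CF {m.CF} inconsistent with RSE {m.RSE}"
            )
        models.append(m)
    return models


def get_model(model_id: str, models: Sequence[AllometricModel] | None = None) -> AllometricModel:
    """Look one model up by id, from the packaged fixture by default."""
    models = models if models is not None else load_published_models()
    for m in models:
        if m.model_id == model_id:
            return m
    available = ", ".join(m.model_id for m in models)
    raise ModelNotFoundError(f"model {model_id!r} not found; available: {available}")
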