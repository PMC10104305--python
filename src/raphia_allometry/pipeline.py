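"""Workflow orchestration: staged fitting and plot application as one call.

These functions are the computational back end of the command-line
interface and of the numbered analysis drivers. Each writes tidy CSV
outputs plus a JSON run manifest (command, config digest, seed, input
digests, outputs) so any table can be traced to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agb_application as app
from . import allometry_fitting as fitmod
from . import tissue_processing as tissue
from .data_model_io import (
    AllometricModel,
    get_model,
    load_published_models,
    read_inventory,
    read_palm_table,
)
from .errors import DomainError

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def write(self, out_dir: Path) -> Path:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        path = Path(out_dir) / f"manifest_{self.command}.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def _digest_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _digest_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _manifest(command: str, config, inputs: Sequence[Path], seed=None) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=_digest_config(config),
        seed=seed,
        inputs={str(p): _digest_file(p) for p in inputs},
    )


def run_fit_workflow(
    palms_path: str | Path,
    subset_rules: Sequence[float] = (2.0, 5.0),
    out_dir: str | Path = "results",
    alpha: float = 0.05,
) -> dict:
    """Staged allometric fitting on one or more size subsets.

    For each mean-petiole-diameter threshold, builds and fits the staged
    candidate set (6 single + 3 pair + 2 triple models when the best
    single predictor is a coarseness one and the best pair adds height),
    annotates nested F-tests, ranks, and writes ``fitted_models.csv``
    (published-table layout) and ``residuals.csv``. Returns the selection
    report (also written as ``selection_report.json``).
    """
    palms_path = Path(palms_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_palm_table(palms_path)
    if not records:
        raise DomainError(f"no palm records in {palms_path}")

    model_rows, resid_rows = [], []
    report: dict = {"input": str(palms_path), "subsets": {}}
    mid = 0
    for threshold in subset_rules:
        candidates = fitmod.build_candidates(records, mdp_min=threshold, alpha=alpha)
        ranked = fitmod.rank_models([(spec, fit.metrics) for spec, fit in candidates])
        fits = {spec.predictors: fit for spec, fit in candidates}
        label = f">={threshold:g} cm"
        for spec, fit in candidates:
            mid += 1
            model_id = f"f{mid}"
            met = fit.metrics
            coeffs = list(fit.coefficients) + [np.nan] * (4 - len(fit.coefficients))
            model_rows.append(
                [model_id, "+".join(spec.predictors), *coeffs[:4],
                 met.R2adj, met.RSE, met.AIC, met.RMSE, met.BiasPct, met.CF,
                 label, fit.n, spec.stage, spec.partial_F, spec.partial_p]
            )
            for i, r in enumerate(fit.residuals):
                resid_rows.append([model_id, i, float(r)])
        singles = [(s, f.metrics) for s, f in candidates if s.stage == 1]
        best_single = fitmod.rank_models(singles)[0][0]
        best_overall = ranked[0][0]
        report["subsets"][label] = {
            "n": len(fitmod.filter_subset(records, threshold)),
            "n_candidates": len(candidates),
            "best_single": "+".join(best_single.predictors),
            "best_overall": "+".join(best_overall.predictors),
            "ranking": ["+".join(s.predictors) for s, _ in ranked],
        }

    models_df = pd.DataFrame(
        model_rows,
        columns=["model_id", "predictors", "a", "b", "c", "d", "R2adj", "RSE",
                 "AIC", "RMSE", "BiasPct", "CF", "subset", "n", "stage",
                 "partial_F", "partial_p"],
    )
    models_df.to_csv(out_dir / "fitted_models.csv", index=False)
    pd.DataFrame(resid_rows, columns=["model_id", "obs", "residual"]).to_csv(
        out_dir / "residuals.csv", index=False)
    (out_dir / "selection_report.json").write_text(json.dumps(report, indent=2))
    man = _manifest("fit", {"subsets": list(subset_rules), "alpha": alpha}, [palms_path])
    man.outputs = [str(out_dir / f) for f in
                   ("fitted_models.csv", "residuals.csv", "selection_report.json")]
    man.write(out_dir)
    return report


def run_tissue_workflow(
    palms_path: str | Path,
    samples_path: str | Path,
    out_dir: str | Path = "results",
) -> dict:
    """Tissue summaries, AGB partitioning and the rank tests, as tidy CSVs."""
    from .data_model_io import read_component_samples

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    palms = read_palm_table(palms_path)
    samples = read_component_samples(samples_path)

    tiss = tissue.summarise_tissue(samples)
    pd.DataFrame([asdict(t) for t in tiss]).to_csv(
        out_dir / "tissue_summary.csv", index=False)

    parts = tissue.partition_fractions(palms, by_class=True)
    pooled = tissue.partition_fractions(palms, by_class=False)[0]
    part_rows = [
        {"class_label": p.class_label, **p.fractions,
         "frond_fraction": p.frond_fraction, "n": p.n}
        for p in parts + [pooled]
    ]
    pd.DataFrame(part_rows).to_csv(out_dir / "partition_summary.csv", index=False)

    comp_masses = {
        c: [p.component_masses()[c] for p in palms] for c in
        ("stem", "sheath", "petiole", "rachis", "leaflet")
    }
    h_stat, p_kw = tissue.kruskal_wallis(list(comp_masses.values()))
    dunn = tissue.dunn_test(list(comp_masses.values()), adjustment="none")
    names = list(comp_masses)
    dunn["comparison"] = [
        f"{names[i]} vs {names[j]}" for i, j in zip(dunn.group_i, dunn.group_j)
    ]
    tests = pd.concat(
        [pd.DataFrame([{"comparison": "all components", "statistic": h_stat,
                        "p": p_kw, "p_adj": p_kw, "test": "kruskal-wallis"}]),
         dunn.assign(test="dunn").rename(columns={"z": "statistic"})[
             ["comparison", "statistic", "p", "p_adj", "test"]]],
        ignore_index=True,
    )
    tests.to_csv(out_dir / "group_tests.csv", index=False)
    man = _manifest("tissue", {}, [Path(palms_path), Path(samples_path)])
    man.outputs = [str(out_dir / f) for f in
                   ("tissue_summary.csv", "partition_summary.csv", "group_tests.csv")]
    man.write(out_dir)
    return {
        "kruskal_H": h_stat, "kruskal_p": p_kw,
        "pooled_fractions": pooled.fractions,
        "pooled_frond_fraction": pooled.frond_fraction,
    }


def run_apply_workflow(
    inventory_paths: Sequence[str | Path],
    model_id: str = "m16",
    out_dir: str | Path = "results",
    carbon_fraction: float = app.DEFAULT_CARBON_FRACTION,
    region_area_km2: float | None = None,
    fitted_models_path: str | Path | None = None,
) -> pd.DataFrame:
    """Plot-level AGB accounting with one palm model, plus optional upscaling.

    The model id is resolved against the packaged published table, or a
    ``fitted_models.csv`` if one is supplied. When a regional area is
    given, each plot's palm carbon density (AGB x carbon fraction) is
    upscaled to a regional Pg C estimate in ``regional_summary.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = _resolve_model(model_id, fitted_models_path)

    rows, regional = [], []
    for path in inventory_paths:
        inv = read_inventory(path)
        full = app.plot_totals(inv, model, include_palms=True)
        rows.append(asdict(full))
        if region_area_km2 is not None:
            palm_c_mg_ha = app.agb_to_carbon(full.palm_agb_kg, carbon_fraction) / 1000.0
            regional.append({
                "plot_id": inv.plot_id,
                "palm_carbon_mg_ha": palm_c_mg_ha,
                "area_km2": region_area_km2,
                "regional_pg_c": app.upscale_regional_carbon(palm_c_mg_ha,
                                                             region_area_km2)
                if palm_c_mg_ha > 0 else 0.0,
            })
    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "plot_results.csv", index=False)
    outputs = [str(out_dir / "plot_results.csv")]
    if regional:
        pd.DataFrame(regional).to_csv(out_dir / "regional_summary.csv", index=False)
        outputs.append(str(out_dir / "regional_summary.csv"))
    man = _manifest(
        "apply",
        {"model_id": model_id, "carbon_fraction": carbon_fraction,
         "region_area_km2": region_area_km2},
        [Path(p) for p in inventory_paths],
    )
    man.outputs = outputs
    man.write(out_dir)
    return results


def _resolve_model(model_id: str, fitted_models_path=None) -> AllometricModel:
    if fitted_models_path is None:
        return get_model(model_id)
    df = pd.read_csv(fitted_models_path)
    sub = df[df["model_id"] == model_id]
    if sub.empty:
        from .errors import ModelNotFoundError

        raise ModelNotFoundError(
            f"model {model_id!r} not in {fitted_models_path}; "
            f"available: {', '.join(df['model_id'])}"
        )
    row = sub.iloc[0]
    predictors = tuple(str(row["predictors"]).split("+"))
    slopes = tuple(
        float(row[c]) for c in ("b", "c", "d")[: len(predictors)] if pd.notna(row[c])
    )
    return AllometricModel(
        model_id=model_id, predictors=predictors, intercept=float(row["a"]),
        slopes=slopes, RSE=float(row["RSE"]), CF=float(row["CF"]),
        n=int(row["n"]), subset=str(row["subset"]),
    )


def run_reproduce(out_dir: str | Path = "results", seed: int = 0) -> dict:
    """One-shot synthetic end-to-end demonstration of every stage.

    Simulates the stratified destructive sample and two contrasting plot
    inventories, then runs the tissue, fitting and application workflows
    on them. Fully deterministic for a fixed seed.
    """
    from .data_model_io import write_component_samples, write_inventory, write_palm_table
    from .synthetic_data import SimConfig, simulate_palm_dataset, simulate_plot_inventory

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    records, samples = simulate_palm_dataset(cfg)
    write_palm_table(records, out_dir / "palms.csv")
    write_component_samples(samples, out_dir / "samples.csv")
    palm_rich = simulate_plot_inventory(60, 420, seed=seed + 1, plot_id="SYN-PALM")
    hardwood = simulate_plot_inventory(380, 40, seed=seed + 2, plot_id="SYN-HARDWOOD")
    write_inventory(palm_rich, out_dir / "inventory_palm.csv")
    write_inventory(hardwood, out_dir / "inventory_hardwood.csv")

    tissue_report = run_tissue_workflow(out_dir / "palms.csv", out_dir / "samples.csv",
                                        out_dir)
    fit_report = run_fit_workflow(out_dir / "palms.csv", (2.0, 5.0), out_dir)
    plots = run_apply_workflow(
        [out_dir / "inventory_palm.csv", out_dir / "inventory_hardwood.csv"],
        model_id="m16", out_dir=out_dir, region_area_km2=66300.0,
    )
    report = {
        "seed": seed,
        "n_palms": len(records),
        "tissue": tissue_report,
        "fit": fit_report,
        "plots": plots.to_dict(orient="records"),
    }
    (out_dir / "reproduce_report.json").write_text(json.dumps(report, indent=2))
    return report


def published_models_table() -> pd.DataFrame:
    """The packaged published coefficient table as a DataFrame."""
    models = load_published_models()
    return pd.DataFrame(
        [{"model_id": m.model_id, "predictors": "+".join(m.predictors),
          "a": m.intercept,
          **{k: v for k, v in zip("bcd", m.slopes)},
          "RSE": m.RSE, "CF": m.CF, "subset": m.subset, "n": m.n,
          **m.metrics} for m in models]
    )
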