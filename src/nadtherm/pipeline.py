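"""End-to-end study orchestration: fits -> model -> optimization -> MCA.

Reproduces the full study as tidy tables: Arrhenius fits of the
thermolysis table, temperature sweeps of the three allocation objectives
with pathway classification, and control coefficients at class-
representative optima.  Every stage writes TSV/JSON plus a manifest
recording seeds and configuration, so any output table is reconstructible
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import T0_DEFAULT
from .ep import OptimizationProblem, run_ep, runs_to_table, temperature_sweep
from .errors import ConfigurationError
from .io import fixture_path, load_model_config, read_rate_table, to_measurements, write_results
from .mca import control_coefficients
from .network import EnzymeProfile, build_default_model, build_model
from .thermolysis import fit_all_compounds

__all__ = ["PipelineConfig", "run_full_study", "DEFAULT_TEMPERATURE_GRID"]

#: Base temperature up to the hottest measured thermolysis point, six steps.
DEFAULT_TEMPERATURE_GRID = tuple(np.round(np.linspace(T0_DEFAULT, 363.15, 6), 2))


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full study run."""

    out_dir: str
    model_config: str | None = None  # YAML path; None = bundled defaults
    rate_table: str | None = None  # TSV path; None = bundled fixture
    objectives: tuple = ("min_ratio", "min_atp", "max_nad")
    temperatures: tuple = DEFAULT_TEMPERATURE_GRID
    n_repeats: int = 100
    seed: int = 0
    rate_unit: str = "fraction_per_ms"
    mca_rel_step: float = 1e-2

    def __post_init__(self):
        for obj in self.objectives:
            if obj not in ("min_ratio", "min_atp", "max_nad"):
                raise ConfigurationError(f"unknown objective {obj!r}")
        for path in (self.model_config, self.rate_table):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"referenced file does not exist: {path}")


def _fit_table(measurements, unit) -> pd.DataFrame:
    fits = fit_all_compounds(measurements, unit=unit)
    return pd.DataFrame([
        {"compound": c, "A": f.params.prefactor_A,
         "Ea_kJ_per_mol": f.params.activation_energy_Ea, "sse": f.sse,
         "n_points": f.n_points, "rate_unit": f.params.rate_unit,
         "flag": f.flag or ""}
        for c, f in fits.items()
    ])


def run_full_study(config: PipelineConfig) -> dict:
    """Execute every stage; returns ``{"tables": ..., "paths": ..., "manifest": ...}``.

    Any stage failure aborts with the stage name; tables written before the
    failure are left on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }
    tables: dict[str, pd.DataFrame] = {}
    stage = "fit-arrhenius"
    try:
        t0 = time.perf_counter()
        rate_path = config.rate_table or fixture_path()
        measurements = to_measurements(read_rate_table(rate_path))
        tables["arrhenius_fits"] = _fit_table(measurements, config.rate_unit)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "input": str(rate_path)}

        stage = "model-build"
        t0 = time.perf_counter()
        if config.model_config:
            model = build_model(load_model_config(config.model_config))
        else:
            model = build_default_model()
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "n_reactions": model.n_reactions}

        stage = "optimize"
        t0 = time.perf_counter()
        sweep_tables = []
        seed_rng = np.random.default_rng(config.seed)
        objective_seeds = {}
        for objective in config.objectives:
            obj_seed = int(seed_rng.integers(0, 2**31 - 1))
            objective_seeds[objective] = obj_seed
            problem = OptimizationProblem(model=model, objective=objective, seed=obj_seed)
            sweep = temperature_sweep(problem, config.temperatures,
                                      n_repeats=config.n_repeats, seed=obj_seed)
            sweep_tables.append(sweep)
        tables["optimization_sweep"] = pd.concat(sweep_tables, ignore_index=True)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "objective_seeds": objective_seeds}

        stage = "mca"
        t0 = time.perf_counter()
        mca_rows = []
        base_problem = OptimizationProblem(model=model, objective="min_ratio",
                                           seed=int(seed_rng.integers(0, 2**31 - 1)))
        sweep = tables["optimization_sweep"]
        base = sweep[(sweep["objective"] == "min_ratio") & sweep["feasible"]
                     & (sweep["T_K"] == sweep["T_K"].min())]
        for cls, group in base.groupby("classification"):
            best = group.nsmallest(1, "objective_value").iloc[0]
            E = EnzymeProfile.from_dict(
                {e: best[f"E_{e}"] for e in EnzymeProfile.uniform().as_dict()})
            cm = control_coefficients(model, E, float(best["T_K"]),
                                      rel_step=config.mca_rel_step)
            long = cm.coefficients.reset_index(names="species").melt(
                id_vars="species", var_name="process", value_name="coefficient")
            long.insert(0, "classification", cls)
            mca_rows.append(long)
        if mca_rows:
            tables["mca_coefficients"] = pd.concat(mca_rows, ignore_index=True)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
    except Exception as exc:
        write_results(out_dir, tables)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    paths = write_results(out_dir, tables)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"tables": tables, "paths": paths, "manifest": manifest,
            "manifest_path": manifest_path}
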