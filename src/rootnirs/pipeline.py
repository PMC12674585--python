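"""End-to-end study replica: simulate -> preprocess -> calibrate -> BLUP ->
concordance, driven by one configuration object (or YAML file).

For every combination of trait, sample type, pre-treatment and engine the
pipeline produces a calibration run (trimmed repeated-CV metrics plus
holdout validation), then screens pre-treatments with the PLS runs, fits the
multi-environment mixed model to the observed traits and to each engine's
plot-level predictions, and quantifies selection concordance (top-fraction
Cohen kappa) between phenotype-based and prediction-based dBLUP rankings.

Outputs under ``output_dir``: per-run JSON files, ``metrics.csv``,
``blups_<trait>.csv``, ``kappa.csv`` and a ``manifest.json`` with config
hash, seeds, package versions and per-file checksums. Completed run files
are reused when ``resume=True``; a failure in one factorial cell is logged
in the manifest and the remaining cells continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    CalibrationRun,
    CVProtocol,
    EngineSpec,
    aggregate_readings,
    residual_trim_refit,
    select_treatment,
    split_dataset,
    trait_vector,
)
from .datasets import write_traits_csv
from .exceptions import ConfigurationError
from .metrics import MetricSet
from .mixedmodel import fit_mixed_model, write_blups_csv
from .preprocess import TreatmentSpec, fit_treatment, iqr_outlier_filter
from .selection import concordance_long_format, concordance_matrix, select_top_fraction
from .simulate import SimulationConfig, simulate_spectra, simulate_traits


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    treatments: list = field(default_factory=lambda: [TreatmentSpec("raw"), TreatmentSpec("sg_snv")])
    engines: list = field(default_factory=lambda: [EngineSpec("pls")])
    protocol: CVProtocol = field(default_factory=CVProtocol)
    traits: list = field(default_factory=lambda: ["StC", "DMCo", "DMCg"])
    sample_types: list = field(default_factory=lambda: ["fresh", "mashed"])
    selection_fraction: float = 0.20
    output_dir: str = "pipeline_out"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.traits or not self.engines or not self.treatments:
            raise ConfigurationError("traits, engines and treatments must be non-empty")
        self.treatments = [
            t if isinstance(t, TreatmentSpec) else TreatmentSpec(str(t))
            for t in self.treatments
        ]
        self.engines = [
            e if isinstance(e, EngineSpec) else EngineSpec(str(e))
            for e in self.engines
        ]

    def seeded(self) -> "PipelineConfig":
        """Propagate the master seed to the simulation and CV protocol."""
        ss = np.random.SeedSequence(int(self.master_seed))
        sim_seed, cv_seed = (int(s % (2**31)) for s in ss.generate_state(2))
        cfg = dataclasses.replace(self)
        cfg.simulation = dataclasses.replace(self.simulation, seed=sim_seed)
        cfg.protocol = dataclasses.replace(self.protocol, seed=cv_seed)
        return cfg


def config_from_dict(payload: dict) -> PipelineConfig:
    sim = SimulationConfig(**payload.get("simulation", {}))
    treatments = [
        TreatmentSpec(t["name"], t.get("params", {})) if isinstance(t, dict) else TreatmentSpec(t)
        for t in payload.get("treatments", ["raw", "sg_snv"])
    ]
    engines = [
        EngineSpec(**e) if isinstance(e, dict) else EngineSpec(e)
        for e in payload.get("engines", ["pls"])
    ]
    protocol = CVProtocol(**payload.get("protocol", {}))
    return PipelineConfig(
        simulation=sim,
        treatments=treatments,
        engines=engines,
        protocol=protocol,
        traits=payload.get("traits", ["StC", "DMCo", "DMCg"]),
        sample_types=payload.get("sample_types", ["fresh", "mashed"]),
        selection_fraction=payload.get("selection_fraction", 0.20),
        output_dir=payload.get("output_dir", "pipeline_out"),
        master_seed=payload.get("master_seed", 0),
    )


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def demo_config(output_dir: str = "demo_out", master_seed: int = 0) -> PipelineConfig:
    """A small end-to-end configuration (minutes, one CPU)."""
    sim = SimulationConfig(n_clones=120, n_envs=2, n_reps=2)
    return PipelineConfig(
        simulation=sim,
        treatments=[TreatmentSpec("raw"), TreatmentSpec("sg_snv")],
        engines=[EngineSpec("pls")],
        traits=["DMCo"],
        sample_types=["fresh", "mashed"],
        output_dir=output_dir,
        master_seed=master_seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _run_tag(trait, sample_type, treatment, engine) -> str:
    return f"{trait}_{sample_type}_{treatment.name}_{engine.engine}"


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full factorial and write the report bundle.

    Returns a report dict with the calibration runs, the selected treatment,
    mixed-model fits and concordance tables.
    """
    cfg = config.seeded()
    outdir = Path(cfg.output_dir)
    rundir = outdir / "runs"
    rundir.mkdir(parents=True, exist_ok=True)
    failures: list[dict] = []
    t_start = time.time()

    traits_table = simulate_traits(cfg.simulation)
    write_traits_csv(traits_table, outdir / "traits.csv")

    # one split of plots per sample type, shared by all traits/engines
    per_sample: dict[str, dict] = {}
    for st in cfg.sample_types:
        ds = simulate_spectra(traits_table, st, cfg.simulation)
        kept, flagged = iqr_outlier_filter(ds)
        plot_ids, X = aggregate_readings(kept)
        (Xc, _, cal_ids), (Xv, _, hold_ids) = split_dataset(
            X, np.zeros(len(plot_ids)), plot_ids, cfg.protocol
        )
        per_sample[st] = dict(
            X=X, plot_ids=plot_ids, Xc=Xc, Xv=Xv,
            cal_ids=cal_ids, hold_ids=hold_ids,
            flagged=flagged, wavelengths=kept.wavelengths,
        )

    runs: dict[str, dict] = {}  # tag -> {"run": CalibrationRun|None, "record": dict}
    for st in cfg.sample_types:
        data = per_sample[st]
        for treatment in cfg.treatments:
            fitted = fit_treatment(treatment, data["Xc"], data["wavelengths"])
            Tc = fitted.transform(data["Xc"])
            Tv = fitted.transform(data["Xv"])
            Tall = fitted.transform(data["X"])
            for trait in cfg.traits:
                yc = trait_vector(traits_table, data["cal_ids"], trait)
                yv = trait_vector(traits_table, data["hold_ids"], trait)
                for engine in cfg.engines:
                    tag = _run_tag(trait, st, treatment, engine)
                    path = rundir / f"{tag}.json"
                    if resume and path.exists():
                        runs[tag] = dict(run=None, record=json.loads(path.read_text()))
                        continue
                    try:
                        run = residual_trim_refit(
                            Tc, yc, data["cal_ids"], engine, cfg.protocol,
                            holdout=(Tv, yv, data["hold_ids"]),
                            trait=trait, sample_type=st, treatment=treatment,
                        )
                        record = run.to_dict()
                        record["all_plot_ids"] = [str(p) for p in data["plot_ids"]]
                        record["all_plot_predictions"] = run.final_model.predict(Tall).tolist()
                        path.write_text(json.dumps(record, indent=1))
                        runs[tag] = dict(run=run, record=record)
                    except Exception as exc:  # isolate factorial-cell failures
                        warnings.warn(f"cell {tag} failed: {exc}")
                        failures.append(dict(cell=tag, error=str(exc)))

    # metrics table
    metric_rows = []
    for tag, entry in runs.items():
        rec = entry["record"]
        for part in ("cv", "val"):
            m = rec[f"metrics_{part}"]
            if m is None:
                continue
            metric_rows.append(
                dict(trait=rec["trait"], sample_type=rec["sample_type"],
                     treatment=rec["treatment"]["name"], engine=rec["engine"],
                     partition=part, **m)
            )
    metrics_table = pd.DataFrame(metric_rows)
    metrics_table.to_csv(outdir / "metrics.csv", index=False)

    # treatment screening on the PLS runs
    selected_treatment = None
    pls_runs = [e["run"] for e in runs.values() if e["run"] is not None and e["run"].engine.engine == "pls"]
    if pls_runs:
        try:
            selected_treatment = select_treatment(pls_runs)
        except ConfigurationError:
            selected_treatment = None
    best_name = selected_treatment.name if selected_treatment else cfg.treatments[0].name

    # mixed-model BLUPs: observed phenotypes, then each engine's predictions
    pheno_fits, kappa_tables = {}, {}
    for trait in cfg.traits:
        try:
            fit = fit_mixed_model(traits_table, trait)
            pheno_fits[trait] = fit
            write_blups_csv(fit, outdir / f"blups_{trait}.csv")
        except Exception as exc:
            failures.append(dict(cell=f"blup_{trait}", error=str(exc)))
            continue
        pheno_scores = pd.Series(
            fit.clone_effects["dblup"].to_numpy(),
            index=fit.clone_effects["clone_id"].to_numpy(),
        )
        for st in cfg.sample_types:
            selections = {"phenotype": select_top_fraction(pheno_scores, cfg.selection_fraction)}
            for engine in cfg.engines:
                tag = _run_tag(trait, st, TreatmentSpec(best_name), engine)
                if tag not in runs:
                    continue
                rec = runs[tag]["record"]
                pred_table = traits_table.copy()
                pred_map = dict(zip(rec["all_plot_ids"], rec["all_plot_predictions"]))
                pred_table[trait] = pred_table["plot_id"].map(pred_map)
                pred_table = pred_table.dropna(subset=[trait])
                try:
                    pred_fit = fit_mixed_model(pred_table, trait)
                except Exception as exc:
                    failures.append(dict(cell=f"blup_pred_{tag}", error=str(exc)))
                    continue
                scores = pd.Series(
                    pred_fit.clone_effects["dblup"].to_numpy(),
                    index=pred_fit.clone_effects["clone_id"].to_numpy(),
                )
                selections[engine.engine] = select_top_fraction(scores, cfg.selection_fraction)
            universe = traits_table["clone_id"].nunique()
            kappa_tables[(trait, st)] = concordance_matrix(selections, universe)
    kappa_long = concordance_long_format(kappa_tables, outdir / "kappa.csv")

    report = dict(
        runs=runs,
        metrics_table=metrics_table,
        selected_treatment=best_name,
        phenotype_fits=pheno_fits,
        kappa_tables=kappa_tables,
        failures=failures,
    )

    manifest = dict(
        package_version=__version__,
        master_seed=int(cfg.master_seed),
        simulation_seed=int(cfg.simulation.seed),
        protocol_seed=int(cfg.protocol.seed),
        selected_treatment=best_name,
        config_hash=hashlib.sha256(
            json.dumps(_config_summary(cfg), sort_keys=True).encode()
        ).hexdigest(),
        config=_config_summary(cfg),
        elapsed_seconds=round(time.time() - t_start, 2),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        failures=failures,
        files={},
    )
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def _config_summary(cfg: PipelineConfig) -> dict:
    return dict(
        n_clones=cfg.simulation.n_clones,
        n_envs=cfg.simulation.n_envs,
        n_reps=cfg.simulation.n_reps,
        traits=list(cfg.traits),
        sample_types=list(cfg.sample_types),
        treatments=[t.name for t in cfg.treatments],
        engines=[e.engine for e in cfg.engines],
        protocol=dataclasses.asdict(cfg.protocol),
        selection_fraction=cfg.selection_fraction,
        master_seed=int(cfg.master_seed),
    )
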