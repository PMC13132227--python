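"""End-to-end orchestration: simulate -> network -> diffusion analysis ->
choice models -> technique tests, with a machine-readable run report."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, nbda
from .ewafit import FitConfig, fit_ewa, posterior_summary, prepare_choice_data, waic_table
from .network import build_sri_network, movement_rates
from .synthetic import SyntheticConfig, simulate_all
from .techniques import build_predictor_matrix, encode_sequences, partial_mantel, sequence_dissimilarity


@dataclass
class PipelineConfig:
    """Which stages to run and at what scale."""

    data_dir: str = "."
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: SyntheticConfig | None = None
    run_nbda: bool = True
    run_ewa: bool = True
    run_techniques: bool = True
    nbda_ilvs: tuple[str, ...] = ("sex", "age")
    ewa_strategies: tuple[str, ...] = (
        "individual", "frequency", "male_bias", "age_bias", "roost_bias")
    ewa_config: FitConfig = field(default_factory=FitConfig)
    window: float = 60.0
    mantel_permutations: int = 999


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run report.

    Each stage writes its outputs under ``out_dir`` and appends a section to
    the report; a stage failure is recorded with its context and stops the
    run, returning the partial report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    try:
        data_dir = Path(config.data_dir)
        if config.simulate is not None:
            simulate_all(config.simulate, out / "data")
            data_dir = out / "data"
            report["stages"]["simulate"] = {
                "out": str(data_dir),
                "master_seed": config.simulate.master_seed,
            }
        paths = {name: data_dir / f"{name}.csv"
                 for name in ("individuals", "scans", "events", "diffusion",
                              "openings", "sites")
                 if (data_dir / f"{name}.csv").exists()}
        report["stages"]["validate"] = io.validate_bundle(paths)

        individuals = io.read_individuals(paths["individuals"])
        scans = io.read_scans(paths["scans"])
        net = build_sri_network(scans, ids=list(individuals))
        io.write_edge_list(net, out / "edges.csv")
        weights = net.weights[np.triu_indices(len(net), k=1)]
        report["stages"]["network"] = {
            "n_nodes": len(net),
            "n_edges": int((weights > 0).sum()),
            "mean_sri": float(weights.mean()),
            "out": str(out / "edges.csv"),
        }

        if config.run_nbda and "diffusion" in paths:
            record = io.read_diffusion(paths["diffusion"])
            ilvs = nbda.ILVDesign.from_individuals(individuals.values())
            fits = [nbda.fit_oada(record, net, spec, ilvs)
                    for spec in nbda.all_model_specs(config.nbda_ilvs)]
            table = nbda.aicc_model_table(fits)
            table.to_csv(out / "nbda_models.csv", index=False)
            best_social = next(f for f in fits
                               if f.spec.social
                               and f.spec.name == table.loc[
                                   table.family == "social", "model"].iloc[0])
            pst = nbda.percent_social(best_social, record, net, ilvs)
            report["stages"]["nbda"] = {
                "n_events": record.n_events,
                "family_support": nbda.family_support(table),
                "best_model": table["model"].iloc[0],
                "best_social_s": best_social.params.s,
                "percent_social": pst,
                "table": str(out / "nbda_models.csv"),
            }

        if config.run_ewa and "events" in paths:
            events = io.read_events(paths["events"])
            data = prepare_choice_data(events, individuals,
                                       window=config.window)
            fits = {}
            for strategy in config.ewa_strategies:
                cfg = FitConfig(**{**config.ewa_config.__dict__,
                                   "seed": config.ewa_config.seed})
                fits[strategy] = fit_ewa(data, None, strategy, cfg)
            wt = waic_table(list(fits.values()))
            wt.to_csv(out / "ewa_waic.csv")
            summaries = {}
            for strategy, fit in fits.items():
                summary = posterior_summary(fit)
                summary.to_csv(out / f"ewa_summary_{strategy}.csv",
                               index=False)
                fit.to_frame().to_csv(out / f"ewa_draws_{strategy}.csv",
                                      index=False)
                summaries[strategy] = {
                    "max_rhat": fit.diagnostics["max_rhat"],
                    "divergences": fit.diagnostics["divergences"],
                }
                report["warnings"].extend(fit.warnings_)
            report["stages"]["ewa"] = {
                "n_events": data.n_events,
                "n_individuals": len(data.ids),
                "waic": wt.reset_index().to_dict(orient="records"),
                "diagnostics": summaries,
            }

        if config.run_techniques and "openings" in paths:
            openings = io.read_openings(paths["openings"])
            site_coords = io.read_sites(paths["sites"])
            encoded = encode_sequences(openings)
            d_y = sequence_dissimilarity(encoded)
            d_id = build_predictor_matrix(openings, "same_individual")
            d_dist = build_predictor_matrix(openings, "site_distance",
                                            site_coords=site_coords)
            attendance = {}
            for o in openings:
                attendance.setdefault(o.site, set()).add(o.individual)
            mv = movement_rates(attendance)
            d_move = build_predictor_matrix(openings, "site_movement",
                                            movement=mv)
            d_assoc = build_predictor_matrix(openings, "association",
                                             network=net)
            rng = np.random.default_rng(config.seed)
            results = {}
            for name, d_x in [("individual", d_id), ("distance", d_dist),
                              ("movement", d_move), ("association", d_assoc)]:
                control = d_dist if name == "individual" else d_id
                results[name] = partial_mantel(
                    d_y, d_x, control, n_perm=config.mantel_permutations,
                    seed=np.random.default_rng(rng.integers(2 ** 31)),
                )
            report["stages"]["techniques"] = {
                "n_openings": len(openings),
                "mantel": results,
            }
    except Exception as err:  # noqa: BLE001 - partial report on any failure
        report["failed"] = {"stage": _last_stage(report), "error": str(err)}
        report["ok"] = False
        _write_report(report, out)
        raise
    report["ok"] = True
    _write_report(report, out)
    return report


def _last_stage(report: dict) -> str:
    stages = list(report["stages"])
    return stages[-1] if stages else "setup"


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
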