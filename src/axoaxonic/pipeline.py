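"""End-to-end pipeline: generate/ingest → scrub → graphs → specialization →
morphology → simulation, with a machine-readable JSON report per stage."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectome import ConnectomeTable, NeuronClass, load_table, scrub
from .lif import build_network, experiment_fig6, experiment_fig7
from .morphology import cable_length, fit_strength_vs_length, read_swc
from .netstats import (
    build_motif_graph, degree_histograms, graph_metrics, input_summary,
    laterality, nt_composition, rich_club,
)
from .specialization import all_profiles, classify_all, exclusive_per_dn, find_threshold
from .synth import GeneratorConfig, generate, generate_skeletons

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    # either CSV inputs ...
    neurons_csv: str | None = None
    connections_csv: str | None = None
    # ... or a synthetic generator
    generator: GeneratorConfig | None = None
    min_strength: int = 6
    with_morphology: bool = True
    with_simulation: bool = True
    sim_trials: int = 3
    sim_duration_ms: float = 1000.0
    out_dir: str = "results"
    seed: int = 0


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if f == f else None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in dependency order.

    Returns the run report (also written to ``out_dir/run_report.json``); a
    stage failure marks the stage and skips its dependents.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": _jsonable(config), "stages": {}}
    t_all = time.perf_counter()

    def _stage(name: str, fn, *deps_ok):
        t0 = time.perf_counter()
        if deps_ok and not all(deps_ok):
            report["stages"][name] = {"status": "skipped", "reason": "upstream failure"}
            return None, False
        try:
            payload = fn()
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                **(payload if isinstance(payload, dict) else {}),
            }
            return payload, True
        except Exception as exc:  # report and continue; caller decides exit code
            report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            return None, False

    table: ConnectomeTable | None = None
    truth = None

    def _ingest():
        nonlocal table, truth
        if config.generator is not None:
            gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
            table, truth = generate(gen_cfg)
            return {"source": "synthetic", "n_neurons": len(table.neurons),
                    "n_connections": len(table.connections)}
        if not config.neurons_csv or not config.connections_csv:
            raise PipelineError("neither generator nor CSV inputs configured")
        table = load_table(config.neurons_csv, config.connections_csv)
        return {"source": config.neurons_csv, "n_neurons": len(table.neurons),
                "n_connections": len(table.connections)}

    _, ok_ingest = _stage("ingest", _ingest)

    scrubbed = None

    def _scrub():
        nonlocal scrubbed
        scrubbed, rep = scrub(table, min_strength=config.min_strength)
        rep.to_json(out / "scrub_report.json")
        return {"report": _jsonable(rep)}

    _, ok_scrub = _stage("scrub", _scrub, ok_ingest)

    def _graphs():
        dn = build_motif_graph(scrubbed, {NeuronClass.DN})
        metrics = graph_metrics(dn)
        rc = rich_club(dn)
        summ = input_summary(scrubbed)
        payload = {
            "dn_dn_metrics": _jsonable(metrics.to_dict()),
            "rich_club": {"peak_k": rc.peak_k, "peak_phi": rc.peak_phi},
            "input_summary": {
                "pearson_r": summ.pearson_r, "r_squared": summ.r_squared,
                "n_dns": len(summ.per_dn),
            },
            "nt_homotypic": nt_composition(dn, "homotypic"),
            "nt_heterotypic": nt_composition(dn, "heterotypic"),
            "laterality": _jsonable(laterality(dn)),
            "degree_histograms": _jsonable(degree_histograms(dn)),
        }
        (out / "graph_metrics.json").write_text(json.dumps(_jsonable(payload), indent=2))
        return payload

    _, ok_graphs = _stage("graphs", _graphs, ok_scrub)

    spec_payload = None

    def _specialization():
        nonlocal spec_payload
        profiles = all_profiles(scrubbed)
        thr = find_threshold([p.dominant_fraction for p in profiles])
        records = classify_all(scrubbed, thr.cutoff)
        n_biased = sum(1 for r in records if r.call == "single_type_biased")
        spec_payload = {
            "cutoff": thr.cutoff, "ks_statistic": thr.ks_statistic, "ks_p": thr.ks_p,
            "n_profiles": len(profiles), "n_single_type_biased": n_biased,
            "exclusive_per_dn": exclusive_per_dn(records),
        }
        (out / "specialization.json").write_text(json.dumps(_jsonable(spec_payload), indent=2))
        return spec_payload

    _, ok_spec = _stage("specialization", _specialization, ok_scrub)

    def _morphology():
        if not config.with_morphology:
            report["stages"]["morphology"] = {"status": "skipped", "reason": "disabled"}
            raise _SkipStage
        swc_dir = out / "skeletons"
        truth_lengths = generate_skeletons(scrubbed, swc_dir, seed=config.seed)
        summ = input_summary(scrubbed)
        strengths = dict(zip(summ.per_dn["neuron_id"], summ.per_dn["total_strength"]))
        points = []
        for nid in truth_lengths:
            if nid in strengths:
                sk = read_swc(swc_dir / f"{nid}.swc")
                points.append((cable_length(sk), strengths[nid]))
        fit = fit_strength_vs_length(points, "linear")
        payload = {"n_skeletons": len(truth_lengths), "linear_r2": fit.r_squared,
                   "pearson_r": fit.pearson_r}
        (out / "morphology.json").write_text(json.dumps(_jsonable(payload), indent=2))
        return payload

    def _simulation():
        if not config.with_simulation:
            report["stages"]["simulation"] = {"status": "skipped", "reason": "disabled"}
            raise _SkipStage
        model = build_network(scrubbed)
        if truth is not None:
            probe = truth.hub_ids[0]
            octet = truth.octet_ids
        else:
            if not model.gf_ids:
                raise PipelineError("no GF-tagged neuron found for simulation probe")
            probe = model.gf_ids[0]
            octet = []
        rep = experiment_fig6(
            model, probe, octet, scenarios=("A", "B"),
            n_trials=config.sim_trials, base_seed=config.seed,
            duration=config.sim_duration_ms,
        )
        payload = {"fig6": _jsonable({"scenarios": rep.scenarios, "comparisons": rep.comparisons})}
        if octet:
            f7 = experiment_fig7(model, probe, octet, duration=1500.0, seed=config.seed)
            payload["fig7_response_probability"] = f7["response_probability"]
        (out / "simulation.json").write_text(json.dumps(_jsonable(payload), indent=2))
        return payload

    class _SkipStage(Exception):
        pass

    for name, fn, dep in (("morphology", _morphology, ok_scrub), ("simulation", _simulation, ok_spec and ok_scrub)):
        t0 = time.perf_counter()
        if not dep:
            report["stages"][name] = {"status": "skipped", "reason": "upstream failure"}
            continue
        try:
            payload = fn()
            report["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
                **(payload if isinstance(payload, dict) else {}),
            }
        except _SkipStage:
            pass
        except Exception as exc:
            report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}

    report["seconds_total"] = round(time.perf_counter() - t_all, 3)
    report["ok"] = all(s.get("status") != "failed" for s in report["stages"].values())
    (out / "run_report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
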