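"""End-to-end orchestration: simulate -> learn -> average -> evaluate
-> intervene -> sensitivity, driven by one YAML config.

Every stage writes its artifacts to the run directory as plain files
(datasets and graphs as CSV, networks as XMLBIF, reports as CSV/JSON),
so externally learned graphs can be spliced into the ensemble between
stages.  A manifest records all seeds and the package version; reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .averaging import average_graphs, count_edges, threshold_sweep
from .cbn import fit_cpts, risk_difference, sensitivity_analysis
from .dataio import read_edge_list, write_cbn, write_dataset, write_graph
from .evaluation import evaluate_all, reports_to_frame
from .schema import build_gdm_schema, schema_from_dict
from .structure_learning import LearnConfig, run_ensemble
from .synthetic import (
    STUDY_N,
    apply_missingness,
    build_ground_truth,
    DEFAULT_GDM_EDGES,
    default_missingness,
    sample_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_config", "demo_config"]

#: Table-4-style watched intervention edges of the study-scale preset.
DEFAULT_WATCHED_EDGES = [
    ("Previous_Bariatric_Surgery", "Change_in_Weight"),
    ("Fasting", "Diet_Only"),
    ("Birth_weight", "NICUadmission"),
    ("Birth_weight", "Pregnancy_Complications"),
    ("History_of_Multiple_Pregnancies", "Trauma_to_baby"),
    ("PHx_GDM", "Gestation_at_diagnosis"),
    ("Parity", "PHx_GDM"),
]


@dataclass
class PipelineConfig:
    n: int = STUDY_N
    seed: int = 0
    dirichlet_alpha: float = 0.5
    missingness: str = "default"          # "default" or "none"
    schema_path: str | None = None        # YAML schema; None -> 62-variable default
    ground_truth_edges: str | None = None  # edge CSV; None -> built-in knowledge graph
    learners: list[dict] = field(default_factory=lambda: [
        {"algorithm": a} for a in ("hc", "tabu", "pc_stable", "gs", "mmhc")
    ])
    external_graphs: list[str] = field(default_factory=list)
    threshold: int = 4
    sweep_thresholds: list[int] = field(default_factory=lambda: [4, 6, 8, 10, 12])
    watched_edges: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_WATCHED_EDGES)
    )
    interventions: list[dict] = field(default_factory=list)
    sensitivity: list[dict] = field(default_factory=list)
    ci_bootstrap: int = 0                 # 0 disables bootstrap CIs
    out_dir: str = "runs/demo"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        errors = _validate_raw(raw, base=Path(path).parent)
        if errors:
            raise ValueError("invalid config:\n" + "\n".join(errors))
        if "watched_edges" in raw:
            raw["watched_edges"] = [tuple(e) for e in raw["watched_edges"]]
        return cls(**raw)


def demo_config(out_dir: str = "runs/demo", seed: int = 0, n: int = STUDY_N) -> PipelineConfig:
    """The study-scale demo: full cohort, 5 learners, one intervention
    on neonatal intensive-care admission, one sensitivity run."""
    return PipelineConfig(
        n=n,
        seed=seed,
        out_dir=out_dir,
        interventions=[{
            "variable": "Birth_weight", "x1": "3", "x0": "2",
            "target": "NICUadmission", "target_state": "1",
        }],
        sensitivity=[{"target": "NICUadmission", "delta": 0.05}],
    )


_KNOWN_KEYS = {
    "n", "seed", "dirichlet_alpha", "missingness", "schema_path",
    "ground_truth_edges", "learners", "external_graphs", "threshold",
    "sweep_thresholds", "watched_edges", "interventions", "sensitivity",
    "ci_bootstrap", "out_dir",
}


def _validate_raw(raw: dict, base: Path) -> list[str]:
    errors = []
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown field {key!r}")
    if "n" in raw and (not isinstance(raw["n"], int) or raw["n"] < 1):
        errors.append("n: must be a positive integer")
    if "threshold" in raw and (not isinstance(raw["threshold"], int) or raw["threshold"] < 1):
        errors.append("threshold: must be an integer >= 1")
    if "missingness" in raw and raw["missingness"] not in ("default", "none"):
        errors.append("missingness: must be 'default' or 'none'")
    sweep = raw.get("sweep_thresholds")
    if sweep is not None and list(sweep) != sorted(sweep):
        errors.append("sweep_thresholds: must be ascending")
    for key in ("schema_path", "ground_truth_edges"):
        p = raw.get(key)
        if p is not None and not (base / p).exists() and not Path(p).exists():
            errors.append(f"{key}: path {p!r} does not exist")
    for p in raw.get("external_graphs", []):
        if not (base / p).exists() and not Path(p).exists():
            errors.append(f"external_graphs: path {p!r} does not exist")
    for cfg in raw.get("learners", []):
        try:
            LearnConfig(**cfg)
        except (TypeError, ValueError) as exc:
            errors.append(f"learners: {cfg!r}: {exc}")
    return errors


def validate_config(path: str | Path) -> list[str]:
    """Line-level error report for a config file; empty means valid."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return _validate_raw(raw, base=Path(path).parent)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "graphs").mkdir(exist_ok=True)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrap

    # ---- simulate ---------------------------------------------------
    def _simulate():
        if config.schema_path:
            schema = schema_from_dict(yaml.safe_load(Path(config.schema_path).read_text()))
        else:
            schema = build_gdm_schema()
        if config.ground_truth_edges:
            ref = read_edge_list(config.ground_truth_edges)
            edges = sorted(ref.directed)
        else:
            edges = list(DEFAULT_GDM_EDGES)
        miss = default_missingness(schema) if config.missingness == "default" else {}
        model = build_ground_truth(
            schema, edges, seed=config.seed, dirichlet_alpha=config.dirichlet_alpha,
            missingness=miss,
        )
        complete = sample_dataset(model, config.n, seed=config.seed + 1)
        data = apply_missingness(complete, model, seed=config.seed + 2)
        write_dataset(data, out / "dataset.csv")
        write_graph(model.dag, out / "ground_truth.csv")
        write_cbn(model.to_cbn(), out / "ground_truth.xmlbif")
        return model, data

    model, data = stage("simulate")(_simulate)

    # ---- learn ------------------------------------------------------
    def _learn():
        configs = []
        for j, cfg in enumerate(config.learners):
            cfg = dict(cfg)
            cfg.setdefault("seed", config.seed + 10 + j)
            configs.append(LearnConfig(**cfg))
        externals = [
            (Path(p).stem, read_edge_list(p)) for p in config.external_graphs
        ]
        members = run_ensemble(data, configs, externals)
        for m in members:
            write_graph(m.graph, out / "graphs" / f"{m.label}.csv")
        return members

    members = stage("learn")(_learn)

    # ---- average ----------------------------------------------------
    def _average():
        table = count_edges([m.graph for m in members])
        table.to_frame().to_csv(out / "edge_frequencies.csv", index=False)
        averaged, audit = average_graphs(table, config.threshold)
        write_graph(averaged, out / "averaged.csv")
        (out / "audit.json").write_text(
            json.dumps([e.to_dict() for e in audit], indent=1) + "\n"
        )
        retention = threshold_sweep(table, config.sweep_thresholds, config.watched_edges)
        retention.to_csv(out / "retention.csv", index=False)
        return averaged

    averaged = stage("average")(_average)

    # ---- evaluate ---------------------------------------------------
    def _evaluate():
        graphs = [(m.label, m.graph) for m in members] + [("Model Average", averaged)]
        reports = evaluate_all(
            graphs, model.dag, data,
            ci_bootstrap=config.ci_bootstrap or None, seed=config.seed + 100,
        )
        reports_to_frame(reports).to_csv(out / "metrics.csv", index=False)
        return reports

    stage("evaluate")(_evaluate)

    # ---- intervene / sensitivity ------------------------------------
    def _inference():
        cbn = fit_cpts(averaged, data, alpha=1.0)
        write_cbn(cbn, out / "averaged.xmlbif")
        results = []
        for q in config.interventions:
            res = risk_difference(
                cbn, q["variable"], str(q["x1"]), str(q["x0"]),
                q["target"], str(q["target_state"]),
            )
            results.append(res.to_dict())
        (out / "interventions.json").write_text(json.dumps(results, indent=1) + "\n")
        reports = []
        for s in config.sensitivity:
            rep = sensitivity_analysis(
                cbn, s["target"], delta=float(s.get("delta", 0.05)),
                evidence=s.get("evidence"),
            )
            reports.append(rep.to_dict())
        (out / "sensitivity.json").write_text(json.dumps(reports, indent=1) + "\n")

    stage("inference")(_inference)

    manifest = {
        "package": "gdmcbn",
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": {
            "sampling": config.seed + 1,
            "missingness": config.seed + 2,
            "learners": [config.seed + 10 + j for j in range(len(config.learners))],
            "bootstrap": config.seed + 100,
        },
        "config": {
            k: (list(map(list, v)) if k == "watched_edges" else v)
            for k, v in vars(config).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
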