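"""End-to-end orchestration: simulate -> outcomes -> encode -> screen ->
train/select -> DCV -> pair search -> graph -> report.

Every stage writes plain-text artifacts into the output directory and the
run closes with a manifest (inputs, seeds, checksums) so each number in
the report is traceable to a file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv as _cv
from . import graph as _graph
from . import outcomes as _outcomes
from . import pairsearch as _ps
from . import pwlnet as _net
from . import screen as _screen
from .cohort import read_cohort, write_cohort
from .encoding import build_design_matrix, write_encoded
from .errors import ConfigurationError
from .synthetic import CohortSpec, PlantedEffect, generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "outcomes", "encode", "screen", "train", "dcv", "pairsearch", "graph", "report",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, YAML-serialisable.

    Thresholds default to the analysis constants: rapid cut -10 %/yr,
    moderate cut -3.3 %/yr, detection fraction 0.5, importance 0.25
    (auto) / 0.06 (curated), candidate cap 50, high-AUC 0.8 (PWL) / 0.9
    (HCLR), graph pruning 0.8 / 500.
    """

    out_dir: str = "decliner_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    cohort: dict = field(default_factory=lambda: {
        "n_samples": 135,
        "n_plasma_metab": 30,
        "n_urine_metab": 30,
        "n_clinical": 12,
        "planted": True,  # plant one univariate and one ratio marker
    })
    detection_fraction: float = 0.5
    importance_auto: float = 0.25
    importance_curated: float = 0.06
    curated: list[str] = field(default_factory=list)
    feature_cap: int = 50
    dcv_k: int = 10
    dcv_models: list[str] = field(default_factory=lambda: list(_cv.MODEL_NAMES))
    # the explanation fit runs to convergence on the full data (no early
    # stopping): importance scores need a converged model, while held-out
    # performance is the DCV stage's job
    net: dict = field(default_factory=lambda: {"hidden_layers": 2, "width": 16,
                                               "max_epochs": 300, "patience": 0,
                                               "validation_fraction": 0.0})
    pair_max_features: int = 12
    pwl_high_auc: float = _ps.PWL_HIGH_AUC
    hclr_high_auc: float = _ps.HCLR_HIGH_AUC
    include_raw: bool = True
    model_ceiling: int = 2_000_000
    graph_prune_pwl: float = _graph.PWL_PRUNE
    graph_prune_hclr: float = _graph.HCLR_PRUNE

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages {unknown}")
        for name in ("detection_fraction", "importance_auto", "importance_curated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.feature_cap < 2:
            raise ConfigurationError("feature_cap must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_spec(cfg: PipelineConfig) -> CohortSpec:
    c = dict(cfg.cohort)
    planted = []
    if c.pop("planted", False):
        planted = [
            PlantedEffect("univariate_shift", ("MP0000",), 2.0, +1),
            PlantedEffect("ratio", ("MU0000", "MU0001"), 3.0, +1),
        ]
    return CohortSpec(seed=cfg.seed, planted_markers=planted, **c)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}, "timings_s": {}}
    config.to_yaml(out / "config.yaml")

    def register(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage_enabled(s: str) -> bool:
        return s in config.stages

    cohort = truth = None
    t0 = time.time()

    if stage_enabled("simulate"):
        spec = _cohort_spec(config)
        cohort, _, truth = generate_cohort(spec)
        paths = write_cohort(cohort, out / "cohort")
        for k, p in paths.items():
            register(f"cohort/{k}", p)
        manifest["stages"].append("simulate")
    else:
        cohort = read_cohort(out / "cohort")
    manifest["timings_s"]["simulate"] = round(time.time() - t0, 3)

    outc = _outcomes.derive_outcomes(cohort.egfr)
    y = _outcomes.rapid_labels(outc, cohort.sample_ids)
    if stage_enabled("outcomes"):
        p = out / "outcomes.tsv"
        outc.to_csv(p, sep="\t", index=False)
        register("outcomes", p)
        manifest["stages"].append("outcomes")

    datasets = {tag: build_design_matrix(cohort, dataset_tag=tag)
                for tag in ("metabolomic", "clinical", "combined")}
    if stage_enabled("encode"):
        for tag, em in datasets.items():
            p = out / f"encoded_{tag}.tsv"
            write_encoded(em, p)
            register(f"encoded/{tag}", p)
        manifest["stages"].append("encode")

    if stage_enabled("screen"):
        t = time.time()
        scr = _screen.run_screen(cohort, y, min_fraction=config.detection_fraction)
        p = out / "screen.tsv"
        scr.to_csv(p, sep="\t", index=False)
        register("screen", p)
        manifest["stages"].append("screen")
        manifest["timings_s"]["screen"] = round(time.time() - t, 3)

    selected = None
    if stage_enabled("train"):
        t = time.time()
        em = datasets["combined"]
        net_cfg = _net.PWLNetConfig(**config.net)
        model = _net.fit_pwl_net(em, y, hyper=net_cfg, seed=config.seed)
        _net.save_model(model, out / "pwl_net_model.json")
        register("model", out / "pwl_net_model.json")
        report = _net.importance_scores(model, em, y)
        p = out / "importance.tsv"
        report.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        register("importance", p)
        selected = _net.select_features(
            report,
            auto_threshold=config.importance_auto,
            curated=[c for c in config.curated if c in set(report.table["feature"])],
            curated_threshold=config.importance_curated,
            cap=config.feature_cap,
        )
        p = out / "selected_features.tsv"
        selected.to_csv(p, sep="\t", index=False, float_format="%.6g")
        register("selected", p)
        manifest["stages"].append("train")
        manifest["timings_s"]["train"] = round(time.time() - t, 3)

    if stage_enabled("dcv"):
        t = time.time()
        table, results = _cv.compare_models(
            datasets, y, models=config.dcv_models, k=config.dcv_k, seed=config.seed
        )
        p = out / "dcv_table.tsv"
        table.to_csv(p, sep="\t", index=False)
        register("dcv_table", p)
        folds = pd.concat(
            [r.per_fold.assign(model=r.model, dataset=r.dataset_tag) for r in results]
        )
        p = out / "dcv_folds.tsv"
        folds.to_csv(p, sep="\t", index=False, float_format="%.6g")
        register("dcv_folds", p)
        manifest["stages"].append("dcv")
        manifest["timings_s"]["dcv"] = round(time.time() - t, 3)

    aggs = {}
    if stage_enabled("pairsearch"):
        t = time.time()
        if selected is None:
            raise ConfigurationError("pairsearch requires the train stage (feature selection)")
        names = list(selected["feature"].head(config.pair_max_features))
        sub = datasets["combined"].select(names)
        for kind, thr in (("PWL", config.pwl_high_auc), ("HCLR", config.hclr_high_auc)):
            if kind == "PWL" and len(_ps.pwl_eligible(sub)) < 2:
                logger.warning("fewer than 2 PWL-eligible features; skipping PWL search")
                continue
            agg = _ps.run_pair_search(
                sub, y, kind, high_auc_threshold=thr,
                include_raw=config.include_raw, model_ceiling=config.model_ceiling,
                seed=config.seed,
            )
            aggs[kind] = agg
            freq = _ps.frequency_table(agg, feature_names=names)
            p = out / f"frequency_{kind.lower()}.tsv"
            freq.to_csv(p, sep="\t", index=False, float_format="%.6g")
            register(f"frequency/{kind}", p)
            retained = pd.DataFrame(
                [
                    {
                        "kind": r.kind,
                        "inputs": " | ".join(
                            i.label if isinstance(i, _ps.HandcraftedFeature) else str(i)
                            for i in r.inputs
                        ),
                        "involved": ";".join(r.involved),
                        "auc": r.auc,
                    }
                    for r in sorted(agg.retained, key=lambda r: -r.auc)
                ]
            )
            p = out / f"high_auc_models_{kind.lower()}.tsv"
            retained.to_csv(p, sep="\t", index=False, float_format="%.6g")
            register(f"high_auc/{kind}", p)
        manifest["stages"].append("pairsearch")
        manifest["timings_s"]["pairsearch"] = round(time.time() - t, 3)

    if stage_enabled("graph") and aggs:
        for kind, agg in aggs.items():
            thr = config.graph_prune_pwl if kind == "PWL" else config.graph_prune_hclr
            g = _graph.graph_from_search(agg, threshold=thr)
            p = _graph.export_graph(g, out / f"interaction_{kind.lower()}.tsv", "tsv")
            register(f"graph/{kind}", p)
            _graph.export_graph(g, out / f"interaction_{kind.lower()}.graphml", "graphml")
            hub = _graph.hub_feature(g)
            (out / f"hub_{kind.lower()}.txt").write_text(f"{hub or 'none'}\n")
            register(f"hub/{kind}", out / f"hub_{kind.lower()}.txt")
        manifest["stages"].append("graph")

    if stage_enabled("report"):
        text = render_report(out)
        p = out / "report.md"
        p.write_text(text)
        register("report", p)
        manifest["stages"].append("report")

    manifest["timings_s"]["total"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _read(path: Path) -> pd.DataFrame | None:
    return pd.read_csv(path, sep="\t") if path.exists() else None


def render_report(artifact_dir: str | Path) -> str:
    """Human-readable summary assembled from the artifact files.

    Regeneration from the same artifacts is idempotent; a missing
    artifact is listed as absent rather than failing the report.
    """
    out = Path(artifact_dir)
    lines = ["# Rapid-decliner biomarker discovery report", ""]

    outc = _read(out / "outcomes.tsv")
    lines.append("## Cohort outcome")
    if outc is None:
        lines.append("artifact absent: outcomes.tsv")
    else:
        counts = outc["group"].value_counts().sort_index()
        lines.append(f"{len(outc)} samples; decline groups: "
                     + ", ".join(f"group{g}={counts.get(g, 0)}" for g in (1, 2, 3, 4))
                     + f"; rapid decliners: {int(outc['rapid'].sum())}")
    lines.append("")

    scr = _read(out / "screen.tsv")
    lines.append("## Univariate screen (top 10 by AUC)")
    if scr is None:
        lines.append("artifact absent: screen.tsv")
    else:
        lines.append(scr.head(10).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")

    dcv = _read(out / "dcv_table.tsv")
    lines.append("## Double cross-validation model comparison")
    lines.append(dcv.to_string(index=False) if dcv is not None else "artifact absent: dcv_table.tsv")
    lines.append("")

    sel = _read(out / "selected_features.tsv")
    lines.append("## Selected biomarker candidates")
    if sel is None:
        lines.append("artifact absent: selected_features.tsv")
    else:
        lines.append(f"{len(sel)} features selected")
        lines.append(sel.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")

    for kind in ("pwl", "hclr"):
        freq = _read(out / f"frequency_{kind}.tsv")
        lines.append(f"## {kind.upper()} pair-model frequency table")
        if freq is None:
            lines.append(f"artifact absent: frequency_{kind}.tsv (pair search disabled or skipped)")
        else:
            high = _read(out / f"high_auc_models_{kind}.tsv")
            n_high = 0 if high is None else len(high)
            if n_high == 0:
                lines.append("zero models above the high-AUC threshold")
            lines.append(freq.head(10).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("")

    lines.append("## Interaction graphs")
    for kind in ("pwl", "hclr"):
        hub_p = out / f"hub_{kind}.txt"
        edges = _read(out / f"interaction_{kind}.tsv")
        if edges is None:
            lines.append(f"{kind.upper()}: artifact absent")
        else:
            hub = hub_p.read_text().strip() if hub_p.exists() else "none"
            lines.append(f"{kind.upper()}: {len(edges)} edges above threshold; hub feature: {hub}")
    lines.append("")
    return "\n".join(lines)
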