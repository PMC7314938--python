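"""End-to-end orchestration of the two-stage analysis.

A :class:`PipelineConfig` names either on-disk inputs (three modality
matrices plus a clinical table) or a synthetic spec, and fixes every knob of
the run: the MMI estimator settings, the selection rule and its parameter
(the hand-off point between variable selection and network modeling), the
network score settings, and the post-hoc thresholds.  Every artifact records
the config hash so intermediates from different runs cannot be mixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .bn import ScoreConfig, export_dot, learn_structure
from .datamodel import (
    DataModelError,
    Modality,
    MultiOmicsDataset,
    assemble_dataset,
    dichotomize_survival,
    encode_tumor_status,
    load_clinical,
    load_modality,
)
from .discretize import discretize_dataset
from .mmi import MMIConfig, rank_genes, select_by_threshold, select_top_cdf
from .posthoc import extract_mn, posthoc_table
from .synthetic import SyntheticSpec, generate, write_ground_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "InputPaths", "run_pipeline", "config_hash", "check_run_meta"]


@dataclass(frozen=True)
class InputPaths:
    s_matrix: str
    e_matrix: str
    m_matrix: str
    clinical: str


@dataclass(frozen=True)
class PipelineConfig:
    inputs: InputPaths | None = None
    synthetic: SyntheticSpec | None = None
    outcome: str = "tumor_status"  # tumor_status | survival2y
    mmi: MMIConfig = field(default_factory=MMIConfig)
    selection_rule: str = "cdf_quantile"  # cdf_quantile | mmi_threshold
    selection_parameter: float = 0.995
    score: ScoreConfig = field(default_factory=ScoreConfig)
    mn_radius: int = 1
    alpha: float = 0.05
    min_count: int = 5
    outdir: str = "mmibn_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of inputs / synthetic must be given")
        if self.outcome not in ("tumor_status", "survival2y"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.selection_rule not in ("cdf_quantile", "mmi_threshold"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("inputs"):
            raw["inputs"] = InputPaths(**raw["inputs"])
        if raw.get("synthetic"):
            syn = dict(raw["synthetic"])
            if "planted_effects" in syn:
                from .synthetic import PlantedEffect

                syn["planted_effects"] = tuple(
                    PlantedEffect(**e) for e in syn["planted_effects"]
                )
            if "inter_gene_edges" in syn:
                syn["inter_gene_edges"] = tuple(
                    tuple(e) for e in syn["inter_gene_edges"]
                )
            raw["synthetic"] = SyntheticSpec(**syn)
        if raw.get("mmi"):
            raw["mmi"] = MMIConfig(**raw["mmi"])
        if raw.get("score"):
            raw["score"] = ScoreConfig(**raw["score"])
        return cls(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    canonical = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def check_run_meta(outdir: Path, cfg_hash: str) -> None:
    """Refuse to mix artifacts produced under a different configuration."""
    meta_path = outdir / "run_meta.json"
    if meta_path.exists():
        existing = json.loads(meta_path.read_text()).get("config_hash")
        if existing != cfg_hash:
            raise DataModelError(
                f"output directory {outdir} holds artifacts from a different "
                f"config (hash {existing} != {cfg_hash})"
            )
    else:
        outdir.mkdir(parents=True, exist_ok=True)
        meta_path.write_text(json.dumps({"config_hash": cfg_hash}, indent=2))


def _load_input_dataset(cfg: PipelineConfig) -> MultiOmicsDataset:
    paths = cfg.inputs
    S = load_modality(paths.s_matrix, Modality.S)
    E = load_modality(paths.e_matrix, Modality.E)
    M = load_modality(paths.m_matrix, Modality.M)
    records = load_clinical(paths.clinical)
    if cfg.outcome == "tumor_status":
        outcome = encode_tumor_status(records)
    else:
        outcome = dichotomize_survival(records)
    return assemble_dataset(S, E, M, outcome)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the artifact paths."""
    outdir = Path(cfg.outdir)
    chash = config_hash(cfg)
    check_run_meta(outdir, chash)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    try:
        stage("dataset")
        if cfg.synthetic is not None:
            ds, truth = generate(cfg.synthetic)
            write_ground_truth(truth, outdir / "ground_truth.json")
            artifacts["ground_truth"] = outdir / "ground_truth.json"
        else:
            ds = _load_input_dataset(cfg)
        ds.write(outdir / "dataset")
        artifacts["dataset"] = outdir / "dataset"
        done("dataset")

        stage("rank")
        table = rank_genes(ds, cfg.mmi)
        table.to_tsv(outdir / "rank_table.tsv")
        artifacts["rank_table"] = outdir / "rank_table.tsv"
        done("rank")

        stage("select")
        if cfg.selection_rule == "cdf_quantile":
            selection = select_top_cdf(table, cfg.selection_parameter)
        else:
            selection = select_by_threshold(table, cfg.selection_parameter)
        if not selection.selected_genes:
            raise DataModelError(
                "selection produced no genes; relax the selection parameter"
            )
        selection.write(outdir / "selected_genes.txt")
        artifacts["selected_genes"] = outdir / "selected_genes.txt"
        done("select")

        stage("discretize")
        disc = discretize_dataset(ds, selection.selected_genes)
        disc.to_tsv(outdir / "discretized.tsv")
        artifacts["discretized"] = outdir / "discretized.tsv"
        done("discretize")

        stage("learn")
        score_cfg = ScoreConfig(**{**asdict(cfg.score), "seed": cfg.seed})
        model = learn_structure(disc, score_cfg)
        model.to_json(outdir / "bn.json")
        (outdir / "bn.dot").write_text(export_dot(model))
        artifacts["bn_json"] = outdir / "bn.json"
        artifacts["bn_dot"] = outdir / "bn.dot"
        done("learn")

        stage("mn")
        mn = extract_mn(model, ds.outcome.name, cfg.mn_radius)
        sub = _mn_submodel(model, mn)
        (outdir / "mn.dot").write_text(export_dot(sub, graph_name="mn"))
        artifacts["mn_dot"] = outdir / "mn.dot"
        done("mn")

        stage("posthoc")
        report = posthoc_table(ds, mn, alpha=cfg.alpha, min_count=cfg.min_count)
        report.to_tsv(outdir / "posthoc.tsv")
        artifacts["posthoc"] = outdir / "posthoc.tsv"
        done("posthoc")
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", current["stage"], exc)
        if isinstance(exc, (DataModelError, ValueError, KeyError, OSError)):
            raise DataModelError(f"stage {current['stage']!r}: {exc}") from exc
        raise RuntimeError(f"stage {current['stage']!r}: {exc}") from exc

    log = {
        "config": asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "version": __version__,
        "timings_s": timings,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    artifacts["run_log"] = outdir / "run_log.json"
    return artifacts


def _mn_submodel(model, mn):
    from .bn import BayesianNetworkModel

    keep = set(mn.members) | {mn.center}
    edges = [(u, v) for u, v in model.edges if u in keep and v in keep]
    sub = BayesianNetworkModel(
        nodes=sorted(keep),
        edges=edges,
        log_score=float("nan"),
        edge_strengths={e: model.edge_strengths.get(e, 0.0) for e in edges},
        config=model.config,
    )
    return sub
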