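"""Staged pipeline with artifact caching and hash integrity checks.

Stages: ``simulate`` (synthetic benchmark TSVs) -> ``embed`` (node2vec
matrix) -> ``encode`` (per-variant encoding matrices) -> ``cv``
(cross-validated metrics). Every artifact's sha256 goes into
``manifest.json``; a stage is skipped when its config and its inputs'
hashes are unchanged, and refuses to run when an input file no longer
matches the hash recorded for it (stale or corrupted artifact).

Per-stage seeds derive from the global seed by stable hashing of the stage
name, so adding or rerunning one stage never shifts another's randomness.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluation as ev
from . import training as tr
from .artifacts import config_hash, content_hash, load_matrix, save_matrix
from .encoding import EncodingBundle
from .graph_data import (
    label_pairs,
    load_disease_associations,
    load_edge_list,
    load_pair_table,
)
from .model import ComorbidityModel
from .node_embedding import WalkConfig, generate_walks, train_node_embeddings
from .simulate import SimConfig, make_benchmark
from .transformer import ModelConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "embed", "encode", "cv")


@dataclass
class RunConfig:
    """Flat pipeline configuration (overridable per stage)."""

    out_dir: str
    seed: int = 0
    mode: str = "RR1"
    variants: tuple[str, ...] = ("NoPE", "LPE", "SPE")
    folds: int = 10
    gpe_d: int = 8
    sim: dict = field(default_factory=dict)
    walk: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "variants" in data:
            data["variants"] = tuple(data["variants"])
        return cls(**data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


class Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data: dict = {"artifacts": {}, "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record_artifact(self, name: str, path: Path, stage: str) -> None:
        self.data["artifacts"][name] = {
            "path": path.name,
            "sha256": content_hash(path),
            "stage": stage,
        }

    def record_stage(self, stage: str, cfg_hash: str, inputs: dict[str, str]) -> None:
        self.data["stages"][stage] = {"config": cfg_hash, "inputs": inputs}

    def artifact_hash(self, name: str) -> str | None:
        entry = self.data["artifacts"].get(name)
        return entry["sha256"] if entry else None

    def verify_input(self, name: str, path: Path) -> None:
        """Fail if `path` no longer matches the hash recorded for artifact `name`."""
        recorded = self.artifact_hash(name)
        if recorded is None:
            raise RuntimeError(
                f"artifact {name!r} missing from manifest; run its stage first"
            )
        actual = content_hash(path)
        if actual != recorded:
            raise RuntimeError(
                f"artifact {name!r} ({path}) does not match its recorded hash; "
                "stale or corrupted — regenerate its stage"
            )

    def stage_unchanged(self, stage: str, cfg_hash: str,
                        inputs: dict[str, str], outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry["config"] != cfg_hash or entry["inputs"] != inputs:
            return False
        for out in outputs:
            if not out.exists():
                return False
            name = out.name
            rec = self.artifact_hash(name)
            if rec is None or content_hash(out) != rec:
                return False
        return True

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _walk_config(cfg: RunConfig) -> WalkConfig:
    return WalkConfig(seed=stage_seed(cfg.seed, "embed"), **cfg.walk)


def _paths(out: Path, cfg: RunConfig) -> dict[str, Path]:
    p = {
        "edges.tsv": out / "edges.tsv",
        "associations.tsv": out / "associations.tsv",
        "pairs.tsv": out / "pairs.tsv",
        "embeddings.tsv": out / "embeddings.tsv",
    }
    for v in cfg.variants:
        p[f"encoding_{v.lower()}.tsv"] = out / f"encoding_{v.lower()}.tsv"
        p[f"metrics_{v.lower()}.json"] = out / f"metrics_{v.lower()}.json"
    return p


def stage_simulate(cfg: RunConfig, out: Path, manifest: Manifest) -> list[Path]:
    sim = SimConfig(seed=stage_seed(cfg.seed, "simulate"), **cfg.sim)
    make_benchmark(sim, out_dir=out)
    outs = [out / n for n in ("edges.tsv", "associations.tsv", "pairs.tsv", "truth.tsv")]
    for o in outs:
        manifest.record_artifact(o.name, o, "simulate")
    return outs


def stage_embed(cfg: RunConfig, out: Path, manifest: Manifest) -> list[Path]:
    edges = out / "edges.tsv"
    manifest.verify_input("edges.tsv", edges)
    g = load_edge_list(edges)
    wc = _walk_config(cfg)
    walks = generate_walks(g, wc)
    M = train_node_embeddings(walks, wc, n_nodes=g.n_nodes)
    path = out / "embeddings.tsv"
    save_matrix(path, M, {
        "kind": "node_embedding",
        "walk_config": wc.to_dict(),
        "nodes": content_hash(edges),
    })
    manifest.record_artifact(path.name, path, "embed")
    return [path]


def _build_model(cfg: RunConfig, out: Path, variant: str) -> ComorbidityModel:
    g = load_edge_list(out / "edges.tsv")
    dm = load_disease_associations(out / "associations.tsv", g)
    pairs = load_pair_table(out / "pairs.tsv", dm)
    M, _ = load_matrix(out / "embeddings.tsv")
    wc = _walk_config(cfg)
    d_model = M.shape[1] + (cfg.gpe_d if variant == "SPE" else 0)
    mc = ModelConfig(d_model=d_model, **cfg.model)
    return ComorbidityModel(
        g, dm, pairs, mode=cfg.mode, variant=variant,
        walk_config=wc, model_config=mc, gpe_d=cfg.gpe_d, node_embedding=M,
    )


def stage_encode(cfg: RunConfig, out: Path, manifest: Manifest) -> list[Path]:
    for name in ("edges.tsv", "associations.tsv", "embeddings.tsv"):
        manifest.verify_input(name, out / name)
    outs = []
    input_hashes = {n: content_hash(out / n)
                    for n in ("edges.tsv", "associations.tsv", "embeddings.tsv")}
    for variant in cfg.variants:
        model = _build_model(cfg, out, variant)
        bundle = model.encodings()
        path = out / f"encoding_{variant.lower()}.tsv"
        save_matrix(path, bundle.E, {
            "kind": "encoding",
            "variant": variant,
            "gpe_d": cfg.gpe_d,
            "inputs": input_hashes,
        })
        manifest.record_artifact(path.name, path, "encode")
        outs.append(path)
    return outs


def stage_cv(cfg: RunConfig, out: Path, manifest: Manifest) -> list[Path]:
    for name in ("edges.tsv", "associations.tsv", "pairs.tsv"):
        manifest.verify_input(name, out / name)
    g = load_edge_list(out / "edges.tsv")
    dm = load_disease_associations(out / "associations.tsv", g)
    raw = load_pair_table(out / "pairs.tsv", dm)
    ds = label_pairs(raw, cfg.mode)
    seed = stage_seed(cfg.seed, "cv")
    plan = ev.stratified_folds(ds.labels, k=cfg.folds, seed=seed)
    outs = []
    for variant in cfg.variants:
        enc_path = out / f"encoding_{variant.lower()}.tsv"
        manifest.verify_input(enc_path.name, enc_path)
        E, meta = load_matrix(enc_path)
        bundle = EncodingBundle(variant=variant, E=E)
        tokens = tr.disease_tokens(bundle, dm)
        mc = ModelConfig(d_model=E.shape[1], **cfg.model)
        run = tr.TrainRun(seed=seed, **cfg.train)
        report = tr.cross_validate(ds, tokens, mc, run, plan, variant=variant)
        path = out / f"metrics_{variant.lower()}.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        manifest.record_artifact(path.name, path, "cv")
        outs.append(path)
    return outs


_STAGE_FN = {
    "simulate": stage_simulate,
    "embed": stage_embed,
    "encode": stage_encode,
    "cv": stage_cv,
}

_STAGE_INPUTS = {
    "simulate": [],
    "embed": ["edges.tsv"],
    "encode": ["edges.tsv", "associations.tsv", "embeddings.tsv"],
    "cv": ["edges.tsv", "associations.tsv", "pairs.tsv"],
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest mapping (also written to manifest.json). Raises on
    an unknown stage or a hash-integrity failure.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out)
    for stage in ordered:
        cfg_hash = config_hash({"stage": stage, "run": cfg.to_dict()})
        inputs = {}
        ready = True
        for name in _STAGE_INPUTS[stage]:
            p = out / name
            if not p.exists():
                ready = False
                break
            inputs[name] = content_hash(p)
        if stage == "cv":
            for v in cfg.variants:
                p = out / f"encoding_{v.lower()}.tsv"
                if p.exists():
                    inputs[p.name] = content_hash(p)
        expected = {
            "simulate": [out / n for n in ("edges.tsv", "associations.tsv", "pairs.tsv", "truth.tsv")],
            "embed": [out / "embeddings.tsv"],
            "encode": [out / f"encoding_{v.lower()}.tsv" for v in cfg.variants],
            "cv": [out / f"metrics_{v.lower()}.json" for v in cfg.variants],
        }[stage]
        if ready and manifest.stage_unchanged(stage, cfg_hash, inputs, expected):
            logger.info("stage %s: unchanged, skipped", stage)
            continue
        logger.info("stage %s: running", stage)
        _STAGE_FN[stage](cfg, out, manifest)
        manifest.record_stage(stage, cfg_hash, inputs if ready else {
            name: content_hash(out / name)
            for name in _STAGE_INPUTS[stage] if (out / name).exists()
        })
        manifest.save()
    manifest.save()
    with open(out / "run_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
    return manifest.data
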