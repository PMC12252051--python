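"""End-to-end orchestration: simulate -> preprocess -> train -> embed ->
cluster -> explain, with per-stage artifact caching and a machine-readable
summary.

Every stage writes its artifact into the run directory; a rerun with
``resume=True`` loads whatever artifacts already exist, so the pipeline can
be resumed from any completed stage.  All randomness derives from the
single ``PipelineConfig.seed``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import clustering, explain, io, pca, preprocessing, synthetic
from . import model as model_mod
from .schema import DEFAULT_SCHEMA, REGIONS
from .types import GaitCycleInstance

log = logging.getLogger("gaitlens")


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    preprocess: preprocessing.PreprocessConfig = field(
        default_factory=preprocessing.PreprocessConfig)
    model: Optional[model_mod.ModelConfig] = None   # n_classes filled from data
    train: model_mod.TrainConfig = field(default_factory=model_mod.TrainConfig)
    k: Optional[int] = None                         # default: number of classes
    n_init: int = 10
    regular_class: str = "none"
    region_weights: Optional[dict[str, float]] = None
    feature_mode: str = "vector"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "class_list" in c:
                c["class_list"] = tuple(
                    synthetic.PathologySpec(**spec) for spec in c["class_list"])
            kw["cohort"] = synthetic.CohortConfig(**c)
        if "preprocess" in raw:
            kw["preprocess"] = preprocessing.PreprocessConfig(**raw["preprocess"])
        if "model" in raw:
            m = dict(raw["model"])
            if "channels_per_block" in m:
                m["channels_per_block"] = tuple(m["channels_per_block"])
            kw["model"] = model_mod.ModelConfig(**m)
        if "train" in raw:
            t = dict(raw["train"])
            if "split" in t:
                t["split"] = tuple(t["split"])
            kw["train"] = model_mod.TrainConfig(**t)
        for key in ("k", "n_init", "regular_class", "region_weights",
                    "feature_mode", "seed"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v
        return clean(asdict(self))


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)
            return False
    return _Timer()


def _instances_to_npz(instances: list[GaitCycleInstance], path: Path) -> None:
    np.savez(path,
             velocities=np.stack([i.velocities for i in instances]),
             subjects=np.array([i.subject_id for i in instances]),
             labels=np.array([i.class_label or "" for i in instances]),
             ids=np.array([i.instance_id for i in instances]))


def _instances_from_npz(path: Path) -> list[GaitCycleInstance]:
    d = np.load(path, allow_pickle=False)
    out = []
    for v, s, l, i in zip(d["velocities"], d["subjects"], d["labels"], d["ids"]):
        out.append(GaitCycleInstance(velocities=v, subject_id=str(s),
                                     class_label=str(l) or None,
                                     instance_id=str(i)))
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 resume: bool = False) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``summary.json`` in the run directory)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    schema = DEFAULT_SCHEMA

    stage = "simulate"
    try:
        cohort_path = out / "cohort.parquet"
        with _timed(stage):
            if resume and cohort_path.exists():
                seqs = io.read_sequences(cohort_path, "parquet")
            else:
                seqs = synthetic.generate_cohort(config.cohort)
                io.write_sequences(seqs, cohort_path, "parquet")

        stage = "preprocess"
        inst_path = out / "instances.npz"
        with _timed(stage):
            if resume and inst_path.exists():
                instances = _instances_from_npz(inst_path)
            else:
                instances = preprocessing.preprocess_cohort(
                    seqs, config.preprocess, schema)
                _instances_to_npz(instances, inst_path)
        labels = [i.class_label or "" for i in instances]
        classes = sorted(set(labels))

        stage = "train"
        model_path = out / "model"
        with _timed(stage):
            if resume and model_path.with_suffix(".npz").exists():
                model = model_mod.load_model(model_path, schema)
                fold_metrics = json.loads((out / "fold_metrics.json").read_text())
                train_idx = np.load(out / "train_idx.npy")
            else:
                mcfg = config.model or model_mod.ModelConfig(
                    n_classes=len(classes))
                if mcfg.n_classes != len(classes):
                    mcfg = model_mod.ModelConfig(
                        **{**asdict(mcfg), "n_classes": len(classes),
                           "channels_per_block": mcfg.channels_per_block})
                tcfg = model_mod.TrainConfig(
                    **{**asdict(config.train), "seed": config.seed,
                       "split": config.train.split})
                model, fold_metrics = model_mod.train(
                    mcfg, instances, labels, tcfg, schema)
                train_idx = model.split_indices_["train"]
                model_mod.save_model(model, model_path)
                (out / "fold_metrics.json").write_text(json.dumps(fold_metrics))
                np.save(out / "train_idx.npy", train_idx)

        stage = "embed"
        emb_path = out / "embeddings.csv"
        with _timed(stage):
            if resume and emb_path.exists():
                embeddings = io.read_embeddings(emb_path)
                pca_model = None
            else:
                latents = model_mod.extract_embeddings(model, instances)
                # PCA fitted on the training fold only, applied everywhere
                pca_model = pca.fit_joint_pca(latents[train_idx])
                embeddings = pca.transform(latents, pca_model, instances)
                io.write_embeddings(embeddings, emb_path)

        stage = "cluster"
        with _timed(stage):
            k = config.k or len(classes)
            cm = clustering.fit_kmeans(embeddings, k=k, seed=config.seed,
                                       n_init=config.n_init)
            ref = [i for i, l in enumerate(labels) if l == config.regular_class]
            regular_id = clustering.identify_regular_cluster(cm, ref)
            eval_all = clustering.evaluate_clustering(cm, labels)
            # also report accuracy restricted to held-out-subject instances
            test_idx = (model.split_indices_.get("test", np.array([], int))
                        if hasattr(model, "split_indices_") else np.array([], int))
            eval_test = None
            if len(test_idx):
                sub = clustering.ClusterModel(
                    k=cm.k, centroids=cm.centroids,
                    assignments=cm.assignments[test_idx],
                    inertia=cm.inertia, seed=cm.seed)
                eval_test = clustering.evaluate_clustering(
                    sub, [labels[i] for i in test_idx])

        stage = "explain"
        with _timed(stage):
            from .types import stack_embeddings
            vectors = cm.transform(stack_embeddings(embeddings))
            report = explain.explain_clusters(
                vectors, cm.assignments, regular_id, schema,
                config.region_weights, config.feature_mode)
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({err}); rerun with: "
            f"gaitlens run --config {out / 'config.yaml'} --out {out} --resume"
        ) from err

    summary = {
        "n_instances": len(instances),
        "classes": classes,
        "k": cm.k,
        "fold_metrics": fold_metrics,
        "clustering_accuracy": eval_all.accuracy,
        "clustering_macro_f1": eval_all.macro_f1,
        "clustering_accuracy_heldout": (
            eval_test.accuracy if eval_test is not None else None),
        "per_class_accuracy": eval_all.per_class_accuracy,
        "cluster_to_class": {str(c): l for c, l in eval_all.mapping.items()},
        "regular_cluster": regular_id,
        "mean_confidence": {str(c): v for c, v in report.mean_confidence.items()},
        "mean_severity": {str(c): v for c, v in report.mean_severity.items()},
        "regular_mean_severity": report.regular_mean_severity,
        "region_ranks": {str(c): r.region_ranks
                         for c, r in report.dimwise.items()},
        "region_percentages": {str(c): r.region_percentages
                               for c, r in report.dimwise.items()},
    }
    if pca_model is not None:
        flagged = pca.variance_report(pca_model)
        summary["pca_flagged_fraction"] = float(flagged["flagged"].mean())
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    report.instance_scores.to_csv(out / "instance_scores.csv", index=False)
    eval_all.confusion.to_csv(out / "confusion.csv")
    return summary


def render_report(run_dir: str | Path) -> str:
    """Human-readable report for a completed run directory."""
    run_dir = Path(run_dir)
    missing = [f for f in ("summary.json",) if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing {missing}")
    s = json.loads((run_dir / "summary.json").read_text())
    lines = ["gait assessment report", "=" * 40,
             f"instances: {s['n_instances']}   classes: {', '.join(s['classes'])}",
             f"clustering accuracy (matched): {s['clustering_accuracy']:.3f}",
             f"macro F1: {s['clustering_macro_f1']:.3f}",
             f"regular cluster: {s['regular_cluster']}", "",
             "region importance ranks (1 = most important)",
             "cluster  " + "  ".join(f"{r:>9s}" for r in REGIONS)]
    for cid, ranks in sorted(s["region_ranks"].items()):
        lines.append(f"{cid:>7s}  " + "  ".join(
            f"{ranks[r]:>9d}" for r in REGIONS))
    lines.append("")
    lines.append("per-cluster mean confidence / severity")
    for cid in sorted(s["mean_confidence"]):
        lines.append(f"  cluster {cid}: confidence {s['mean_confidence'][cid]:.3f}"
                     f"  severity {s['mean_severity'][cid]:.3f}")
    lines.append(f"  regular-cluster baseline severity: "
                 f"{s['regular_mean_severity']:.3f}")
    return "\n".join(lines)
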