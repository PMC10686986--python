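"""End-to-end orchestration: simulate → features → cluster → tree → stats.

One root seed drives every stage, so a pipeline run is bit-reproducible.
Artifacts are plain CSV/JSON files written under a single output
directory; `forecast` applies a saved tree to new feature files (the
online part of the offline-learning / online-forecasting loop).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from sow_welfare import cluster as cl
from sow_welfare import features as ft
from sow_welfare import io as sio
from sow_welfare import simgen, stats, treeclf
from sow_welfare.simgen import SimConfig, child_rng

log = logging.getLogger(__name__)

FEATURE_SETS = {
    "feeder_only": ft.FEEDER_FEATURES,
    "feeder+posture": ft.FEEDER_FEATURES + ft.POSTURE_FEATURES,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "artifacts"
    sim: SimConfig = field(default_factory=SimConfig)
    k_range: tuple[int, int] = (2, 10)
    max_depth: int = 3
    test_fraction: float = 0.3
    feature_sets: tuple[str, ...] = ("feeder_only", "feeder+posture")
    seed: int = 42

    def __post_init__(self):
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range must satisfy 2 <= lo <= hi")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        for fs in self.feature_sets:
            if fs not in FEATURE_SETS:
                raise ValueError(f"unknown feature set {fs!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim_block = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim_block:
            cfg.sim = SimConfig(**sim_block)
        if "seed" in raw:
            cfg.sim = dataclasses.replace(cfg.sim, seed=int(raw["seed"]))
        return cfg


@dataclass
class PipelineResult:
    summary: dict
    features: pd.DataFrame
    clusters: pd.DataFrame
    cluster_model: cl.ClusterModel
    trees: dict[str, treeclf.TreeModel]
    evals: dict[str, dict[str, treeclf.EvalReport]]
    stats_table: pd.DataFrame
    out_dir: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 — re-raise with stage context
                raise PipelineError(name, e) from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage and collate a summary; see module docstring."""
    out = Path(config.out_dir)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)

    dataset = _stage("simulate")(simgen.generate_dataset)(sim_cfg)
    if write:
        sio.write_dataset(dataset, out)

    feats = _stage("features")(ft.build_feature_table)(
        dataset.visits, dataset.ethogram, dataset.postures, dataset.schedule
    )
    if write:
        sio.write_table(feats, out / "features.csv", "features")

    @_stage("cluster")
    def _cluster():
        pts = feats[ft.INDEX_FEATURES].to_numpy()
        report = cl.validity_suite(
            pts, range(config.k_range[0], config.k_range[1] + 1),
            seed=int(child_rng(config.seed, "cluster").integers(2**31)),
        )
        k = cl.select_k(report)
        model = report.models[k]
        model.labels = cl.label_clusters(model.medoids) if k == 3 else {
            c: f"cluster_{c}" for c in range(k)
        }
        return report, model

    report, model = _cluster()
    clusters = feats[["sow_id", "group_id", "period"]].copy()
    clusters["cluster_id"] = model.assignment
    clusters["label"] = [model.labels[c] for c in model.assignment]
    if write:
        sio.write_table(clusters, out / "clusters.csv", "clusters")
        cl.write_model(model, out / "model.json", report=report, seed=config.seed)
        trajectory = clusters.pivot(index="sow_id", columns="period", values="label")
        trajectory.to_csv(out / "trajectory.csv")

    @_stage("treeclf")
    def _trees():
        labeled = feats.merge(clusters[["sow_id", "period", "label"]], on=["sow_id", "period"])
        split_seed = int(child_rng(config.seed, "split").integers(2**31))
        train, test = treeclf.stratified_split(labeled, config.test_fraction, split_seed)
        trees, evals = {}, {}
        for fs in config.feature_sets:
            tree = treeclf.grow_tree(
                train, train["label"], config.max_depth, features=FEATURE_SETS[fs]
            )
            trees[fs] = tree
            evals[fs] = {
                "train": treeclf.evaluate(
                    treeclf.predict_frame(tree, train), train["label"],
                    dataset="train", feature_set=fs,
                ),
                "test": treeclf.evaluate(
                    treeclf.predict_frame(tree, test), test["label"],
                    dataset="test", feature_set=fs,
                ),
            }
        return trees, evals, len(train), len(test)

    trees, evals, n_train, n_test = _trees()
    if write:
        for fs, tree in trees.items():
            tag = fs.replace("+", "_")
            tree.save(out / f"tree_{tag}.json")
            (out / f"rules_{tag}.txt").write_text(treeclf.rules_text(tree))
        (out / "eval.json").write_text(
            json.dumps(
                [r.to_dict() for fs in evals.values() for r in fs.values()], indent=2
            )
        )

    stats_table = _stage("stats")(stats.association_report)(
        clusters, dataset.schedule, dataset.registry
    )
    if write:
        stats_table.to_csv(out / "stats.csv", index=False)

    summary = {
        "seed": config.seed,
        "n_observations": len(feats),
        "k": model.k,
        "inertia": model.inertia,
        "medoids": {model.labels[c]: [round(x, 4) for x in model.medoids[c]]
                    for c in range(model.k)},
        "n_train": n_train,
        "n_test": n_test,
        "accuracy": {
            fs: {split: round(r.accuracy, 4) for split, r in by.items()}
            for fs, by in evals.items()
        },
        "weighted_f1": {
            fs: {split: round(r.weighted_f1, 4) for split, r in by.items()}
            for fs, by in evals.items()
        },
        "week_type_verdicts": {
            row["contrast"]: row["verdict"]
            for _, row in stats_table[stats_table["test"] == "cochran_q_week_type"].iterrows()
        },
    }
    if write:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return PipelineResult(
        summary=summary,
        features=feats,
        clusters=clusters,
        cluster_model=model,
        trees=trees,
        evals=evals,
        stats_table=stats_table,
        out_dir=out,
    )


def forecast(tree_path: str | Path, features_csv: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """Classify new sow-period feature rows with a saved tree.

    Writes one prediction per row plus the traversed rule path; an
    empty input yields an empty prediction file with a header.
    """
    tree = treeclf.TreeModel.load(tree_path)
    feats = pd.read_csv(features_csv)
    missing = [f for f in tree.features if f not in feats.columns]
    if missing:
        raise treeclf.TreeError(f"feature file is missing columns: {missing}")
    records = feats.to_dict("records")
    preds = pd.DataFrame(
        {
            "prediction": [treeclf.predict(tree, r) for r in records],
            "rule_path": [" and ".join(treeclf.rule_path(tree, r)[:-1]) for r in records],
        }
    )
    out = pd.concat(
        [feats[[c for c in ("sow_id", "group_id", "period") if c in feats.columns]], preds],
        axis=1,
    )
    if len(out) == 0:  # keep the header even for empty inputs
        out = pd.DataFrame(columns=list(out.columns))
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(out_csv, index=False)
    return out
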