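import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from sow_welfare import cluster as cl
from sow_welfare import features as ft
from sow_welfare import treeclf
from sow_welfare.pipeline import FEATURE_SETS
from sow_welfare.simgen import SimConfig, child_rng, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic herd (4 groups x 17 sows x 6 periods)."""
    return generate_dataset(SimConfig())


@pytest.fixture(scope="session")
def feature_table(default_dataset):
    ds = default_dataset
    return ft.build_feature_table(ds.visits, ds.ethogram, ds.postures, ds.schedule)


@pytest.fixture(scope="session")
def labeled_model(feature_table):
    """k=3 K-medoids fit of the default indices, semantically labeled."""
    pts = feature_table[ft.INDEX_FEATURES].to_numpy()
    model = cl.kmedoids_fit(pts, 3, seed=7)
    model.labels = cl.label_clusters(model.medoids)
    return model


@pytest.fixture(scope="session")
def ten_seed_accuracies():
    """Full cluster-then-classify protocol over 10 seeds, both feature sets.

    Returns one row per seed with train/test accuracy for the
    feeder-only and feeder+posture trees (depth 3, 70/30 stratified).
    """
    rows = []
    for seed in range(1, 11):
        ds = generate_dataset(SimConfig(seed=seed))
        feats = ft.build_feature_table(ds.visits, ds.ethogram, ds.postures, ds.schedule)
        model = cl.kmedoids_fit(
            feats[ft.INDEX_FEATURES].to_numpy(),
            3,
            seed=int(child_rng(seed, "cluster").integers(2**31)),
        )
        model.labels = cl.label_clusters(model.medoids)
        labeled = feats.assign(label=[model.labels[c] for c in model.assignment])
        train, test = treeclf.stratified_split(
            labeled, 0.3, int(child_rng(seed, "split").integers(2**31))
        )
        row = {"seed": seed}
        for fs, cols in FEATURE_SETS.items():
            tree = treeclf.grow_tree(train, train["label"], 3, features=cols)
            row[f"{fs}_train"] = treeclf.evaluate(
                treeclf.predict_frame(tree, train), train["label"]
            ).accuracy
            row[f"{fs}_test"] = treeclf.evaluate(
                treeclf.predict_frame(tree, test), test["label"]
            ).accuracy
        rows.append(row)
    return pd.DataFrame(rows)
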