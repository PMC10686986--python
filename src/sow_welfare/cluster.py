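"""K-medoids clustering of the behavior indices and semantic labeling.

The three valence indices (activity, giving, receiving) are clustered
with K-medoids under Euclidean distance: cluster centers are actual
observations (medoids), making the partition robust to outliers, which
matters for behavioral data. Model selection over a candidate range of
k uses a suite of validity indices (inertia + elbow, mean silhouette,
Calinski–Harabasz, Davies–Bouldin), with mean silhouette as the primary
criterion. For k = 3 a sign rule on the medoid coordinates names the
clusters: the cluster giving the most agonistic interactions is
``aggressive``; of the remaining two, the one receiving the most
agonistic interactions is ``scapegoat``; the last is ``gentle``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

LABELS = ("aggressive", "gentle", "scapegoat")


class ClusterError(ValueError):
    pass


class LabelingError(ClusterError):
    """A tie on a deciding medoid coordinate: label manually."""


@dataclass
class ClusterModel:
    """A fitted K-medoids partition of the index space."""

    k: int
    medoid_indices: np.ndarray  # row ids into the fitted points
    medoids: np.ndarray  # (k, d) medoid coordinates
    assignment: np.ndarray  # cluster id per observation
    inertia: float  # sum of Euclidean distances to own medoid
    n_iter: int = 0
    converged: bool = True
    labels: dict[int, str] | None = None

    def label_of(self, cluster_id: int) -> str:
        if self.labels is None:
            raise ClusterError("model has no semantic labels yet")
        return self.labels[int(cluster_id)]

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "medoid_indices": [int(i) for i in self.medoid_indices],
            "medoids": [[float(x) for x in m] for m in self.medoids],
            "inertia": float(self.inertia),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "labels": {str(k): v for k, v in self.labels.items()} if self.labels else None,
        }


@dataclass
class ValidityReport:
    """Per-candidate-k validity indices plus the elbow candidate."""

    frame: pd.DataFrame  # columns: k, inertia, silhouette, calinski_harabasz, davies_bouldin
    elbow_k: int | None = None
    models: dict[int, ClusterModel] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "elbow_k": self.elbow_k,
            "candidates": self.frame.where(pd.notna(self.frame), None).to_dict("records"),
        }


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if not np.isfinite(pts).all():
        raise ClusterError("points must be finite")
    return pts


def _kmeanspp_init(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding restricted to the data points (D² sampling)."""
    n = dist.shape[0]
    chosen = [int(rng.integers(n))]
    while len(chosen) < k:
        d2 = dist[:, chosen].min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:  # duplicate-point degeneracy: any unchosen point works
            remaining = [i for i in range(n) if i not in chosen]
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
    return np.array(chosen)


def _swap_refine(dist: np.ndarray, medoids: np.ndarray, max_sweeps: int = 100):
    """Greedy PAM-style SWAP phase: exchange a medoid for a non-medoid
    while any exchange strictly lowers inertia (best improvement first)."""
    n = dist.shape[0]
    medoids = medoids.copy()
    inertia = dist[:, medoids].min(axis=1).sum()
    for _ in range(max_sweeps):
        best = (0.0, None, None)
        d_meds = dist[:, medoids]
        for c in range(len(medoids)):
            others = np.delete(d_meds, c, axis=1)
            others_min = others.min(axis=1) if others.shape[1] else np.full(n, np.inf)
            # inertia after swapping medoid c for each candidate point
            cand = np.minimum(others_min[:, None], dist).sum(axis=0)
            j = int(cand.argmin())
            gain = inertia - cand[j]
            if gain > best[0] + 1e-12:
                best = (gain, c, j)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        inertia = dist[:, medoids].min(axis=1).sum()
    assignment = dist[:, medoids].argmin(axis=1)
    return medoids, assignment, float(inertia)


def _fit_once(dist: np.ndarray, medoids: np.ndarray, max_iter: int):
    assignment = dist[:, medoids].argmin(axis=1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_medoids = medoids.copy()
        for c in range(len(medoids)):
            members = np.flatnonzero(assignment == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(within.argmin())]
        new_assignment = dist[:, new_medoids].argmin(axis=1)
        if (new_medoids == medoids).all() and (new_assignment == assignment).all():
            converged = True
            break
        medoids, assignment = new_medoids, new_assignment
    inertia = float(dist[np.arange(dist.shape[0]), medoids[assignment]].sum())
    return medoids, assignment, inertia, it, converged


def kmedoids_fit(
    points,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
    swap_refine: bool = True,
) -> ClusterModel:
    """K-medoids with k-means++ seeding and a PAM SWAP refinement.

    Alternates nearest-medoid assignment with per-cluster medoid update
    (the member minimizing total within-cluster distance) until the
    assignment is stable or `max_iter` is hit, then greedily applies
    inertia-decreasing medoid/non-medoid swaps until 1-swap-optimal;
    the best of `n_init` restarts (lowest inertia) is kept. Restarts
    alternate k-means++ D² seeding with uniform seeding: D² sampling
    spreads initial medoids apart and can systematically miss optima
    that place two medoids in nearby dense regions.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} must be in [1, {n}]")
    dist = cdist(pts, pts)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_init)):
        if restart % 2 == 0:
            init = _kmeanspp_init(dist, k, rng)
        else:
            init = rng.choice(n, size=k, replace=False)
        medoids, assignment, inertia, it, conv = _fit_once(dist, init, max_iter)
        if swap_refine:
            medoids, assignment, inertia = _swap_refine(dist, medoids)
        if best is None or inertia < best[2] - 1e-12:
            best = (medoids, assignment, inertia, it, conv)
    medoids, assignment, inertia, it, conv = best
    order = np.argsort(medoids)  # stable cluster ids: medoid row order
    medoids = medoids[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignment = relabel[assignment]
    return ClusterModel(
        k=k,
        medoid_indices=medoids,
        medoids=pts[medoids],
        assignment=assignment,
        inertia=inertia,
        n_iter=it,
        converged=conv,
    )


def silhouette_mean(points, assignment) -> float:
    """Mean silhouette width; singleton clusters score 0, as does 0/0."""
    pts = _as_points(points)
    assignment = np.asarray(assignment)
    clusters = np.unique(assignment)
    if len(clusters) < 2:
        raise ClusterError("silhouette requires at least 2 clusters")
    dist = cdist(pts, pts)
    scores = np.zeros(len(pts))
    members = {c: np.flatnonzero(assignment == c) for c in clusters}
    for i in range(len(pts)):
        own = members[assignment[i]]
        if own.size == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.size - 1)
        b = min(dist[i, members[c]].mean() for c in clusters if c != assignment[i])
        denom = max(a, b)
        scores[i] = (b - a) / denom if denom > 0 else 0.0
    return float(scores.mean())


def _centroid_scatter(pts: np.ndarray, assignment: np.ndarray):
    clusters = np.unique(assignment)
    overall = pts.mean(axis=0)
    between = within = 0.0
    sigmas, centroids = [], []
    for c in clusters:
        sub = pts[assignment == c]
        centroid = sub.mean(axis=0)
        centroids.append(centroid)
        between += len(sub) * float(((centroid - overall) ** 2).sum())
        within += float(((sub - centroid) ** 2).sum())
        sigmas.append(float(np.linalg.norm(sub - centroid, axis=1).mean()))
    return between, within, np.array(centroids), np.array(sigmas)


def calinski_harabasz(points, assignment) -> float:
    """Variance-ratio criterion [B/(k−1)] / [W/(n−k)], centroid-based."""
    pts = _as_points(points)
    assignment = np.asarray(assignment)
    k = len(np.unique(assignment))
    n = len(pts)
    if k < 2 or k >= n:
        raise ClusterError("Calinski–Harabasz requires 2 <= k < n")
    between, within, _, _ = _centroid_scatter(pts, assignment)
    if within <= 0:
        return float("inf") if between > 0 else 0.0
    return float((between / (k - 1)) / (within / (n - k)))


def davies_bouldin(points, assignment) -> float:
    """Mean over clusters of the worst (σi+σj)/d(ci,cj) similarity."""
    pts = _as_points(points)
    assignment = np.asarray(assignment)
    k = len(np.unique(assignment))
    if k < 2:
        raise ClusterError("Davies–Bouldin requires at least 2 clusters")
    _, _, centroids, sigmas = _centroid_scatter(pts, assignment)
    cd = cdist(centroids, centroids)
    worst = np.zeros(k)
    for i in range(k):
        ratios = [
            (sigmas[i] + sigmas[j]) / cd[i, j] if cd[i, j] > 0 else
            (0.0 if sigmas[i] + sigmas[j] == 0 else float("inf"))
            for j in range(k) if j != i
        ]
        worst[i] = max(ratios)
    return float(worst.mean())


def validity_suite(points, k_range, seed: int = 0) -> ValidityReport:
    """Fit every candidate k and tabulate the validity indices.

    Silhouette, Calinski–Harabasz and Davies–Bouldin are defined only
    for 2 <= k < n and are NaN otherwise. The elbow candidate maximizes
    the second difference of inertia over the candidate grid.
    """
    pts = _as_points(points)
    n = len(pts)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > n:
        raise ClusterError(f"k_range must lie within [1, {n}]")
    rows, models = [], {}
    for k in ks:
        model = kmedoids_fit(pts, k, seed=seed + k)
        models[k] = model
        effective = len(np.unique(model.assignment))
        row = {"k": k, "inertia": model.inertia,
               "silhouette": np.nan, "calinski_harabasz": np.nan, "davies_bouldin": np.nan}
        if 2 <= effective < n:
            row["silhouette"] = silhouette_mean(pts, model.assignment)
            row["calinski_harabasz"] = calinski_harabasz(pts, model.assignment)
            row["davies_bouldin"] = davies_bouldin(pts, model.assignment)
        rows.append(row)
    frame = pd.DataFrame(rows)
    elbow = None
    if len(ks) >= 3:
        inertia = frame["inertia"].to_numpy()
        curvature = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
        elbow = int(frame["k"].iloc[1 + int(curvature.argmax())])
    return ValidityReport(frame=frame, elbow_k=elbow, models=models)


def select_k(report: ValidityReport) -> int:
    """Pick k maximizing mean silhouette.

    Ties (to 1e-12) are broken by higher Calinski–Harabasz, then lower
    Davies–Bouldin, then smaller k. With a single candidate, that k is
    returned.
    """
    frame = report.frame
    if frame.empty:
        raise ClusterError("empty validity report")
    scored = frame.dropna(subset=["silhouette"])
    if scored.empty:
        return int(frame["k"].iloc[0])

    def key(row):
        return (
            -round(row.silhouette, 12),
            -round(row.calinski_harabasz, 12),
            round(row.davies_bouldin, 12),
            row.k,
        )

    best = min(scored.itertuples(), key=key)
    return int(best.k)


def label_clusters(medoids) -> dict[int, str]:
    """Name three clusters from their medoid signs.

    ``aggressive``: minimum giving index (gives the most agonistic
    interactions); of the remaining two, ``scapegoat``: minimum
    receiving index; ``gentle``: the rest. An exact tie on a deciding
    coordinate is ambiguous and raises for manual labeling.
    """
    med = np.asarray(medoids, dtype=float)
    if med.shape != (3, 3):
        raise ClusterError("labeling requires exactly 3 medoids in index space")
    giving = med[:, 1]
    if (giving == giving.min()).sum() > 1:
        raise LabelingError("tie on the giving index; label manually")
    aggressive = int(giving.argmin())
    rest = [i for i in range(3) if i != aggressive]
    receiving = med[rest, 2]
    if receiving[0] == receiving[1]:
        raise LabelingError("tie on the receiving index; label manually")
    scapegoat = rest[int(receiving.argmin())]
    gentle = next(i for i in rest if i != scapegoat)
    return {aggressive: "aggressive", scapegoat: "scapegoat", gentle: "gentle"}


def write_model(model: ClusterModel, path: str | Path, report: ValidityReport | None = None,
                seed: int | None = None) -> None:
    payload = model.to_dict()
    payload["seed"] = seed
    if report is not None:
        payload["validity"] = report.to_dict()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2))
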