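"""Repeated-measures tests relating welfare states to conditions.

Cluster membership is a within-sow repeated categorical outcome, so
dependence on housing conditions uses Cochran's Q (paired binary data
across conditions; with two conditions it reduces to McNemar's test).
Continuous sow covariates across the three states use Friedman's
rank test with Nemenyi post hoc comparisons. Verdicts follow the
two-threshold convention: significant at P < 0.05, trend at
0.05 ≤ P < 0.10, otherwise ns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

P_SIGNIFICANT = 0.05
P_TREND = 0.10


class StatsError(ValueError):
    pass


def verdict(p_value: float) -> str:
    if not 0.0 <= p_value <= 1.0:
        raise StatsError(f"p-value {p_value} outside [0, 1]")
    if p_value < P_SIGNIFICANT:
        return "significant"
    if p_value < P_TREND:
        return "trend"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    verdict: str
    n_blocks: int = 0

    @classmethod
    def from_chi2(cls, name: str, statistic: float, df: int, n_blocks: int = 0) -> "TestResult":
        p = float(sps.chi2.sf(statistic, df)) if statistic > 0 else 1.0
        return cls(name, float(statistic), float(df), p, verdict(p), n_blocks)


def cochran_q(binary_matrix, name: str = "cochran_q") -> TestResult:
    """Cochran's Q over b blocks (sows) × k conditions of 0/1 outcomes.

    Q = (k−1)[kΣGj² − (ΣGj)²] / (kΣLi − ΣLi²) with Gj the column sums
    and Li the row sums; P from the χ² upper tail with k−1 df. Blocks
    with constant rows contribute nothing; if every row is constant the
    statistic degenerates to 0 with P = 1.
    """
    x = np.asarray(binary_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise StatsError("need a b × k matrix with k >= 2")
    if not np.isin(x, (0.0, 1.0)).all():
        raise StatsError("entries must be binary")
    b, k = x.shape
    g = x.sum(axis=0)
    li = x.sum(axis=1)
    denom = k * li.sum() - (li**2).sum()
    if denom == 0:
        return TestResult(name, 0.0, float(k - 1), 1.0, "ns", b)
    q = (k - 1) * (k * (g**2).sum() - g.sum() ** 2) / denom
    return TestResult.from_chi2(name, q, k - 1, b)


def friedman(value_matrix, name: str = "friedman") -> TestResult:
    """Friedman's rank test over b complete blocks × k treatments.

    Within-block mid-ranks; χ²_F = 12/(bk(k+1))·ΣRj² − 3b(k+1), divided
    by the standard tie-correction factor 1 − Σ(t³−t)/(bk(k²−1)).
    All-tied blocks everywhere degenerate to statistic 0, P = 1.
    """
    x = np.asarray(value_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise StatsError("need a b × k matrix with k >= 2")
    if np.isnan(x).any():
        raise StatsError("incomplete blocks; apply listwise deletion first")
    b, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    uncorrected = 12.0 / (b * k * (k + 1)) * (rj**2).sum() - 3.0 * b * (k + 1)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (b * k * (k**2 - 1))
    if correction <= 0:
        return TestResult(name, 0.0, float(k - 1), 1.0, "ns", b)
    return TestResult.from_chi2(name, uncorrected / correction, k - 1, b)


def mcnemar(x, y, name: str = "mcnemar") -> TestResult:
    """McNemar χ² (no continuity correction) on two paired binary vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired vectors must have equal length")
    if not (np.isin(x, (0.0, 1.0)).all() and np.isin(y, (0.0, 1.0)).all()):
        raise StatsError("entries must be binary")
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    if b + c == 0:
        return TestResult(name, 0.0, 1.0, 1.0, "ns", len(x))
    stat = (b - c) ** 2 / (b + c)
    return TestResult.from_chi2(name, stat, 1, len(x))


def nemenyi_pairwise(value_matrix) -> pd.DataFrame:
    """All-pairs Nemenyi rank comparisons after a Friedman test.

    The statistic |R̄i − R̄j| / sqrt(k(k+1)/(12b)) is referred to the
    studentized range distribution with k groups and ∞ df.
    """
    x = np.asarray(value_matrix, dtype=float)
    b, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * b))
    rows = []
    for i, j in combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
        rows.append({"i": i, "j": j, "statistic": float(q), "p_value": p})
    return pd.DataFrame(rows)


def posthoc_pairwise(matrix, kind: str) -> pd.DataFrame:
    """Pairwise contrasts after an omnibus test, with Holm correction.

    `kind` is ``"mcnemar"`` for paired binary membership matrices or
    ``"nemenyi"`` for continuous block designs. Both raw and
    Holm-adjusted p-values (and their verdicts) are reported.
    """
    x = np.asarray(matrix, dtype=float)
    if kind == "mcnemar":
        rows = []
        for i, j in combinations(range(x.shape[1]), 2):
            r = mcnemar(x[:, i], x[:, j])
            rows.append({"i": i, "j": j, "statistic": r.statistic, "p_value": r.p_value})
        out = pd.DataFrame(rows)
    elif kind == "nemenyi":
        out = nemenyi_pairwise(x)
    else:
        raise StatsError(f"unknown post hoc kind {kind!r}")
    if len(out):
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
        out["verdict"] = out["p_holm"].map(verdict)
        out["verdict_unadjusted"] = out["p_value"].map(verdict)
    return out


def _modal(series: pd.Series) -> str:
    counts = series.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]  # alphabetical tie-break


def association_report(
    clusters: pd.DataFrame,
    schedule: pd.DataFrame,
    registry: pd.DataFrame,
    pairing: str = "modal",
) -> pd.DataFrame:
    """Tidy table of condition/covariate/health association tests.

    * week type × membership: per label, each sow contributes a binary
      indicator (modal cluster equals the label) under control and
      under event weeks; sows observed in both conditions enter a
      paired Cochran Q (k = 2). With ``pairing="per_period"`` the i-th
      control and event periods of each sow are paired instead.
    * covariates (parity, body weight, backfat): Friedman across the
      three states over sows observed in all three.
    * health × membership: two-proportion z-test of each label's
      observation share for unhealthy vs. healthy sows.
    """
    df = clusters.merge(
        schedule[["group_id", "period", "week_type"]], on=["group_id", "period"], how="left"
    )
    labels = sorted(df["label"].unique())
    rows = []

    def add(test, contrast, result: TestResult):
        rows.append(
            {
                "test": test,
                "contrast": contrast,
                "statistic": result.statistic,
                "df": result.df,
                "p_value": result.p_value,
                "verdict": result.verdict,
                "n": result.n_blocks,
            }
        )

    # week-type dependence, one-vs-rest per label
    both = df.groupby("sow_id")["week_type"].nunique()
    eligible = set(both[both == 2].index)
    skipped = df["sow_id"].nunique() - len(eligible)
    if skipped:
        log.info("week-type test: excluded %d sows lacking both conditions", skipped)
    for label in labels:
        if pairing == "modal":
            modal = (
                df[df["sow_id"].isin(eligible)]
                .groupby(["sow_id", "week_type"])["label"]
                .agg(_modal)
                .unstack("week_type")
            )
            mat = np.column_stack(
                [(modal["control"] == label).astype(float), (modal["event"] == label).astype(float)]
            )
        elif pairing == "per_period":
            pairs = []
            for sow, sub in df[df["sow_id"].isin(eligible)].groupby("sow_id"):
                ctrl = sub[sub["week_type"] == "control"].sort_values("period")["label"].tolist()
                ev = sub[sub["week_type"] == "event"].sort_values("period")["label"].tolist()
                for c_lab, e_lab in zip(ctrl, ev):
                    pairs.append((float(c_lab == label), float(e_lab == label)))
            mat = np.asarray(pairs)
        else:
            raise StatsError(f"unknown pairing {pairing!r}")
        add("cochran_q_week_type", f"{label}: control vs event", cochran_q(mat))

    # sow covariates across states (blocks: sows seen in all three states)
    cov = df.merge(registry, on=["sow_id", "group_id"], how="left")
    for covariate in ("parity", "body_weight_kg", "backfat_mm"):
        # registry covariates are one value per sow; `first` avoids the
        # float drift a mean over repeated identical values would add
        wide = (
            cov.groupby(["sow_id", "label"])[covariate].first().unstack("label").dropna()
        )
        if set(wide.columns) >= set(labels) and len(wide) >= 2:
            add("friedman_covariate", covariate, friedman(wide[labels].to_numpy()))

    # health status vs membership: share of observations per label
    health = df.merge(registry[["sow_id", "healthy"]], on="sow_id", how="left")
    for label in labels:
        grp = health.groupby("healthy")["label"].agg(
            count=lambda s, L=label: int((s == L).sum()), nobs="size"
        )
        if set(grp.index) == {True, False} and (grp["nobs"] > 0).all():
            from statsmodels.stats.proportion import proportions_ztest

            stat, p = proportions_ztest(grp["count"].to_numpy(), grp["nobs"].to_numpy())
            add(
                "health_proportion",
                f"{label}: unhealthy vs healthy",
                TestResult("health", float(stat), float("nan"), float(p), verdict(float(p)),
                           int(grp["nobs"].sum())),
            )
    return pd.DataFrame(rows)
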