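"""Stage-wise regulatory-mode dynamics across spermatogenesis.

Per-stage gene categories collapse to a two-state regulatory mode: "S"
(categories I and III -- regulation consistent with directional or
diversifying selection on the regulator) versus "N" (categories II, IV and
V).  This module counts gain/loss transitions between successive stages,
tests turnover (genes that gain S and immediately lose it) with the
hypergeometric distribution, compares gain:loss ratios between gene sets
with chi-square tests, and clusters expression trajectories by their peak
stage with fuzzy c-means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import STAGES

logger = logging.getLogger(__name__)

S_CATEGORIES = ("I", "III")
N_CATEGORIES = ("II", "IV", "V")

TRANSITION_KINDS = ("N->N", "N->S", "S->N", "S->S")


def assign_modes(records_by_stage: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene x stage mode matrix ("S"/"N") from per-stage effect records.

    Only genes classifiable (non-VI) at all four stages are kept; the
    number dropped is logged.
    """
    missing = [s for s in STAGES if s not in records_by_stage]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    common = records_by_stage[STAGES[0]].index
    for s in STAGES[1:]:
        common = common.intersection(records_by_stage[s].index)
    modes = pd.DataFrame(index=common)
    classifiable = pd.Series(True, index=common)
    for s in STAGES:
        cat = records_by_stage[s].loc[common, "category"]
        classifiable &= cat != "VI"
        modes[s] = np.where(cat.isin(S_CATEGORIES), "S", "N")
    dropped = int((~classifiable).sum())
    if dropped:
        logger.info(
            "dropping %d genes ambiguous (category VI) at >=1 stage", dropped
        )
    return modes[classifiable]


def transitions(modes: pd.DataFrame) -> pd.DataFrame:
    """Counts of N->N, N->S, S->N, S->S per successive stage pair."""
    if len(modes) == 0:
        raise ValueError("empty mode matrix")
    rows = {}
    for a, b in zip(STAGES[:-1], STAGES[1:]):
        pair = f"{a}->{b}"
        rows[pair] = {
            kind: int(
                (
                    (modes[a] == kind[0]) & (modes[b] == kind[-1])
                ).sum()
            )
            for kind in TRANSITION_KINDS
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(TRANSITION_KINDS)]


@dataclass(frozen=True)
class TurnoverResult:
    """Hypergeometric test of gained-then-lost regulatory mode at a stage."""

    stage: str
    n_s: int  # genes in S at the stage (M)
    n_losing: int  # of those, genes N at the next stage (K)
    n_gained: int  # genes N at the previous stage, S here (n)
    n_gained_lost: int  # gained genes that lose S at the next stage (k)
    fraction_lost: float
    p: float
    defined: bool = True


def turnover_test(
    modes: pd.DataFrame, stage: str, population: str = "S_at_stage"
) -> TurnoverResult:
    """Do genes that just gained mode S at ``stage`` lose it immediately?

    With population = S genes at the stage (size M), K of which lose S at
    the next stage, the n genes that gained S at the stage form the sample
    and k of them lose S; p = P(X >= k) under Hypergeometric(M, K, n).
    ``population='all'`` uses all genes in the matrix as the population
    instead (alternative sampling frame).
    """
    idx = STAGES.index(stage)
    if idx == 0 or idx == len(STAGES) - 1:
        raise ValueError(f"stage {stage} needs both a predecessor and a successor")
    prev_s, next_s = STAGES[idx - 1], STAGES[idx + 1]
    in_s = modes[stage] == "S"
    losing = in_s & (modes[next_s] == "N")
    gained = (modes[prev_s] == "N") & in_s
    gained_lost = gained & losing
    M = int(in_s.sum()) if population == "S_at_stage" else len(modes)
    K = int(losing.sum())
    n = int(gained.sum())
    k = int(gained_lost.sum())
    if M == 0 or n == 0:
        return TurnoverResult(stage, M, K, n, k, np.nan, np.nan, defined=False)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return TurnoverResult(stage, M, K, n, k, k / n, p)


def gain_loss_counts(modes: pd.DataFrame) -> pd.DataFrame:
    """Per stage pair: number of genes gaining (N->S) and losing (S->N)."""
    t = transitions(modes)
    return t[["N->S", "S->N"]].rename(columns={"N->S": "gain", "S->N": "loss"})


def target_transition_enrichment(
    target_counts: Sequence[int], all_counts: Sequence[int]
) -> tuple[float, float]:
    """2x2 chi-square (1 df, no continuity correction) comparing the
    gain:loss ratio of a target set against a reference set.

    Each argument is a (gain, loss) pair of counts.  Returns (chi2, p).
    """
    table = np.asarray([list(target_counts), list(all_counts)], dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected two (gain, loss) pairs")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("chi-square test undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass(frozen=True)
class TrajectoryModel:
    """Fuzzy c-means configuration for 4-stage expression trajectories."""

    n_clusters: int = 4
    fuzzifier: float = 1.25
    membership_threshold: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")
        if not 0 < self.membership_threshold <= 1:
            raise ValueError("membership threshold must lie in (0, 1]")


@dataclass(frozen=True)
class FittedTrajectories:
    """Fitted fuzzy c-means model over standardized stage trajectories."""

    memberships: pd.DataFrame  # gene x cluster, rows sum to 1
    centroids: pd.DataFrame  # cluster x stage (standardized scale)
    cluster_peak: pd.Series  # cluster -> peak stage label
    peak_stage: pd.Series  # gene -> stage label, NaN if below threshold
    objective_trace: list[float] = field(compare=False, default_factory=list)


def _fcm(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Classic fuzzy c-means on rows of x; returns (memberships, centers,
    objective trace).  Centers are initialized from k-means++-style seeded
    draws of data rows for stable, reproducible starts."""
    n = len(x)
    centers = np.empty((c, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    for i in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - centers[None, :i, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers[i] = x[rng.integers(n)]
        else:
            centers[i] = x[rng.choice(n, p=d2 / total)]
    expo = 1.0 / (m - 1.0)
    trace: list[float] = []
    u = np.empty((n, c))
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d2 ** (-expo)
            u = w / w.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        obj = float((um * d2).sum())
        if trace and abs(trace[-1] - obj) < tol:
            trace.append(obj)
            break
        trace.append(obj)
    return u, centers, trace


def cluster_trajectories(
    stage_means: pd.DataFrame,
    model: TrajectoryModel | None = None,
    seed: int = 0,
) -> FittedTrajectories:
    """Cluster per-gene stage-mean trajectories by peak stage.

    Each gene's 4-stage trajectory is standardized to mean 0, sd 1
    (constant trajectories are removed first), then clustered with fuzzy
    c-means (c clusters, fuzzifier m).  Clusters are labeled by the stage
    at which their centroid peaks (ties broken by the earliest stage);
    genes whose maximum membership falls below the threshold stay
    unassigned (NaN peak stage).
    """
    model = model or TrajectoryModel()
    if list(stage_means.columns) != list(STAGES):
        raise ValueError(f"stage_means must have columns {STAGES}")
    x = stage_means.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("removing %d constant trajectories", n_const)
    x = x[keep]
    genes = stage_means.index[keep]
    if len(np.unique(x, axis=0)) < model.n_clusters:
        raise ValueError(
            f"need >= {model.n_clusters} distinct trajectories, have "
            f"{len(np.unique(x, axis=0))}"
        )
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    u, centers, trace = _fcm(
        z, model.n_clusters, model.fuzzifier, model.tol, model.max_iter, rng
    )
    cluster_ids = [f"cluster_{i + 1}" for i in range(model.n_clusters)]
    memberships = pd.DataFrame(u, index=genes, columns=cluster_ids)
    centroids = pd.DataFrame(centers, index=cluster_ids, columns=list(STAGES))
    cluster_peak = pd.Series(
        [STAGES[int(np.argmax(row))] for row in centers],
        index=cluster_ids,
        name="peak_stage",
    )
    best = u.argmax(axis=1)
    assigned = u.max(axis=1) >= model.membership_threshold
    peak = pd.Series(
        np.where(assigned, cluster_peak.to_numpy()[best], None),
        index=genes,
        name="peak_stage",
        dtype=object,
    )
    return FittedTrajectories(memberships, centroids, cluster_peak, peak, trace)


def peak_stage_test(
    gained_labels: Sequence[str], lost_labels: Sequence[str]
) -> tuple[float, float]:
    """Chi-square comparison of peak-stage composition between genes
    gaining and losing the S mode: SG peak vs post-SG peak (2x2, 1 df)."""
    gained = pd.Series(list(gained_labels)).dropna()
    lost = pd.Series(list(lost_labels)).dropna()
    if len(gained) == 0 or len(lost) == 0:
        raise ValueError("both label sets must be non-empty")
    table = [
        [int((gained == "SG").sum()), int((gained != "SG").sum())],
        [int((lost == "SG").sum()), int((lost != "SG").sum())],
    ]
    return target_transition_enrichment(table[0], table[1])
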