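"""Statistics for sperm-length and sperm-competition phenotypes.

Sperm length tables hold one row per measured sperm (genotype, male,
sperm, length in mm).  Competition records hold per-female offspring
counts from the double-mating assay: red-eyed progeny are sired by the
reference male, white-eyed by the test male; the test male is first mate
(P1) in the defense assay and second mate (P2) in the offense assay.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_PROGENY = 10

ROLES = ("P1", "P2")


def cv_per_male(sperm: pd.DataFrame) -> pd.DataFrame:
    """Within-male coefficient of variation of sperm length (%).

    CV = sample standard deviation / mean x 100 per male.  Males with a
    single measurement are excluded (CV undefined) and logged.
    Columns of the result: ``genotype, male_id, n_sperm, cv_percent``.
    """
    if (sperm["length_mm"] <= 0).any():
        raise ValueError("sperm lengths must be positive")
    grouped = sperm.groupby(["genotype", "male_id"])["length_mm"]
    n = grouped.size()
    single = n[n < 2]
    if len(single):
        logger.info("excluding %d males with a single measurement", len(single))
    keep = n[n >= 2].index
    cv = (grouped.std(ddof=1) / grouped.mean() * 100.0).loc[keep]
    out = cv.rename("cv_percent").reset_index()
    out.insert(2, "n_sperm", n.loc[keep].to_numpy())
    return out


def percent_reduction(mean_ref: float, mean_test: float) -> float:
    """Percent reduction of the test mean relative to the reference mean:
    100 * (ref - test) / ref."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_ref - mean_test) / mean_ref


def length_comparison(
    sperm: pd.DataFrame, genotype1: str, genotype2: str
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of sperm lengths between genotypes."""
    x = sperm.loc[sperm["genotype"] == genotype1, "length_mm"]
    y = sperm.loc[sperm["genotype"] == genotype2, "length_mm"]
    return _ranksum(x.to_numpy(), y.to_numpy())


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum: exact enumeration for small tie-free samples,
    normal approximation with tie correction otherwise."""
    small = max(len(x), len(y)) <= 25
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def competition_scores(
    records: pd.DataFrame, min_progeny: int = MIN_PROGENY
) -> pd.DataFrame:
    """Per-female sperm-competition scores.

    score = n_white / (n_red + n_white), the proportion of offspring sired
    by the (white-eyed) test male.  Females with fewer than ``min_progeny``
    total progeny are excluded.  P1 records yield defense scores, P2
    offense scores (column ``assay``).
    """
    required = {"genotype", "female_id", "role", "n_red", "n_white"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"competition table missing columns: {sorted(missing)}")
    if (records[["n_red", "n_white"]] < 0).any().any():
        raise ValueError("offspring counts must be >= 0")
    bad_roles = set(records["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    total = records["n_red"] + records["n_white"]
    kept = records[total >= min_progeny].copy()
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.info(
            "excluding %d females with < %d progeny", n_excluded, min_progeny
        )
    kept["score"] = kept["n_white"] / (kept["n_red"] + kept["n_white"])
    kept["assay"] = np.where(kept["role"] == "P1", "defense", "offense")
    return kept


def score_comparisons(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of competition scores between
    genotypes, separately per assay (defense/offense)."""
    rows = []
    for assay, sub in scores.groupby("assay"):
        genotypes = sorted(sub["genotype"].unique())
        for i, g1 in enumerate(genotypes):
            for g2 in genotypes[i + 1 :]:
                x = sub.loc[sub["genotype"] == g1, "score"].to_numpy()
                y = sub.loc[sub["genotype"] == g2, "score"].to_numpy()
                stat, p = _ranksum(x, y)
                rows.append(
                    {
                        "assay": assay,
                        "genotype1": g1,
                        "genotype2": g2,
                        "n1": len(x),
                        "n2": len(y),
                        "statistic": stat,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
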