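"""Negative-binomial differential-expression engine.

Normalizes raw counts with median-of-ratios size factors, estimates per-gene
NB dispersion by the method of moments (var = mu + phi * mu^2), and computes
per-gene log2 fold changes between two sample groups with a delta-method
standard error.  This is an unshrunk moment estimator: simple, transparent
and verifiable by simulation.  Its calibration properties are what matter
downstream, not numerical agreement with any particular shrinkage fitter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

#: Lower bound on moment dispersion estimates.
DISPERSION_FLOOR = 1e-8

#: Pseudocount added to normalized group means before taking log2.
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are rows with no zero count.  For each sample, the
    factor is the median over reference genes of count / per-gene geometric
    mean.  Raises if no gene is positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (consider a pseudocount on the input counts)"
        )
    logs = np.log(arr[ref])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    sf /= np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def estimate_dispersion(
    norm: pd.DataFrame, groups: list[list[str]]
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion pooled across groups.

    Within each group, phi = (s^2 - m) / m^2 on normalized replicate counts;
    group estimates are pooled by a residual-degrees-of-freedom weighted
    mean and floored at :data:`DISPERSION_FLOOR`.
    """
    num = np.zeros(len(norm))
    den = 0.0
    for g in groups:
        if len(g) < 2:
            raise ValueError("dispersion estimation needs >=2 replicates per group")
        x = norm[g].to_numpy(dtype=float)
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (s2 - m) / np.square(m), 0.0)
        w = len(g) - 1
        num += w * phi
        den += w
    pooled = np.maximum(DISPERSION_FLOOR, num / den)
    return pd.Series(pooled, index=norm.index, name="dispersion")


def contrast_lfc(
    counts: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    sf: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 fold change of group1 over group2 with standard error.

    lfc = log2((m1 + c) / (m2 + c)) on normalized group means.  The delta
    method gives se^2 = (1/ln2)^2 * [s1^2/(n1 (m1+c)^2) + s2^2/(n2 (m2+c)^2)]
    with s^2 the sample variance of normalized replicate counts.  A group
    with zero sample variance falls back to the NB model variance
    m + phi * m^2 (phi pooled across the two groups), so the se stays
    positive wherever the gene is expressed.

    Returns a DataFrame with columns ``lfc, se, m1, m2, n1, n2, v1, v2, ok``
    where v1/v2 are the per-group variance contributions to se^2 (needed by
    downstream difference tests that share a baseline group) and ``ok`` is
    False for genes with an all-zero group (lfc inestimable in any
    meaningful sense).
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >=2 replicates")
    norm = normalize(counts, sf)
    phi = estimate_dispersion(norm, [group1, group2]).to_numpy()

    def moments(g: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = norm[g].to_numpy(dtype=float)
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        zero = s2 == 0
        s2 = np.where(zero, m + phi * np.square(m), s2)
        return m, s2, zero & (m == 0)

    m1, s1, dead1 = moments(group1)
    m2, s2, dead2 = moments(group2)
    n1, n2 = len(group1), len(group2)
    c = pseudocount
    lfc = np.log2((m1 + c) / (m2 + c))
    v1 = s1 / (n1 * np.square(m1 + c)) / LN2**2
    v2 = s2 / (n2 * np.square(m2 + c)) / LN2**2
    se = np.sqrt(v1 + v2)
    ok = ~(dead1 | dead2)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "se": se,
            "m1": m1,
            "m2": m2,
            "n1": n1,
            "n2": n2,
            "v1": v1,
            "v2": v2,
            "ok": ok,
        },
        index=counts.index,
    )


def wald_p(lfc: np.ndarray | pd.Series, se: np.ndarray | pd.Series) -> np.ndarray:
    """Two-sided Wald p-value of lfc = 0 against a normal reference."""
    lfc = np.asarray(lfc, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    return 2.0 * stats.norm.sf(np.abs(lfc / se))


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def call_de(
    result: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.Index:
    """Differentially expressed genes: |lfc| > threshold and adjusted p < FDR.

    ``result`` must carry columns ``lfc`` and ``se`` (from
    :func:`contrast_lfc`); Wald p-values are BH-adjusted internally.
    """
    p = wald_p(result["lfc"], result["se"])
    padj = bh_adjust(p)
    mask = (np.abs(result["lfc"].to_numpy()) > lfc_threshold) & (
        padj < fdr_threshold
    )
    return result.index[mask]


def de_table(
    counts: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    sf: pd.Series | None = None,
    contrast: str = "",
) -> pd.DataFrame:
    """Full differential-expression result table for one contrast:
    ``gene_id, contrast, lfc, se, m1, m2, p, p_adj``."""
    res = contrast_lfc(counts, group1, group2, sf)
    p = wald_p(res["lfc"], res["se"])
    out = res[["lfc", "se", "m1", "m2"]].copy()
    out.insert(0, "contrast", contrast)
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    return out
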