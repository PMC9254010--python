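"""Interspecific expression divergence and the bootstrap selection scan.

Global divergence between species is 1 - rho (Spearman) per cross-species
sample pair.  Per-gene divergence is a pseudocounted log2 ratio of mean
abundance between species, computed separately for WT and KO genotype
classes; the normalized difference D = (|d_KO| - |d_WT|) / mean(|d_KO|,
|d_WT|) summarizes how much the regulator contributes to a gene's
divergence.  The selection scan flags genes whose WT divergence exceeds a
bootstrap quantile of the expressed-gene distribution in nearly all
bootstrap replicates and intersects them with the enhancing category
(III), the signature of diversifying selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import de_engine
from .counts_io import CountMatrix, ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


def global_divergence(
    abundance: ExpressionMatrix | pd.DataFrame,
    sheet: SampleSheet,
    stage: str | None = None,
) -> pd.DataFrame:
    """1 - Spearman rho for every matched cross-species sample pair.

    Pairs are formed within a genotype class (mel WT x sim WT, mel KO x
    sim KO) at the same stage/tissue.  Returns one row per pair with
    columns ``mel_sample, sim_sample, genotype, stage, divergence``.
    """
    values = abundance.values if isinstance(abundance, ExpressionMatrix) else abundance
    if len(values) < 4:
        raise ValueError("need >= 4 genes for a stable rank correlation")
    sub = sheet.subset(stage)
    rows = []
    stages = sub.table["stage"].unique()
    for st in stages:
        for genotype in ("WT", "KO"):
            mel = [
                s
                for s in sub.samples_for("mel", genotype, st)
                if s in values.columns
            ]
            sim = [
                s
                for s in sub.samples_for("sim", genotype, st)
                if s in values.columns
            ]
            for ms in mel:
                for ss in sim:
                    rho = stats.spearmanr(values[ms], values[ss]).statistic
                    rows.append(
                        {
                            "mel_sample": ms,
                            "sim_sample": ss,
                            "genotype": genotype,
                            "stage": st,
                            "divergence": 1.0 - rho,
                        }
                    )
    if not rows:
        raise ValueError("no matched cross-species sample pairs found")
    return pd.DataFrame(rows)


def divergence_comparison(
    summary: pd.DataFrame, key: str, group1: str, group2: str
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of 1 - rho values between two groups
    (e.g. WT vs KO, or two stages)."""
    x = summary.loc[summary[key] == group1, "divergence"]
    y = summary.loc[summary[key] == group2, "divergence"]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def gene_divergence(
    abundance: ExpressionMatrix | pd.DataFrame,
    sheet: SampleSheet,
    stage: str | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene interspecific divergence for WT and KO genotype classes.

    d = log2((mel mean + c) / (sim mean + c)) over replicate means of each
    class, plus the normalized difference
    D = (|d_KO| - |d_WT|) / ((|d_KO| + |d_WT|) / 2), defined as 0 when both
    divergences are 0.  Columns: ``d_WT, d_KO, D``.
    """
    values = abundance.values if isinstance(abundance, ExpressionMatrix) else abundance
    sub = sheet.subset(stage)
    out = pd.DataFrame(index=values.index)
    for genotype in ("WT", "KO"):
        mel = [s for s in sub.samples_for("mel", genotype) if s in values.columns]
        sim = [s for s in sub.samples_for("sim", genotype) if s in values.columns]
        if len(mel) < 2 or len(sim) < 2:
            raise ValueError(
                f"genotype class {genotype} needs >=2 replicates per species"
            )
        out[f"d_{genotype}"] = np.log2(
            (values[mel].mean(axis=1) + pseudocount)
            / (values[sim].mean(axis=1) + pseudocount)
        )
    a_ko = out["d_KO"].abs()
    a_wt = out["d_WT"].abs()
    denom = (a_ko + a_wt) / 2.0
    with np.errstate(invalid="ignore"):
        out["D"] = np.where(denom > 0, (a_ko - a_wt) / denom, 0.0)
    return out


def divergence_difference_ks(
    d1: np.ndarray | pd.Series, d2: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test on normalized
    divergence differences.  Returns (statistic, p)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if len(d1) < 5 or len(d2) < 5:
        raise ValueError("each sample needs >= 5 values")
    res = stats.ks_2samp(d1, d2)
    return float(res.statistic), float(res.pvalue)


def effect_correlations(
    records: pd.DataFrame, gdiv: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations among the regulator effect (C - B), the context
    effect (B - A) and WT interspecific divergence.

    Rows: ``mir_vs_context, mir_vs_divergence, context_vs_divergence``,
    columns r and p.  Note that the naive mir-context correlation shares
    the estimated B in both variables; use
    :func:`cross_replicate_correlation` for the corrected version.
    """
    common = records.index.intersection(gdiv.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes")
    mir = records.loc[common, "mir_effect"].to_numpy(dtype=float)
    ctx = records.loc[common, "context_effect"].to_numpy(dtype=float)
    div = gdiv.loc[common, "d_WT"].to_numpy(dtype=float)
    pairs = {
        "mir_vs_context": (mir, ctx),
        "mir_vs_divergence": (mir, div),
        "context_vs_divergence": (ctx, div),
    }
    rows = {}
    for name, (x, y) in pairs.items():
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in correlation {name}")
        r, p = stats.pearsonr(x, y)
        rows[name] = {"r": float(r), "p": float(p), "n": len(common)}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class CrossReplicateResult:
    corrected_r: float
    naive_r: float
    n_splits: int
    n_genes: int


def cross_replicate_correlation(
    merged: CountMatrix | pd.DataFrame,
    sheet: SampleSheet,
    stage: str | None = None,
    genes: pd.Index | None = None,
    pseudocount: float = de_engine.PSEUDOCOUNT,
) -> CrossReplicateResult:
    """Shared-noise-free correlation between context and regulator effects.

    The naive Pearson correlation of (B - A) with (C - B) is biased
    negative because the estimated B (with its sampling noise) enters both
    variables.  The cross-replicate correction splits the replacement
    replicates into two disjoint balanced halves, estimates B twice (B1,
    B2), and correlates (B1 - A) with (C - B2), so no replicate's noise is
    shared.  The correlation is averaged over all balanced disjoint
    splits.
    """
    counts = merged.counts if isinstance(merged, CountMatrix) else merged
    sub = sheet.subset(stage)
    samples = [s for s in sub.sample_ids if s in counts.columns]
    counts = counts[samples]
    if genes is not None:
        counts = counts.loc[genes]
    sf = de_engine.size_factors(counts)
    norm = de_engine.normalize(counts, sf)
    c = pseudocount

    def group_lfc(g1: list[str], g2: list[str]) -> np.ndarray:
        return np.log2(
            (norm[g1].mean(axis=1) + c) / (norm[g2].mean(axis=1) + c)
        ).to_numpy()

    sim_wt = sub.samples_for("sim", "WT")
    sim_ko = sub.samples_for("sim", "KO")
    mel_wt = sub.samples_for("mel", "WT")
    mel_ko = sub.samples_for("mel", "KO")
    repl = sub.samples_for("mel", "replacement")
    if len(repl) < 2:
        raise ValueError("cross-replicate correction needs >=2 replacement replicates")
    A = group_lfc(sim_wt, sim_ko)
    C = group_lfc(mel_wt, mel_ko)
    B = group_lfc(repl, mel_ko)
    naive_r = float(stats.pearsonr(B - A, C - B)[0])

    half = len(repl) // 2
    rs = []
    for subset1 in combinations(sorted(repl), half):
        subset2 = [s for s in repl if s not in subset1]
        b1 = np.log2((norm[list(subset1)].mean(axis=1) + c)
                     / (norm[mel_ko].mean(axis=1) + c)).to_numpy()
        b2 = np.log2((norm[subset2].mean(axis=1) + c)
                     / (norm[mel_ko].mean(axis=1) + c)).to_numpy()
        rs.append(stats.pearsonr(b1 - A, C - b2)[0])
    return CrossReplicateResult(
        corrected_r=float(np.mean(rs)),
        naive_r=naive_r,
        n_splits=len(rs),
        n_genes=len(counts),
    )


def category_divergence_test(
    gdiv: pd.DataFrame, genes: pd.Index
) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean WT divergence against zero for
    a gene subset.  Returns (t, p)."""
    values = gdiv.loc[gdiv.index.intersection(genes), "d_WT"].to_numpy(dtype=float)
    if len(values) < 3:
        raise ValueError("need >= 3 genes")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance in divergence values")
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ScanConfig:
    """Bootstrap quantile-outlier scan parameters."""

    n_boot: int = 10_000
    q: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    signed: bool = True  # scan on signed d_WT (mel-up outliers); False: |d_WT|

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.n_boot < 100:
            warnings.warn(
                "fewer than 100 bootstrap replicates: quantile cutoffs will "
                "be unstable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ScanResult:
    candidates: pd.Index  # divergence-significant AND category III
    significant: pd.Index  # divergence-significant genes
    bootstrap_frac: pd.Series  # per gene: fraction of replicates exceeded
    quantiles: np.ndarray  # the n_boot bootstrap quantiles


def selection_scan(
    gdiv: pd.DataFrame, records: pd.DataFrame, config: ScanConfig | None = None
) -> ScanResult:
    """Bootstrap scan for selection candidates.

    Resamples the expressed genes' WT divergence values with replacement
    ``n_boot`` times, recording the q-quantile of each replicate.  A gene
    is divergence-significant when its value exceeds the recorded quantile
    in at least (1 - alpha) of replicates; candidates are the intersection
    with category III (enhancing) genes.  Deterministic for a fixed seed.
    """
    config = config or ScanConfig()
    common = gdiv.index.intersection(records.index)
    values = gdiv.loc[common, "d_WT"].to_numpy(dtype=float)
    if not config.signed:
        values = np.abs(values)
    n = len(values)
    if n == 0:
        raise ValueError("no genes to scan")
    rng = np.random.default_rng(config.seed)
    quantiles = np.empty(config.n_boot)
    for b in range(config.n_boot):
        quantiles[b] = np.quantile(values[rng.integers(0, n, n)], config.q)
    sorted_q = np.sort(quantiles)
    frac = np.searchsorted(sorted_q, values, side="left") / config.n_boot
    significant = frac >= 1.0 - config.alpha
    cat3 = (records.loc[common, "category"] == "III").to_numpy()
    return ScanResult(
        candidates=common[significant & cat3],
        significant=common[significant],
        bootstrap_frac=pd.Series(frac, index=common, name="bootstrap_frac"),
        quantiles=quantiles,
    )
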