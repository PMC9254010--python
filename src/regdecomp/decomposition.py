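"""Decomposition of single-regulator (trans) and genomic-context (cis)
effects from the five-genotype knockout/replacement design.

Three within-species contrasts are estimated per gene:

* A = log2(sim WT / sim KO)            -- the regulator's effect in its own
  genomic background,
* B = log2(replacement / mel KO)       -- the foreign regulator's effect in
  the mel background,
* C = log2(mel WT / mel KO)            -- the native regulator's effect in
  the mel background.

The context effect is B - A (same regulator, different background) and the
regulator ("miR") effect is C - B (different regulator, same background).
Two pairwise difference tests (A vs B, B vs C) classify each gene into six
categories: I regulator-only, II context-only, III both acting in the same
direction (enhancing), IV both in opposite directions (compensating),
V conserved, VI ambiguous (a required genotype has no expression, so a
contrast is inestimable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import de_engine
from .counts_io import CountMatrix, SampleSheet

ALPHA = 0.05

CATEGORIES = ("I", "II", "III", "IV", "V", "VI")

#: Contrast name -> ((species, genotype) numerator, (species, genotype) baseline)
CONTRAST_DESIGN = {
    "A": (("sim", "WT"), ("sim", "KO")),
    "B": (("mel", "replacement"), ("mel", "KO")),
    "C": (("mel", "WT"), ("mel", "KO")),
}


def build_contrasts(
    merged: CountMatrix | pd.DataFrame,
    sheet: SampleSheet,
    stage: str | None = None,
    genes: pd.Index | None = None,
    pseudocount: float = de_engine.PSEUDOCOUNT,
) -> pd.DataFrame:
    """Estimate contrasts A, B, C for every gene of one analysis unit.

    Size factors are computed jointly over all samples of the unit so the
    three contrasts share one normalization scale.  Returns a wide table
    with, per contrast X: ``X, X_se, X_v1, X_v2, X_n1, X_n2, X_ok`` where
    v1/v2 are the numerator-/baseline-group variance contributions to se^2.
    """
    counts = merged.counts if isinstance(merged, CountMatrix) else merged
    sub = sheet.subset(stage)
    samples = [s for s in sub.sample_ids if s in counts.columns]
    counts = counts[samples]
    if genes is not None:
        counts = counts.loc[genes]
    sf = de_engine.size_factors(counts)
    pieces = {}
    for name, (num_cell, base_cell) in CONTRAST_DESIGN.items():
        g1 = sub.samples_for(*num_cell)
        g2 = sub.samples_for(*base_cell)
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(
                f"contrast {name} needs >=2 replicates in {num_cell} and "
                f"{base_cell}; found {len(g1)} and {len(g2)}"
            )
        res = de_engine.contrast_lfc(counts, g1, g2, sf, pseudocount)
        pieces[name] = res
    out = pd.DataFrame(index=counts.index)
    for name, res in pieces.items():
        out[name] = res["lfc"]
        out[f"{name}_se"] = res["se"]
        out[f"{name}_v1"] = res["v1"]
        out[f"{name}_v2"] = res["v2"]
        out[f"{name}_n1"] = res["n1"]
        out[f"{name}_n2"] = res["n2"]
        out[f"{name}_ok"] = res["ok"]
    return out


def diff_test(
    lfc1: np.ndarray | float,
    se1: np.ndarray | float,
    lfc2: np.ndarray | float,
    se2: np.ndarray | float,
    df: np.ndarray | float | None = None,
) -> np.ndarray:
    """Two-sided test of equality of two log2 fold changes.

    z = (lfc1 - lfc2) / sqrt(se1^2 + se2^2), referred to the standard
    normal by default, or to Student's t with ``df`` degrees of freedom
    when given (appropriate when the standard errors come from few
    replicates).
    """
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if (se1 <= 0).any() or (se2 <= 0).any():
        raise ValueError("standard errors must be positive")
    z = (np.asarray(lfc1, dtype=float) - np.asarray(lfc2, dtype=float)) / np.sqrt(
        se1**2 + se2**2
    )
    if df is None:
        return 2.0 * stats.norm.sf(np.abs(z))
    return 2.0 * stats.t.sf(np.abs(z), df)


def classify(
    contrasts: pd.DataFrame,
    alpha: float = ALPHA,
    residual_df: bool = True,
    shared_baseline: bool = True,
) -> pd.DataFrame:
    """Classify genes into categories I-VI from the contrast table.

    ``residual_df=True`` refers each difference test to Student's t with
    the residual degrees of freedom of the replicate groups whose variance
    enters the test (sum of n_i - 1); with False, the normal reference is
    used.  ``shared_baseline=True`` accounts for B and C sharing the mel KO
    baseline: in the B vs C test the shared baseline cancels exactly in
    B - C, so only the replacement and mel WT variance components enter the
    standard error.  Both corrections matter for type-I-error calibration
    at realistic replicate numbers; see the methods note.

    No multiplicity correction is applied: classification compares raw
    p-values to ``alpha``.
    """
    ct = contrasts
    ok = ct["A_ok"] & ct["B_ok"] & ct["C_ok"]
    se_ab = np.sqrt(ct["A_se"] ** 2 + ct["B_se"] ** 2)
    df_ab = (
        (ct["A_n1"] - 1) + (ct["A_n2"] - 1) + (ct["B_n1"] - 1) + (ct["B_n2"] - 1)
        if residual_df
        else None
    )
    if shared_baseline:
        se_bc = np.sqrt(ct["B_v1"] + ct["C_v1"])
        df_bc = (ct["B_n1"] - 1) + (ct["C_n1"] - 1) if residual_df else None
    else:
        se_bc = np.sqrt(ct["B_se"] ** 2 + ct["C_se"] ** 2)
        df_bc = (
            (ct["B_n1"] - 1) + (ct["B_n2"] - 1) + (ct["C_n1"] - 1) + (ct["C_n2"] - 1)
            if residual_df
            else None
        )
    # inestimable genes keep NaN p-values; they are category VI regardless
    se_ab = np.where(ok & (se_ab > 0), se_ab, np.nan)
    se_bc = np.where(ok & (se_bc > 0), se_bc, np.nan)

    def _p(z, df):
        if df is None:
            return 2.0 * stats.norm.sf(np.abs(z))
        return 2.0 * stats.t.sf(np.abs(z), np.asarray(df, dtype=float))

    with np.errstate(invalid="ignore"):
        p_ab = _p((ct["A"] - ct["B"]).to_numpy() / se_ab, df_ab)
        p_bc = _p((ct["B"] - ct["C"]).to_numpy() / se_bc, df_bc)
    sig_ab = p_ab < alpha
    sig_bc = p_bc < alpha
    prod = (ct["A"] - ct["B"]) * (ct["B"] - ct["C"])
    category = np.select(
        [
            ~ok,
            ~sig_ab & sig_bc,
            sig_ab & ~sig_bc,
            sig_ab & sig_bc & (prod > 0),
            sig_ab & sig_bc & (prod <= 0),
        ],
        ["VI", "I", "II", "III", "IV"],
        default="V",
    )
    interaction = np.select(
        [category == "III", category == "IV"],
        ["enhancing", "compensating"],
        default="none",
    )
    out = pd.DataFrame(
        {
            "A": ct["A"],
            "se_A": ct["A_se"],
            "B": ct["B"],
            "se_B": ct["B_se"],
            "C": ct["C"],
            "se_C": ct["C_se"],
            "context_effect": ct["B"] - ct["A"],
            "mir_effect": ct["C"] - ct["B"],
            "p_AB": p_ab,
            "p_BC": p_bc,
            "category": category,
            "interaction": interaction,
        },
        index=ct.index,
    )
    out.loc[~ok, ["p_AB", "p_BC"]] = np.nan
    return out


def category_counts(records: pd.DataFrame) -> pd.Series:
    """Counts of genes per category, in the fixed order I..VI."""
    return records["category"].value_counts().reindex(CATEGORIES, fill_value=0)


@dataclass(frozen=True)
class MagnitudeComparison:
    """Wilcoxon rank-sum comparison of |context| vs |miR| magnitudes."""

    statistic: float
    p_two_sided: float
    p_context_greater: float
    n: int


def magnitude_comparison(
    records: pd.DataFrame, genes: pd.Index | None = None
) -> MagnitudeComparison:
    """Compare |B - A| (context) against |C - B| (miR) over a gene subset.

    Uses the rank-sum test with the normal approximation and tie
    correction (no continuity correction, so identical samples yield
    p = 1 exactly).
    """
    sub = records if genes is None else records.loc[genes]
    if len(sub) == 0:
        raise ValueError("empty gene subset")
    ctx = np.abs(sub["context_effect"].to_numpy(dtype=float))
    mir = np.abs(sub["mir_effect"].to_numpy(dtype=float))
    two = stats.mannwhitneyu(
        ctx, mir, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    one = stats.mannwhitneyu(
        ctx, mir, alternative="greater", method="asymptotic", use_continuity=False
    )
    return MagnitudeComparison(
        statistic=float(two.statistic),
        p_two_sided=float(two.pvalue),
        p_context_greater=float(one.pvalue),
        n=len(sub),
    )
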