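"""Prioritization of candidate amplified driver genes.

Pipeline: amplification-frequency filter, per-gene copy-number/expression
Pearson correlation, BH-FDR candidate selection, essentiality ranking,
plus a Fisher's-exact 2x2 clinical association helper.

Copy-number matrices use GISTIC-style integer codes:
-2 deep loss, -1 loss, 0 diploid, +1 gain, +2 amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CandidateGene",
    "amplification_frequency",
    "cn_expression_correlation",
    "cn_expression_correlations",
    "bh_fdr",
    "select_candidates",
    "rank_by_essentiality",
    "clinical_association_2x2",
]

CN_CODES = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    amp_frequency: float
    pearson_r: float
    p_value: float
    fdr: float
    essentiality: float | None = None
    rank: int | None = None


def _validate_cn(cn: pd.DataFrame) -> None:
    if cn.shape[1] == 0:
        raise ValueError("copy-number matrix has zero samples")
    if cn.columns.duplicated().any():
        raise ValueError("sample IDs must be unique")
    vals = cn.to_numpy()
    if not np.isin(vals[~np.isnan(vals.astype(float))], CN_CODES).all():
        raise ValueError("copy-number codes must be in {-2,-1,0,1,2}")


def amplification_frequency(cn: pd.DataFrame, min_code: int = 1) -> pd.Series:
    """Per-gene fraction of samples with CN code >= min_code.

    min_code=1 pools gain and amplification; min_code=2 restricts to
    amplification proper.
    """
    if min_code not in (1, 2):
        raise ValueError("min_code must be 1 or 2")
    _validate_cn(cn)
    freq = (cn.to_numpy() >= min_code).mean(axis=1)
    return pd.Series(freq, index=cn.index, name="amp_frequency")


def cn_expression_correlation(
    cn_row: np.ndarray | pd.Series,
    expr_row: np.ndarray | pd.Series,
    include_losses: bool = False,
) -> tuple[float, float]:
    """Pearson r and two-sided t-based p between CN codes and expression.

    Restricted by default to samples with codes {0, 1, 2} (losses excluded,
    matching the diploid/gain/amplification comparison). Returns
    (nan, nan) when fewer than 3 usable pairs remain or either vector has
    zero variance; such genes are excluded from candidacy.
    """
    cn_arr = np.asarray(cn_row, dtype=float)
    ex_arr = np.asarray(expr_row, dtype=float)
    if cn_arr.shape != ex_arr.shape:
        raise ValueError("cn and expression rows must align on samples")
    mask = np.isfinite(cn_arr) & np.isfinite(ex_arr)
    if not include_losses:
        mask &= cn_arr >= 0
    cn_arr, ex_arr = cn_arr[mask], ex_arr[mask]
    if cn_arr.size < 3:
        return math.nan, math.nan
    if np.ptp(cn_arr) == 0 or np.ptp(ex_arr) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(cn_arr, ex_arr)
    return float(r), float(p)


def cn_expression_correlations(
    cn: pd.DataFrame, expr: pd.DataFrame, include_losses: bool = False
) -> pd.DataFrame:
    """Per-gene CN-expression correlation table (gene, pearson_r, p_value, n).

    Requires identical sample ID sets; genes are taken from the
    intersection of the two row indexes.
    """
    if set(cn.columns) != set(expr.columns):
        raise ValueError("paired analysis requires identical sample ID sets")
    expr = expr[cn.columns]
    genes = cn.index.intersection(expr.index)
    rows = []
    for gene in genes:
        r, p = cn_expression_correlation(
            cn.loc[gene], expr.loc[gene], include_losses=include_losses
        )
        codes = cn.loc[gene].to_numpy(dtype=float)
        n = int(((codes >= 0) | include_losses).sum())
        rows.append((gene, r, p, n))
    return pd.DataFrame(rows, columns=["gene", "pearson_r", "p_value", "n"]).set_index(
        "gene"
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_candidates(
    freq: pd.Series,
    corr: pd.DataFrame,
    freq_min: float = 0.05,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Candidate genes: freq >= freq_min, r > 0, BH-FDR < fdr_max.

    FDR is computed once over every gene with a defined correlation (the
    tested universe), not only over frequency-passing genes.
    """
    if len(freq) == 0 or len(corr) == 0:
        raise ValueError("empty gene universe")
    genes = freq.index.intersection(corr.index)
    if len(genes) == 0:
        raise ValueError("frequency and correlation tables share no genes")
    table = corr.loc[genes].copy()
    table["amp_frequency"] = freq.loc[genes]
    tested = table["p_value"].notna()
    table["fdr"] = np.nan
    table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p_value"].to_numpy())
    keep = (
        tested
        & (table["amp_frequency"] >= freq_min)
        & (table["pearson_r"] > 0)
        & (table["fdr"] < fdr_max)
    )
    out = table.loc[keep].reset_index().rename(columns={"index": "gene"})
    if "gene" not in out.columns:  # index name preserved
        out = out.rename(columns={out.columns[0]: "gene"})
    return out[["gene", "amp_frequency", "pearson_r", "p_value", "fdr"]]


def rank_by_essentiality(
    candidates: pd.DataFrame, essentiality: pd.Series
) -> pd.DataFrame:
    """Rank candidates ascending by essentiality score (lower = rank 1).

    Genes missing from the essentiality table sort last and are flagged
    via ``essentiality_missing``. Ties break lexicographically by gene
    symbol for determinism.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    out = candidates.copy()
    out["essentiality"] = out["gene"].map(essentiality)
    out["essentiality_missing"] = out["essentiality"].isna()
    key = out["essentiality"].fillna(np.inf)
    order = np.lexsort((out["gene"].to_numpy(), key.to_numpy()))
    out = out.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def clinical_association_2x2(
    group: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Fisher's exact test of a binary group against a binary outcome.

    Returns (odds_ratio, two_sided_p). The odds ratio uses a Haldane
    (+0.5 per cell) correction whenever any cell is zero. A zero margin
    yields p = 1.0 and an undefined (nan) odds ratio.
    """
    g = np.asarray(group).astype(int)
    o = np.asarray(outcome).astype(int)
    if g.shape != o.shape:
        raise ValueError("group and outcome must cover the same samples")
    if not (np.isin(g, (0, 1)).all() and np.isin(o, (0, 1)).all()):
        raise ValueError("group and outcome must be binary 0/1 vectors")
    a = int(((g == 1) & (o == 1)).sum())
    b = int(((g == 1) & (o == 0)).sum())
    c = int(((g == 0) & (o == 1)).sum())
    d = int(((g == 0) & (o == 0)).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        return math.nan, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
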