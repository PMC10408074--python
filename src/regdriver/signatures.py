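"""Joint direct-target signature construction and signature scoring.

The joint direct-target signature is the set of genes differentially
expressed (FDR < 0.1) upon knockdown of *both* factors, concordantly by
default, whose promoter window (TSS +/- 5 kb) carries at least one peak
of *each* factor. Signature scores are (weighted) sums of per-gene
z-normalized expression across samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from regdriver.intervals import PeakSet, intersect_intervals, merge_intervals

__all__ = [
    "SignatureDefinition",
    "CorrelationResult",
    "filter_low_expression",
    "select_de_genes",
    "common_de_genes",
    "joint_direct_targets",
    "build_joint_signature",
    "score_signature",
    "correlate_scores",
    "load_ar_panel",
    "read_signature",
    "write_signature",
    "read_de_table",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene panel with per-gene weights (default +1)."""

    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValueError("|genes| must equal |weights|")

    def weight_map(self) -> dict[str, float]:
        w = self.weights or tuple(1.0 for _ in self.genes)
        return dict(zip(self.genes, w))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def filter_low_expression(counts: pd.DataFrame, min_total: float = 2) -> pd.Index:
    """Genes with cumulative read count across samples >= min_total."""
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    return counts.index[totals >= min_total]


def select_de_genes(de: pd.DataFrame, fdr_max: float = 0.1) -> pd.DataFrame:
    """DE genes at fdr < fdr_max (strict), annotated with direction = sign(log2fc)."""
    for col in ("gene", "log2fc", "fdr"):
        if col not in de.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if de["gene"].duplicated().any():
        raise ValueError("gene must be unique per DE table")
    out = de.loc[de["fdr"] < fdr_max].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


def common_de_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    require_concordant: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two selected DE tables.

    Returns (common, discordant). With ``require_concordant`` (default)
    a gene is common only when sign(log2fc) agrees in both tables;
    direction-discordant genes come back in the second frame. With the
    flag off the plain intersection is returned and discordant is empty.
    """
    merged = de_a.merge(de_b, on="gene", suffixes=("_a", "_b"))
    if not require_concordant:
        return merged, merged.iloc[0:0]
    concordant = merged["direction_a"] == merged["direction_b"]
    return merged.loc[concordant].copy(), merged.loc[~concordant].copy()


def joint_direct_targets(
    common: pd.DataFrame,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    promoters: PeakSet,
) -> tuple[list[str], list[str]]:
    """Genes from ``common`` bound by both factors in their promoter window.

    A gene qualifies iff >= 1 peak of each factor overlaps its promoter;
    the two factors' peaks need not overlap each other. Genes without a
    promoter window (missing annotation) are excluded with a warning.
    Returns (targets, missing_annotation).
    """
    genes = list(common["gene"])
    have_window = {iv.name for iv in promoters}
    missing = [g for g in genes if g not in have_window]
    if missing:
        warnings.warn(
            f"{len(missing)} common DE genes lack promoter annotation "
            "and were excluded",
            stacklevel=2,
        )
    bound_a = {
        iv.name
        for iv, _ in intersect_intervals(promoters, merge_intervals(peaks_a))
    }
    bound_b = {
        iv.name
        for iv, _ in intersect_intervals(promoters, merge_intervals(peaks_b))
    }
    targets = [g for g in genes if g in bound_a and g in bound_b]
    return targets, missing


def build_joint_signature(
    targets: list[str],
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    name: str = "joint_direct_targets",
    weighting: str = "sign_mean_log2fc",
) -> SignatureDefinition:
    """Signature over the joint targets.

    Default weights: sign of the mean log2fc of the gene across the two
    knockdown tables, magnitude 1 (direction-aware, magnitude-free).
    ``weighting='unit'`` uses +1 for every gene.
    """
    if weighting == "unit":
        return SignatureDefinition(name, tuple(targets))
    if weighting != "sign_mean_log2fc":
        raise ValueError(f"unknown weighting {weighting!r}")
    fc_a = de_a.set_index("gene")["log2fc"]
    fc_b = de_b.set_index("gene")["log2fc"]
    weights = []
    for g in targets:
        mean_fc = np.mean([fc_a.get(g, 0.0), fc_b.get(g, 0.0)])
        weights.append(1.0 if mean_fc >= 0 else -1.0)
    return SignatureDefinition(name, tuple(targets), tuple(weights))


def score_signature(
    expr: pd.DataFrame,
    sig: SignatureDefinition,
    mode: str = "z_sum",
) -> pd.Series:
    """Per-sample signature score: sum over panel genes of w_g * z_{g,s}.

    Each gene is z-normalized across samples (population sd). Modes:
    ``z_sum`` forces unit weights; ``weighted_z_sum`` uses the panel's
    weights. Panel genes absent from the matrix or with zero variance
    are skipped with a warning; an empty panel/matrix intersection is an
    error and the score of an empty sum is 0.
    """
    if mode not in {"z_sum", "weighted_z_sum"}:
        raise ValueError(f"unknown mode {mode!r}")
    present = [g for g in sig.genes if g in expr.index]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is in the matrix")
    absent = set(sig.genes) - set(present)
    if absent:
        warnings.warn(
            f"{len(absent)} signature genes absent from the matrix: "
            f"{sorted(absent)[:5]}...",
            stacklevel=2,
        )
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance signature genes skipped",
            stacklevel=2,
        )
        sub = sub.loc[~degenerate]
        sd = sd.loc[~degenerate]
    if sub.empty:
        return pd.Series(0.0, index=expr.columns, name=sig.name)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    wmap = sig.weight_map()
    w = np.ones(len(z)) if mode == "z_sum" else np.array([wmap[g] for g in z.index])
    score = pd.Series(z.to_numpy().T @ w, index=expr.columns, name=sig.name)
    return score


def correlate_scores(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> CorrelationResult:
    """Pearson r with a two-sided t-based p between two paired vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must be paired")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(math.nan, math.nan, xa.size)
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(float(r), float(p), int(xa.size))


def load_ar_panel() -> SignatureDefinition:
    """The packaged 30-gene androgen-receptor signaling panel."""
    with resources.files("regdriver.data").joinpath("ar_panel_30.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return SignatureDefinition(
        "AR_signaling_30", tuple(df["gene"]), tuple(df["weight"].astype(float))
    )


def read_signature(path: str | Path, name: str | None = None) -> SignatureDefinition:
    """Two-column TSV (gene, weight) -> SignatureDefinition."""
    df = pd.read_csv(path, sep="\t")
    weights = (
        tuple(df["weight"].astype(float)) if "weight" in df.columns else None
    )
    return SignatureDefinition(name or Path(path).stem, tuple(df["gene"]), weights)


def write_signature(sig: SignatureDefinition, path: str | Path) -> None:
    pd.DataFrame({"gene": sig.genes, "weight": list(sig.weight_map().values())}).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path: str | Path) -> pd.DataFrame:
    """DE table TSV with columns gene, log2fc, p_value, fdr[, mean_count]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "p_value", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df
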