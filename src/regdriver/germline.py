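"""Inherited-risk layer: LD proxies, SNP-in-peak enrichment, eQTL mapping,
PWM allele-affinity deltas, allelic imbalance, and qPCR quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from regdriver.intervals import (
    PeakSet,
    assign_points_to_peaks,
    intersection_regions,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "SNPRecord",
    "PWM",
    "StandardCurve",
    "ld_r2",
    "expand_proxies",
    "cooccupancy_categories",
    "snp_peak_enrichment",
    "map_eqtl_genes",
    "pwm_allele_delta",
    "allelic_imbalance",
    "fit_standard_curve",
    "qpcr_quantify",
    "read_snp_table",
    "read_vcf_snps",
    "read_pwm",
    "write_pwm",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP; ``pos`` is 0-based."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    risk_allele: str | None = None
    is_tag: bool = False

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.rsid}: alleles must be one of A,C,G,T")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt must differ")
        if self.risk_allele is not None and self.risk_allele not in (
            self.ref,
            self.alt,
        ):
            raise ValueError(f"{self.rsid}: risk allele must be ref or alt")

    @property
    def other_allele(self) -> str:
        if self.risk_allele is None:
            raise ValueError(f"{self.rsid}: no risk allele set")
        return self.alt if self.risk_allele == self.ref else self.ref


@dataclass
class PWM:
    """Position probability matrix with log-odds scoring support."""

    motif_id: str
    matrix: np.ndarray  # L x 4, rows sum to 1, order A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2((p + pc) / (bg + pc)) per position/base."""
        p = self.matrix + self.pseudocount
        bg = self.background + self.pseudocount
        return np.log2(p / bg[None, :])


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR standard curve: ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r2: float


def ld_r2(g1: np.ndarray | pd.Series, g2: np.ndarray | pd.Series) -> float:
    """Composite LD: squared Pearson correlation of dosages, pairwise-complete.

    Returns nan (flagged) for monomorphic SNPs or < 3 complete pairs.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must cover the same individuals")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def expand_proxies(
    tags: list[str],
    snps: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    ld_pairs: pd.DataFrame | None = None,
    r2_min: float = 0.5,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Expand tag SNPs to proxies with r^2 >= r2_min (inclusive) in a window.

    ``snps`` columns: rsid, chrom, pos. LD comes either from a dosage
    ``genotypes`` matrix (SNPs x individuals, computed on the fly) or a
    precomputed ``ld_pairs`` table (tag, proxy, r2). A tag is always its
    own proxy with r^2 = 1. Tags missing from the LD source are reported
    with a warning flag in the output (column ``tag_found``).
    """
    if genotypes is None and ld_pairs is None:
        raise ValueError("provide genotypes or a precomputed LD table")
    pos = snps.set_index("rsid")
    rows = []
    for tag in tags:
        if tag not in pos.index:
            rows.append((tag, tag, np.nan, False))
            continue
        t_chrom, t_pos = pos.at[tag, "chrom"], int(pos.at[tag, "pos"])
        in_window = pos[
            (pos["chrom"] == t_chrom) & (abs(pos["pos"] - t_pos) <= window_bp)
        ].index
        rows.append((tag, tag, 1.0, True))
        for proxy in in_window:
            if proxy == tag:
                continue
            if genotypes is not None:
                if tag not in genotypes.index or proxy not in genotypes.index:
                    continue
                r2 = ld_r2(genotypes.loc[tag], genotypes.loc[proxy])
            else:
                hit = ld_pairs[
                    ((ld_pairs["tag"] == tag) & (ld_pairs["proxy"] == proxy))
                    | ((ld_pairs["tag"] == proxy) & (ld_pairs["proxy"] == tag))
                ]
                if hit.empty:
                    continue
                r2 = float(hit["r2"].max())
            if np.isfinite(r2) and r2 >= r2_min:
                rows.append((tag, proxy, r2, True))
    return pd.DataFrame(rows, columns=["tag", "proxy", "r2", "tag_found"])


def cooccupancy_categories(a: PeakSet, b: PeakSet) -> dict[str, PeakSet]:
    """Region partition {A-only, B-only, common} from two peak sets."""
    a_m = a if a.merged else merge_intervals(a)
    b_m = b if b.merged else merge_intervals(b)
    return {
        "a_only": subtract_intervals(a_m, b_m),
        "b_only": subtract_intervals(b_m, a_m),
        "common": intersection_regions(a_m, b_m),
    }


def snp_peak_enrichment(
    snps: pd.DataFrame,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    background: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation fold-enrichment of risk SNPs in co-occupancy categories.

    For each category in {a_only, b_only, common}: observed = # risk SNPs
    inside category regions; null = same count for ``len(snps)`` SNPs drawn
    without replacement from the background pool, repeated n_perm times;
    fold = observed / mean(null); empirical p = (1 + #{null >= obs})/(1 + n_perm).
    """
    if len(background) < len(snps):
        raise ValueError("background pool smaller than the risk SNP set")
    rng = np.random.default_rng(seed)
    categories = cooccupancy_categories(peaks_a, peaks_b)
    risk_points = list(zip(snps["chrom"], snps["pos"].astype(int)))
    bg_points = list(zip(background["chrom"], background["pos"].astype(int)))
    n_draw, n_bg = len(risk_points), len(bg_points)
    rows = []
    for name, regions in categories.items():
        observed = int(assign_points_to_peaks(risk_points, regions).sum())
        inside_bg = assign_points_to_peaks(bg_points, regions).astype(np.int64)
        # vectorized without-replacement draws: argpartition of random keys
        keys = rng.random((n_perm, n_bg))
        idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        null = inside_bg[idx].sum(axis=1)
        fold = observed / null.mean() if null.mean() > 0 else math.inf
        p = (1 + int((null >= observed).sum())) / (1 + n_perm)
        rows.append((name, observed, float(null.mean()), float(fold), p))
    return pd.DataFrame(
        rows, columns=["category", "observed", "null_mean", "fold", "p_value"]
    )


def map_eqtl_genes(proxies: pd.DataFrame, eqtl: pd.DataFrame) -> pd.DataFrame:
    """Join proxies-in-peaks to eQTL eGenes on rsid.

    ``proxies`` columns: tag, proxy[, category]; ``eqtl`` columns: rsid,
    egene[, source]. One row per (tag, proxy, egene); proxies with no
    eGene keep an empty-string egene so no locus is silently dropped.
    """
    left = proxies.copy()
    if "category" not in left.columns:
        left["category"] = ""
    right = eqtl.rename(columns={"rsid": "proxy"})
    out = left.merge(right, on="proxy", how="left")
    out["egene"] = out["egene"].fillna("")
    if "source" in out.columns:
        out["source"] = out["source"].fillna("")
    return out


def _score_windows(log_odds: np.ndarray, seq: str) -> float:
    """Best log-odds placement of the motif over both strands of ``seq``."""
    L = log_odds.shape[0]
    best = -math.inf
    for strand_seq in (seq, seq[::-1].translate(_COMPLEMENT)):
        idx = np.array([_BASE_INDEX[c] for c in strand_seq])
        for off in range(len(idx) - L + 1):
            s = float(log_odds[np.arange(L), idx[off : off + L]].sum())
            if s > best:
                best = s
    return best


def pwm_allele_delta(
    pwm: PWM,
    sequence: str,
    snp: SNPRecord,
    snp_offset: int,
) -> tuple[float, float, float, str]:
    """Best motif log-odds for each allele and the risk-minus-other delta.

    ``sequence`` must carry the ref allele at ``snp_offset`` and cover at
    least pwm length - 1 bases on each side of the SNP. Placements are
    restricted to windows covering the SNP, scored on both strands.
    Returns (best_ref, best_alt, delta, preferred_allele); delta is
    positive when the risk allele scores higher.
    """
    sequence = sequence.upper()
    if any(c not in _BASES for c in sequence):
        raise ValueError("sequence contains a non-ACGT character")
    if sequence[snp_offset] != snp.ref:
        raise ValueError(
            f"{snp.rsid}: sequence has {sequence[snp_offset]!r} at the SNP, "
            f"expected ref allele {snp.ref!r}"
        )
    L = len(pwm)
    lo = max(0, snp_offset - (L - 1))
    hi = min(len(sequence), snp_offset + L)
    if snp_offset - lo < L - 1 or hi - snp_offset < L:
        raise ValueError("sequence must cover pos +/- (L-1) around the SNP")
    window = sequence[lo:hi]
    rel = snp_offset - lo
    log_odds = pwm.log_odds()
    seq_ref = window
    seq_alt = window[:rel] + snp.alt + window[rel + 1 :]
    best_ref = _score_windows(log_odds, seq_ref)
    best_alt = _score_windows(log_odds, seq_alt)
    risk = snp.risk_allele or snp.alt
    if risk == snp.alt:
        delta = best_alt - best_ref
    else:
        delta = best_ref - best_alt
    if best_ref == best_alt:
        preferred = "none"
    else:
        preferred = snp.ref if best_ref > best_alt else snp.alt
    return best_ref, best_alt, delta, preferred


def allelic_imbalance(
    count_risk: int, count_other: int
) -> tuple[float, float]:
    """Risk-allele fraction and exact two-sided binomial p against 0.5.

    Two-sided p sums the point probabilities <= that of the observed
    count (scipy's exact binomial test definition).
    """
    if count_risk < 0 or count_other < 0:
        raise ValueError("allele counts must be nonnegative")
    total = count_risk + count_other
    if total == 0:
        raise ValueError("total allele count is zero")
    ratio = count_risk / total
    p = stats.binomtest(count_risk, total, 0.5, alternative="two-sided").pvalue
    return float(ratio), float(p)


def fit_standard_curve(
    ct: np.ndarray, log10_quantity: np.ndarray
) -> StandardCurve:
    """Least-squares fit ct = slope * log10(quantity) + intercept."""
    res = stats.linregress(np.asarray(log10_quantity, float), np.asarray(ct, float))
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def qpcr_quantify(
    curve: StandardCurve,
    ct: np.ndarray | float,
    control_ct: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Quantity = 10^((ct - intercept)/slope), optionally control-normalized.

    With ``control_ct`` the result is quantity / control quantity (the
    same curve applied to the control), e.g. normalization to a loading
    control locus. Works elementwise on arrays.
    """
    if curve.slope == 0:
        raise ValueError("standard-curve slope must be nonzero")
    ct_arr = np.asarray(ct, dtype=float)
    if not np.isfinite(ct_arr).all():
        raise ValueError("non-finite ct value")
    q = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    if control_ct is not None:
        ctrl = np.asarray(control_ct, dtype=float)
        if not np.isfinite(ctrl).all():
            raise ValueError("non-finite control ct value")
        q = q / (10.0 ** ((ctrl - curve.intercept) / curve.slope))
    return float(q) if np.ndim(ct) == 0 else q


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """SNP TSV: rsid, chrom, pos (0-based), ref, alt[, risk_allele, is_tag]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    if "is_tag" in df.columns:
        df["is_tag"] = df["is_tag"].astype(bool)
    for rec in df.itertuples(index=False):
        risk = getattr(rec, "risk_allele", None)
        if not isinstance(risk, str):
            risk = None
        SNPRecord(
            rec.rsid,
            rec.chrom,
            rec.pos,
            rec.ref,
            rec.alt,
            risk,
            bool(getattr(rec, "is_tag", False)),
        )
    return df


def read_vcf_snps(path: str | Path) -> pd.DataFrame:
    """Minimal VCF (CHROM POS ID REF ALT ...) -> SNP table, 0-based positions."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: VCF data line with < 5 fields")
            chrom, pos, rsid, ref, alt = fields[:5]
            rows.append((rsid, chrom, int(pos) - 1, ref, alt))
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt"])


def read_pwm(path: str | Path) -> PWM:
    """PWM file: header 'A C G T' (tab-separated), one probability row per position."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["A", "C", "G", "T"]:
        raise ValueError("PWM file must have header columns A, C, G, T")
    return PWM(motif_id=Path(path).stem, matrix=df.to_numpy(dtype=float))


def write_pwm(pwm: PWM, path: str | Path) -> None:
    pd.DataFrame(pwm.matrix, columns=list(_BASES)).to_csv(path, sep="\t", index=False)
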