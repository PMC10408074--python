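"""Synthetic cohorts with planted ground truth for every pipeline stage.

Each generator is a pure function of (config, seed): the global seed fans
out to independent per-generator streams, so adding or re-running one
generator never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from regdriver.drivers import bh_fdr
from regdriver.germline import PWM, write_pwm
from regdriver.intervals import (
    GenomicInterval,
    PeakSet,
    write_bed,
    write_gene_annotation,
)

__all__ = [
    "SimConfig",
    "CohortSim",
    "PeakSim",
    "KnockdownSim",
    "GermlineSim",
    "gen_cohort",
    "gen_peaksets",
    "gen_knockdown_experiment",
    "gen_germline",
    "write_cohort",
    "write_peaksets",
    "write_knockdown",
    "write_germline",
]

# stream keys: keep stable so generators stay independent of each other
_STREAM_COHORT = 1
_STREAM_PEAKS = 2
_STREAM_KNOCKDOWN = 3
_STREAM_GERMLINE = 4


@dataclass
class SimConfig:
    """Knobs for every synthetic input; all sizes >= 1, probabilities in [0,1]."""

    seed: int
    # cohort
    n_samples: int = 200
    n_genes: int = 500
    n_driver_genes: int = 10
    amp_frequency: float = 0.10
    cn_expr_effect: float = 0.4  # target Pearson r for planted drivers
    true_hr: float = 2.0
    censoring_fraction: float = 0.3
    baseline_hazard: float = 0.02
    # toy genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 10_000_000,
            "chr2": 10_000_000,
            "chr3": 10_000_000,
        }
    )
    # peak sets
    n_peaks_a: int = 2000
    n_peaks_b: int = 2000
    cooccupancy_fraction: float = 0.5
    peak_width_log_mean: float = math.log(300.0)
    peak_width_log_sd: float = 0.3
    # knockdown experiment
    n_kd_genes: int = 1000
    n_joint_targets: int = 50
    n_de_only_decoys: int = 50
    n_bound_only_decoys: int = 50
    de_effect_size: float = 2.0
    promoter_flank: int = 5000
    # germline
    n_individuals: int = 100
    n_tag_snps: int = 5
    ld_block_size: int = 10
    ld_target_r2: float = 1.0
    n_background_snps: int = 2000
    n_risk_snps: int = 100
    risk_enrichment: float = 3.0
    allelic_ratio: float = 0.7
    read_depth: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "amp_frequency",
            "cooccupancy_fraction",
            "censoring_fraction",
            "allelic_ratio",
            "ld_target_r2",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not -1.0 < self.cn_expr_effect < 1.0:
            raise ValueError("cn_expr_effect must be a correlation in (-1,1)")
        for name in (
            "n_samples",
            "n_genes",
            "n_driver_genes",
            "n_peaks_a",
            "n_peaks_b",
            "n_kd_genes",
            "n_individuals",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("more driver genes than genes")
        if self.n_joint_targets > self.n_kd_genes:
            raise ValueError("more joint targets than knockdown genes")
        if self.n_driver_genes > 0 and self.amp_frequency == 0.0:
            raise ValueError("amp_frequency 0 with planted drivers is infeasible")
        if self.true_hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# cohort: CN / expression / essentiality / clinical


@dataclass
class CohortSim:
    copy_number: pd.DataFrame
    expression: pd.DataFrame
    essentiality: pd.Series
    clinical: pd.DataFrame
    truth: dict


def gen_cohort(cfg: SimConfig) -> CohortSim:
    """Linked CN/expression/essentiality/clinical tables with planted drivers.

    Driver genes carry gain/amplification codes at the configured
    frequency and expression = baseline + beta * code + N(0,1) with beta
    tuned so the population CN-expression Pearson r equals
    ``cfg.cn_expr_effect``. The first driver is the designated
    most-essential gene and also drives survival: samples above its
    expression median have hazard multiplied by ``cfg.true_hr``.
    """
    rng = _rng(cfg, _STREAM_COHORT)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    drivers = genes[: cfg.n_driver_genes]
    top_driver = drivers[0]

    # copy-number codes
    cn = np.zeros((cfg.n_genes, cfg.n_samples), dtype=int)
    # non-drivers: background alteration mix (uncorrelated with expression)
    probs = np.array([0.01, 0.05, 0.80, 0.10, 0.04])
    cn[cfg.n_driver_genes :] = rng.choice(
        np.array([-2, -1, 0, 1, 2]),
        size=(cfg.n_genes - cfg.n_driver_genes, cfg.n_samples),
        p=probs,
    )
    # drivers: diploid/gain/amp only so correlation acts on codes {0,1,2}
    p_amp = cfg.amp_frequency
    cn[: cfg.n_driver_genes] = rng.choice(
        np.array([0, 1, 2]),
        size=(cfg.n_driver_genes, cfg.n_samples),
        p=[1 - p_amp, p_amp / 2, p_amp / 2],
    )

    # expression
    expr = rng.normal(5.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    r = cfg.cn_expr_effect
    if r != 0.0 and cfg.n_driver_genes > 0:
        # theoretical code variance under the planted distribution
        ec = p_amp / 2 + 2 * p_amp / 2
        ec2 = p_amp / 2 + 4 * p_amp / 2
        var_code = ec2 - ec**2
        beta = r / (math.sqrt(var_code) * math.sqrt(1 - r * r))
        expr[: cfg.n_driver_genes] = (
            5.0
            + beta * cn[: cfg.n_driver_genes]
            + rng.normal(0.0, 1.0, size=(cfg.n_driver_genes, cfg.n_samples))
        )

    gene_index = pd.Index(genes, name="gene")
    cn_df = pd.DataFrame(cn, index=gene_index, columns=samples)
    expr_df = pd.DataFrame(expr, index=gene_index, columns=samples)

    # essentiality: lower = more essential; top driver clearly lowest
    ess = rng.normal(0.0, 1.0, size=cfg.n_genes)
    ess[: cfg.n_driver_genes] = rng.normal(-1.5, 0.3, size=cfg.n_driver_genes)
    ess[0] = -4.0 + rng.normal(0.0, 0.1)
    ess_s = pd.Series(ess, index=gene_index, name="essentiality")

    # survival driven by top-driver expression
    exposure = (expr_df.loc[top_driver] > expr_df.loc[top_driver].median()).astype(int)
    lam = cfg.baseline_hazard * cfg.true_hr ** exposure.to_numpy()
    t_event = rng.exponential(1.0 / lam)
    cf = cfg.censoring_fraction
    if cf > 0:
        mu = cf / (1 - cf) * lam.mean()
        t_cens = rng.exponential(1.0 / mu, size=cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    genotype = rng.choice(["TT", "TC", "CC"], size=cfg.n_samples, p=[0.25, 0.5, 0.25])
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "gleason": rng.choice([6, 7, 8, 9], size=cfg.n_samples),
            "genotype_rs_risk": genotype,
            f"expr_{top_driver}": expr_df.loc[top_driver].to_numpy(),
            f"cn_{top_driver}": cn_df.loc[top_driver].to_numpy(),
        }
    )

    truth = {
        "driver_genes": drivers,
        "top_driver": top_driver,
        "true_r": {g: (r if g in drivers else 0.0) for g in genes},
        "amp_frequency": p_amp,
        "true_hr": cfg.true_hr,
        "exposure": dict(zip(samples, exposure.to_numpy().tolist())),
    }
    return CohortSim(cn_df, expr_df, ess_s, clinical, truth)


# ---------------------------------------------------------------------------
# peak sets with planted co-occupancy


class _Occupancy:
    """Per-chromosome bitmap; a 1-base guard ring keeps placements
    non-book-ended so merging never changes peak counts."""

    def __init__(self, chrom_lengths: dict[str, int]) -> None:
        self.maps = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}

    def free(self, chrom: str, start: int, end: int) -> bool:
        m = self.maps[chrom]
        lo = max(0, start - 1)
        hi = min(len(m), end + 1)
        return not m[lo:hi].any()

    def mark(self, chrom: str, start: int, end: int) -> None:
        self.maps[chrom][start:end] = True


@dataclass
class PeakSim:
    peaks_a: PeakSet
    peaks_b: PeakSet
    truth: dict


def _draw_width(cfg: SimConfig, rng: np.random.Generator) -> int:
    w = int(rng.lognormal(cfg.peak_width_log_mean, cfg.peak_width_log_sd))
    return int(np.clip(w, 50, 5000))


def gen_peaksets(cfg: SimConfig) -> PeakSim:
    """Two disjoint-within-set peak tracks with a planted co-occupancy fraction.

    round(f * n_b) peaks of B are placed to overlap distinct A peaks by
    >= 1 bp; the rest land in space free of A. Emitted sets are sorted
    and merged (construction keeps them non-overlapping, so counts are
    preserved exactly).
    """
    rng = _rng(cfg, _STREAM_PEAKS)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    mean_w = math.exp(cfg.peak_width_log_mean + cfg.peak_width_log_sd**2 / 2)
    if (cfg.n_peaks_a + cfg.n_peaks_b) * (mean_w + 2) > 0.5 * total:
        raise ValueError("toy genome too small for the requested peak counts")

    occ_a = _Occupancy(cfg.chrom_lengths)
    occ_b = _Occupancy(cfg.chrom_lengths)
    p_chrom = lengths / total

    def place_free(width: int, *occs: _Occupancy) -> GenomicInterval:
        for _ in range(10_000):
            chrom = chroms[rng.choice(len(chroms), p=p_chrom)]
            start = int(rng.integers(0, cfg.chrom_lengths[chrom] - width))
            if all(o.free(chrom, start, start + width) for o in occs):
                return GenomicInterval(chrom, start, start + width)
        raise ValueError("toy genome too crowded for non-overlapping placement")

    a_ivs: list[GenomicInterval] = []
    for _ in range(cfg.n_peaks_a):
        iv = place_free(_draw_width(cfg, rng), occ_a)
        occ_a.mark(iv.chrom, iv.start, iv.end)
        a_ivs.append(iv)

    n_common = round(cfg.cooccupancy_fraction * cfg.n_peaks_b)
    if n_common > cfg.n_peaks_a:
        raise ValueError("cooccupancy fraction needs more A peaks than available")
    partner_pool = list(rng.permutation(cfg.n_peaks_a))
    b_ivs: list[GenomicInterval] = []
    refills = 0
    for _ in range(n_common):
        placed = False
        while not placed:
            if not partner_pool:
                # distinct partners exhausted (possible when n_common == n_a):
                # reuse partners; fraction_b is unaffected
                if refills >= 5:
                    raise ValueError("could not place an overlapping B peak")
                partner_pool = list(rng.permutation(cfg.n_peaks_a))
                refills += 1
            a = a_ivs[int(partner_pool.pop())]
            for _ in range(50):
                w = _draw_width(cfg, rng)
                lo = max(0, a.start - w + 1)
                hi = min(cfg.chrom_lengths[a.chrom] - w, a.end - 1)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                if occ_b.free(a.chrom, start, start + w):
                    iv = GenomicInterval(a.chrom, start, start + w)
                    occ_b.mark(iv.chrom, iv.start, iv.end)
                    b_ivs.append(iv)
                    placed = True
                    break
    for _ in range(cfg.n_peaks_b - n_common):
        iv = place_free(_draw_width(cfg, rng), occ_a, occ_b)
        occ_b.mark(iv.chrom, iv.start, iv.end)
        b_ivs.append(iv)

    peaks_a = PeakSet("A", a_ivs, merged=True)
    peaks_b = PeakSet("B", b_ivs, merged=True)
    truth = {
        "cooccupancy_fraction": cfg.cooccupancy_fraction,
        "n_common_b": n_common,
        "n_a": cfg.n_peaks_a,
        "n_b": cfg.n_peaks_b,
    }
    return PeakSim(peaks_a, peaks_b, truth)


# ---------------------------------------------------------------------------
# paired knockdown DE tables + promoter binding


@dataclass
class KnockdownSim:
    de_a: pd.DataFrame
    de_b: pd.DataFrame
    annotations: pd.DataFrame
    peaks_a: PeakSet
    peaks_b: PeakSet
    truth: dict


def gen_knockdown_experiment(cfg: SimConfig) -> KnockdownSim:
    """Two knockdown DE tables sharing planted joint targets.

    Planted joint targets are concordantly differential in both tables
    (tiny simulated p-values; BH applied over all genes) and carry one
    peak of each factor inside their promoter window. Decoys: DE-only
    genes (differential, unbound) and bound-only genes (bound, null p).
    Genes are spaced >= 2*flank + 1 apart so promoter windows never collide.
    """
    rng = _rng(cfg, _STREAM_KNOCKDOWN)
    flank = cfg.promoter_flank
    spacing = 2 * flank + 1000
    chroms = list(cfg.chrom_lengths)
    capacity = sum((n - flank) // spacing for n in cfg.chrom_lengths.values())
    if capacity < cfg.n_kd_genes:
        raise ValueError(
            f"toy genome fits {capacity} genes at spacing {spacing}; "
            f"{cfg.n_kd_genes} requested"
        )
    n_special = cfg.n_joint_targets + cfg.n_de_only_decoys + cfg.n_bound_only_decoys
    if n_special > cfg.n_kd_genes:
        raise ValueError("planted + decoy genes exceed n_kd_genes")

    genes = [f"K{i:05d}" for i in range(cfg.n_kd_genes)]
    rows = []
    i = 0
    for chrom in chroms:
        n_fit = (cfg.chrom_lengths[chrom] - flank) // spacing
        for j in range(n_fit):
            if i >= cfg.n_kd_genes:
                break
            tss = flank + j * spacing
            rows.append((genes[i], chrom, tss, "+" if rng.random() < 0.5 else "-"))
            i += 1
    annotations = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])

    perm = rng.permutation(cfg.n_kd_genes)
    targets = [genes[k] for k in perm[: cfg.n_joint_targets]]
    de_only = [
        genes[k]
        for k in perm[cfg.n_joint_targets : cfg.n_joint_targets + cfg.n_de_only_decoys]
    ]
    bound_only = [
        genes[k]
        for k in perm[
            cfg.n_joint_targets
            + cfg.n_de_only_decoys : n_special
        ]
    ]
    de_set = set(targets) | set(de_only)
    bound_set = set(targets) | set(bound_only)

    def de_table() -> pd.DataFrame:
        p = rng.uniform(0.0, 1.0, size=cfg.n_kd_genes)
        fc = rng.normal(0.0, 0.2, size=cfg.n_kd_genes)
        for k, g in enumerate(genes):
            if g in de_set:
                p[k] = 10.0 ** (-rng.uniform(5.0, 9.0))
                fc[k] = signs[g] * (cfg.de_effect_size + abs(rng.normal(0.0, 0.4)))
        return pd.DataFrame(
            {
                "gene": genes,
                "log2fc": fc,
                "p_value": p,
                "fdr": bh_fdr(p),
                "mean_count": rng.lognormal(5.0, 1.0, size=cfg.n_kd_genes),
            }
        )

    signs = {g: (1 if rng.random() < 0.5 else -1) for g in de_set}
    de_a = de_table()
    de_b = de_table()

    tss_of = annotations.set_index("gene")["tss"]
    chrom_of = annotations.set_index("gene")["chrom"]
    a_ivs, b_ivs = [], []
    for g in sorted(bound_set):
        tss, chrom = int(tss_of[g]), chrom_of[g]
        off_a = int(rng.integers(-flank + 1, flank - 200))
        off_b = int(rng.integers(-flank + 1, flank - 200))
        a_ivs.append(
            GenomicInterval(chrom, max(0, tss + off_a), max(0, tss + off_a) + 200)
        )
        b_ivs.append(
            GenomicInterval(chrom, max(0, tss + off_b), max(0, tss + off_b) + 200)
        )
    # background peaks far from every promoter (in the spacing gaps)
    unbound = [g for g in genes if g not in bound_set]
    for g in unbound[: len(unbound) // 2]:
        tss, chrom = int(tss_of[g]), chrom_of[g]
        start = tss + flank + 200  # inside the inter-gene gap
        which = a_ivs if rng.random() < 0.5 else b_ivs
        which.append(GenomicInterval(chrom, start, start + 200))

    truth = {
        "joint_targets": sorted(targets),
        "de_only_decoys": sorted(de_only),
        "bound_only_decoys": sorted(bound_only),
        "signs": signs,
    }
    return KnockdownSim(
        de_a,
        de_b,
        annotations,
        PeakSet("KD_A", a_ivs),
        PeakSet("KD_B", b_ivs),
        truth,
    )


# ---------------------------------------------------------------------------
# germline layer


@dataclass
class GermlineSim:
    snps: pd.DataFrame
    genotypes: pd.DataFrame
    eqtl: pd.DataFrame
    allele_counts: pd.DataFrame
    sequences: dict[str, str]
    pwm: PWM
    truth: dict


_GATA_CONSENSUS = "AGATAA"


def _gata_like_pwm(strong: float = 0.94) -> PWM:
    weak = (1.0 - strong) / 3.0
    mat = np.full((len(_GATA_CONSENSUS), 4), weak)
    for i, base in enumerate(_GATA_CONSENSUS):
        mat[i, "ACGT".index(base)] = strong
    return PWM("GATA_like", mat)


def gen_germline(cfg: SimConfig, peaks_a: PeakSet, peaks_b: PeakSet) -> GermlineSim:
    """SNP tables, LD-block genotypes, eQTL links, allele counts, motif site.

    Risk SNPs fall inside the two factors' common regions at
    ``cfg.risk_enrichment`` times the background density. LD blocks share
    two haplotype patterns per block with per-allele flip noise tuned to
    the target r^2 (zero noise gives exact r^2 = 1 for polymorphic
    pairs). One designated SNP sits in a planted GATA-like motif whose
    consensus is completed by the risk allele.
    """
    rng = _rng(cfg, _STREAM_GERMLINE)
    from regdriver.germline import cooccupancy_categories  # deferred: avoid cycle

    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    common = cooccupancy_categories(peaks_a, peaks_b)["common"]
    common_ivs = list(common)
    common_bp = common.total_bases() if common_ivs else 0
    coverage = common_bp / total
    p_in = cfg.risk_enrichment * coverage
    if p_in > 1.0:
        raise ValueError(
            "risk_enrichment incompatible with common-region coverage "
            f"(implied in-region probability {p_in:.3f} > 1)"
        )

    bases = np.array(list("ACGT"))

    def rand_alleles(n: int) -> tuple[np.ndarray, np.ndarray]:
        ref = bases[rng.integers(0, 4, size=n)]
        alt_shift = rng.integers(1, 4, size=n)
        alt = bases[(np.char.find("ACGT", ref.astype("U1")) + alt_shift) % 4]
        return ref, alt

    def uniform_positions(n: int) -> tuple[list[str], np.ndarray]:
        ch_idx = rng.choice(len(chroms), size=n, p=lengths / total)
        pos = np.array(
            [rng.integers(0, cfg.chrom_lengths[chroms[k]]) for k in ch_idx]
        )
        return [chroms[k] for k in ch_idx], pos

    rows = []
    # background pool
    bg_chrom, bg_pos = uniform_positions(cfg.n_background_snps)
    ref, alt = rand_alleles(cfg.n_background_snps)
    for i in range(cfg.n_background_snps):
        rows.append(
            (f"bg{i:06d}", bg_chrom[i], int(bg_pos[i]), ref[i], alt[i], alt[i],
             False, "background")
        )
    # risk SNPs with planted enrichment in common regions
    if common_ivs:
        widths = np.array([len(iv) for iv in common_ivs], dtype=float)
        w_p = widths / widths.sum()
    ref, alt = rand_alleles(cfg.n_risk_snps)
    n_inside = 0
    for i in range(cfg.n_risk_snps):
        if common_ivs and rng.random() < p_in:
            iv = common_ivs[rng.choice(len(common_ivs), p=w_p)]
            chrom, pos = iv.chrom, int(rng.integers(iv.start, iv.end))
            n_inside += 1
        else:
            chrom_l, pos_l = uniform_positions(1)
            chrom, pos = chrom_l[0], int(pos_l[0])
        rows.append(
            (f"rs_risk{i:04d}", chrom, pos, ref[i], alt[i], alt[i], False, "risk")
        )
    # LD blocks: block_size SNPs clustered around a tag
    flip = (1.0 - cfg.ld_target_r2**0.25) / 2.0
    geno_rows: dict[str, np.ndarray] = {}
    block_members: dict[str, list[str]] = {}
    ref, alt = rand_alleles(cfg.n_tag_snps * cfg.ld_block_size)
    for b in range(cfg.n_tag_snps):
        chrom = chroms[b % len(chroms)]
        center = int(rng.integers(100_000, cfg.chrom_lengths[chrom] - 100_000))
        h1 = rng.integers(0, 2, size=cfg.n_individuals)
        h2 = rng.integers(0, 2, size=cfg.n_individuals)
        members = []
        for j in range(cfg.ld_block_size):
            k = b * cfg.ld_block_size + j
            rsid = f"rs_tag{b}" if j == 0 else f"rs_b{b}p{j}"
            pos = center + j * 500
            rows.append(
                (rsid, chrom, pos, ref[k], alt[k], alt[k], j == 0, "ld_block")
            )
            a1 = h1 ^ (rng.random(cfg.n_individuals) < flip)
            a2 = h2 ^ (rng.random(cfg.n_individuals) < flip)
            geno_rows[rsid] = (a1 + a2).astype(int)
            members.append(rsid)
        block_members[f"rs_tag{b}"] = members

    # designated motif SNP: risk (alt) allele completes the GATA consensus
    pwm = _gata_like_pwm()
    L = len(pwm)
    snp_motif_pos = 3  # the strong 'T' position of AGATAA
    flank_len = 17
    motif_chrom = chroms[0]
    motif_pos = int(rng.integers(200_000, cfg.chrom_lengths[motif_chrom] - 200_000))
    left = "".join(rng.choice(list("ACGT"), size=flank_len))
    right = "".join(rng.choice(list("ACGT"), size=flank_len))
    core_ref = (
        _GATA_CONSENSUS[:snp_motif_pos] + "C" + _GATA_CONSENSUS[snp_motif_pos + 1 :]
    )
    seq_ref = left + core_ref + right
    snp_offset = flank_len + snp_motif_pos
    rows.append(
        ("rs_motif", motif_chrom, motif_pos, "C", "T", "T", True, "motif")
    )
    sequences = {"rs_motif": seq_ref}

    snps = pd.DataFrame(
        rows,
        columns=["rsid", "chrom", "pos", "ref", "alt", "risk_allele", "is_tag", "kind"],
    )
    genotypes = pd.DataFrame.from_dict(
        geno_rows,
        orient="index",
        columns=[f"I{i:04d}" for i in range(cfg.n_individuals)],
    )

    # eQTL links: every LD block maps to one eGene; the motif SNP to EG_MOTIF
    eqtl_rows = [
        (rsid, f"EG{b:03d}", "synthetic")
        for b, tag in enumerate(sorted(block_members))
        for rsid in block_members[tag]
    ]
    eqtl_rows.append(("rs_motif", "EG_MOTIF", "synthetic"))
    eqtl = pd.DataFrame(eqtl_rows, columns=["rsid", "egene", "source"])

    n_risk_allele = int(rng.binomial(cfg.read_depth, cfg.allelic_ratio))
    allele_counts = pd.DataFrame(
        {
            "site": ["rs_motif"],
            "count_risk": [n_risk_allele],
            "count_other": [cfg.read_depth - n_risk_allele],
        }
    )

    truth = {
        "risk_enrichment": cfg.risk_enrichment,
        "n_risk_in_common": n_inside,
        "ld_blocks": block_members,
        "ld_target_r2": cfg.ld_target_r2,
        "allelic_ratio": cfg.allelic_ratio,
        "motif_snp": {
            "rsid": "rs_motif",
            "snp_offset": snp_offset,
            "risk_allele": "T",
        },
    }
    return GermlineSim(snps, genotypes, eqtl, allele_counts, sequences, pwm, truth)


# ---------------------------------------------------------------------------
# file emission (TSV/BED/FASTA/PWM), used by the CLI simulate stage


def write_cohort(sim: CohortSim, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [
        ("copy_number.tsv", sim.copy_number),
        ("expression.tsv", sim.expression),
    ]:
        p = outdir / name
        df.to_csv(p, sep="\t", index_label="gene")
        paths.append(p)
    p = outdir / "essentiality.tsv"
    sim.essentiality.to_csv(p, sep="\t", index_label="gene")
    paths.append(p)
    p = outdir / "clinical.tsv"
    sim.clinical.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "cohort_truth.tsv"
    pd.DataFrame(
        {"gene": list(sim.truth["true_r"]), "true_r": list(sim.truth["true_r"].values())}
    ).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths


def write_peaksets(sim: PeakSim, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pa, pb = outdir / "peaks_a.bed", outdir / "peaks_b.bed"
    write_bed(sim.peaks_a, pa)
    write_bed(sim.peaks_b, pb)
    return [pa, pb]


def write_knockdown(sim: KnockdownSim, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [("de_a.tsv", sim.de_a), ("de_b.tsv", sim.de_b)]:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    p = outdir / "gene_annotation.tsv"
    write_gene_annotation(sim.annotations, p)
    paths.append(p)
    for name, peaks in [("kd_peaks_a.bed", sim.peaks_a), ("kd_peaks_b.bed", sim.peaks_b)]:
        p = outdir / name
        write_bed(peaks, p)
        paths.append(p)
    p = outdir / "joint_target_truth.tsv"
    pd.DataFrame({"gene": sim.truth["joint_targets"]}).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths


def write_germline(sim: GermlineSim, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [
        ("snps.tsv", sim.snps),
        ("eqtl.tsv", sim.eqtl),
        ("allele_counts.tsv", sim.allele_counts),
    ]:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    p = outdir / "genotypes.tsv"
    sim.genotypes.to_csv(p, sep="\t", index_label="rsid")
    paths.append(p)
    p = outdir / "sequences.fa"
    with open(p, "w") as fh:
        for name, seq in sim.sequences.items():
            fh.write(f">{name}\n{seq}\n")
    paths.append(p)
    p = outdir / "motif.pwm"
    write_pwm(sim.pwm, p)
    paths.append(p)
    return paths
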