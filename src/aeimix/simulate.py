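"""Synthetic allele-count generator with the structure the method assumes.

Each gene's two parental copies are read as ``P = Y1 + Z`` and
``M = Y2 + Z`` with independent Poisson ``Y1, Y2`` and a shared
non-negative component ``Z`` that induces positive correlation between the
allele counts without touching their difference (``P - M = Y1 - Y2``).
Genes carry a coverage class (mixture over total expression rates, heavy on
low coverage), a small number of heterozygous SNPs (most genes have four or
fewer), and an optional allelic imbalance: an imbalanced gene expresses its
paternal copy at ``rho`` times the maternal base rate consistently across
its SNPs and tissues.  Which parental allele carries the reference base is
randomised per subject and SNP, so the reference/variant fold is symmetric
by construction.  Per-sample library multipliers emulate sequencing-depth
variation; the pipeline's library-size adjustment approximately inverts
them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import round_half_away

__all__ = ["SimConfig", "simulate_dataset", "truth_eval"]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``coverage_classes`` are (weight, total adjusted reads per SNP) pairs;
    ``z_fraction`` is the share of each allele's expected coverage carried
    by the shared component Z (0 gives independent allele noise);
    ``rho`` multiplies the paternal rate of imbalanced genes
    (``lambda_p = rho * lambda_m``); ``library_sd`` is the log-normal sigma
    of per-sample depth multipliers; ``snp_geom_p`` sets the geometric
    SNP-per-gene law (default: 78% of genes have <= 4 SNPs).
    """

    n_subjects: int = 10
    tissues_per_subject: int = 10
    n_genes: int = 150
    coverage_classes: tuple = ((0.77, 8.0), (0.19, 20.0), (0.03, 43.0), (0.01, 110.0))
    aei_fraction: float = 0.15
    rho: float = 3.0
    z_fraction: float = 0.1
    z_dist: str = "poisson"  # poisson | gamma-poisson | none
    z_dispersion: float = 0.5
    library_sd: float = 0.25
    het_prob: float = 0.5
    expression_prob: float = 0.2
    snp_geom_p: float = 0.315
    max_snps_per_gene: int = 12
    region_probs: tuple = (
        ("utr3", 0.50), ("exon", 0.20), ("intron", 0.15), ("utr5", 0.08),
        ("upstream", 0.03), ("downstream", 0.02), ("intergenic", 0.02),
    )
    ref_paternal_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho:
            raise ValueError("rho must be positive")
        if not 0 <= self.aei_fraction <= 1:
            raise ValueError("aei_fraction must be in [0, 1]")
        if not 0 <= self.z_fraction < 1:
            raise ValueError("z_fraction must be in [0, 1)")
        w = sum(w for w, _ in self.coverage_classes)
        if abs(w - 1.0) > 1e-8:
            raise ValueError("coverage class weights must sum to 1")


def _draw_z(rng: np.random.Generator, rate: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.z_dist == "none" or cfg.z_fraction == 0:
        return np.zeros(rate.size, dtype=np.int64)
    if cfg.z_dist == "poisson":
        return rng.poisson(rate)
    if cfg.z_dist == "gamma-poisson":
        # over-dispersed shared component: Poisson with Gamma-mixed rate
        shape = 1.0 / cfg.z_dispersion
        return rng.poisson(rng.gamma(shape, rate * cfg.z_dispersion))
    raise ValueError(f"unknown z_dist {cfg.z_dist!r}")


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an allele-count table plus its ground truth.

    Returns ``(counts, truth)``: ``counts`` uses the pipeline input schema
    (subject, tissue, gene, snp, region, ref_count, var_count); ``truth``
    adds the generating rates, fold change and imbalance label per row.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    class_w = np.array([w for w, _ in cfg.coverage_classes])
    class_rate = np.array([r for _, r in cfg.coverage_classes])

    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    gene_class = rng.choice(class_w.size, size=cfg.n_genes, p=class_w)
    gene_total = class_rate[gene_class]
    gene_aei = rng.random(cfg.n_genes) < cfg.aei_fraction
    gene_rho = np.where(gene_aei, cfg.rho, 1.0)
    lam_z = cfg.z_fraction * gene_total / 2.0
    lam_m = (1.0 - cfg.z_fraction) * gene_total / 2.0
    lam_p = gene_rho * lam_m

    n_snps = np.minimum(
        rng.geometric(cfg.snp_geom_p, size=cfg.n_genes), cfg.max_snps_per_gene
    )
    region_names = [r for r, _ in cfg.region_probs]
    region_p = np.array([p for _, p in cfg.region_probs])
    region_p = region_p / region_p.sum()

    snp_gene_idx = np.repeat(np.arange(cfg.n_genes), n_snps)
    snp_ids = np.array([f"rs{i:07d}" for i in range(snp_gene_idx.size)])
    snp_region = rng.choice(len(region_names), size=snp_gene_idx.size, p=region_p)

    subjects = np.array([f"S{i:02d}" for i in range(cfg.n_subjects)])
    tissues = np.array([f"T{i:02d}" for i in range(cfg.tissues_per_subject)])

    # heterozygosity: per subject x SNP locus; expression: per sample x gene
    het = rng.random((cfg.n_subjects, snp_ids.size)) < cfg.het_prob
    expressed = (
        rng.random((cfg.n_subjects, cfg.tissues_per_subject, cfg.n_genes))
        < cfg.expression_prob
    )
    ref_is_paternal = (
        rng.random((cfg.n_subjects, snp_ids.size)) < cfg.ref_paternal_prob
    )
    lib_mult = np.exp(
        rng.normal(0.0, cfg.library_sd, size=(cfg.n_subjects, cfg.tissues_per_subject))
    )

    su_idx, ti_idx, sn_idx = np.meshgrid(
        np.arange(cfg.n_subjects),
        np.arange(cfg.tissues_per_subject),
        np.arange(snp_ids.size),
        indexing="ij",
    )
    su_idx, ti_idx, sn_idx = su_idx.ravel(), ti_idx.ravel(), sn_idx.ravel()
    g_idx = snp_gene_idx[sn_idx]
    keep = het[su_idx, sn_idx] & expressed[su_idx, ti_idx, g_idx]
    su_idx, ti_idx, sn_idx, g_idx = su_idx[keep], ti_idx[keep], sn_idx[keep], g_idx[keep]
    n_obs = su_idx.size

    y1 = rng.poisson(lam_p[g_idx])
    y2 = rng.poisson(lam_m[g_idx])
    z = _draw_z(rng, lam_z[g_idx], cfg)
    p_reads = y1 + z
    m_reads = y2 + z
    refp = ref_is_paternal[su_idx, sn_idx]
    r_lat = np.where(refp, p_reads, m_reads)
    v_lat = np.where(refp, m_reads, p_reads)
    mult = lib_mult[su_idx, ti_idx]
    r_obs = round_half_away(r_lat * mult).astype(np.int64)
    v_obs = round_half_away(v_lat * mult).astype(np.int64)

    counts = pd.DataFrame(
        {
            "subject": subjects[su_idx],
            "tissue": tissues[ti_idx],
            "gene": genes[g_idx],
            "snp": snp_ids[sn_idx],
            "region": np.array(region_names)[snp_region[sn_idx]],
            "ref_count": r_obs,
            "var_count": v_obs,
        }
    )
    truth = counts[["subject", "tissue", "gene", "snp"]].copy()
    truth["rho"] = gene_rho[g_idx]
    truth["lambda_p"] = lam_p[g_idx]
    truth["lambda_m"] = lam_m[g_idx]
    truth["z_rate"] = lam_z[g_idx]
    truth["aei_label"] = gene_aei[g_idx]
    return counts, truth


def truth_eval(calls: pd.DataFrame, truth: pd.DataFrame):
    """Confusion summary of designations against generator truth.

    ``calls`` must carry subject/tissue/gene/snp and ``designation``; a call
    is a positive when designated ``AEI``.  Returns ``(overall, per_rho)``:
    a dict with sensitivity, specificity and FDR, and the same metrics per
    fold-change stratum.
    """
    keys = ["subject", "tissue", "gene", "snp"]
    merged = calls.merge(truth, on=keys, how="left", validate="one_to_one")
    if merged["aei_label"].isna().any():
        raise ValueError("calls contain SNPs absent from the truth table")
    pred = (merged["designation"] == "AEI").to_numpy()
    actual = merged["aei_label"].to_numpy(dtype=bool)

    def _metrics(p, a):
        tp = int(np.sum(p & a))
        fp = int(np.sum(p & ~a))
        fn = int(np.sum(~p & a))
        tn = int(np.sum(~p & ~a))
        return {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "fdr": fp / (tp + fp) if tp + fp else float("nan"),
        }

    overall = _metrics(pred, actual)
    rows = []
    for rho, sub in merged.groupby("rho"):
        m = _metrics(
            (sub["designation"] == "AEI").to_numpy(),
            sub["aei_label"].to_numpy(dtype=bool),
        )
        m["rho"] = rho
        m["n"] = len(sub)
        rows.append(m)
    per_rho = pd.DataFrame(rows)
    return overall, per_rho
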