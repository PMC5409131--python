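"""Candidate-gene case/control allelic association with step-up FDR.

Each SNP's dosages collapse to a 2x2 table of minor/major allele counts in
cases vs controls. The default test is the 1-df Pearson chi-square on that
table without continuity correction (the standard allelic test); when any
cell is zero the odds ratio gets a Haldane–Anscombe 0.5 correction and
Fisher's exact p replaces the chi-square p. The odds ratio is the
minor-allele case:control odds ratio.

Multiple testing is adjusted by Benjamini–Hochberg step-up FDR over the
candidate gene's SNP family (hypothesis-based scope); a full-panel family is
available via ``family="panel"``. The candidate-gene finding is validated by
re-running the association on randomly drawn genes with SNP families
size-matched to the target gene and counting how often any of them clears
the FDR threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ASSOC_COLUMNS, MISSING_GENOTYPE, GenotypeTable

logger = logging.getLogger("rankset")

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_N_RESAMPLED_GENES = 500


@dataclass(frozen=True)
class AllelicTestResult:
    snp: str
    minor_case: int
    major_case: int
    minor_control: int
    major_control: int
    odds_ratio: float
    chi2: float
    p_raw: float
    test: str  # "chi2" | "fisher"


def _allele_counts(gt: GenotypeTable) -> pd.DataFrame:
    """Minor/major allele counts per SNP in cases and controls (vectorised)."""
    dos = gt.dosage
    valid = dos != MISSING_GENOTYPE
    dosv = np.where(valid, dos, 0).astype(np.int64)
    case = gt.is_case()
    out = {}
    for label, mask in (("case", case), ("control", ~case)):
        n_valid = valid[mask].sum(axis=0)
        minor = dosv[mask].sum(axis=0)
        out[f"minor_{label}"] = minor
        out[f"major_{label}"] = 2 * n_valid - minor
        out[f"n_valid_{label}"] = n_valid
    return pd.DataFrame(out, index=list(gt.snp_ids))


def _pearson_chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """1-df Pearson chi-square without continuity correction, vectorised.

    Table rows are (a, b) = case minor/major, (c, d) = control minor/major.
    Degenerate margins (an all-zero row or column) give chi2 = 0, p = 1.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(chi2 == 0.0, 1.0, p)
    return chi2, p


def _odds_ratio(a, b, c, d) -> float:
    """Minor-allele OR (case vs control); Haldane–Anscombe 0.5 on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def allelic_test(gt: GenotypeTable, snp: str) -> AllelicTestResult:
    """Allelic case/control association for one SNP.

    Raises ValueError when either phenotype group has no non-missing
    genotype for the SNP.
    """
    if snp not in gt.snp_ids:
        raise KeyError(f"unknown SNP {snp!r}")
    counts = _allele_counts(gt).loc[snp]
    if counts["n_valid_case"] == 0 or counts["n_valid_control"] == 0:
        raise ValueError(f"SNP {snp!r}: all genotypes missing in one phenotype group")
    a, b = int(counts["minor_case"]), int(counts["major_case"])
    c, d = int(counts["minor_control"]), int(counts["major_control"])
    or_ = _odds_ratio(a, b, c, d)
    chi2, p = _pearson_chi2_2x2(a, b, c, d)
    chi2, p = float(chi2), float(p)
    test = "chi2"
    if min(a, b, c, d) == 0:
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        test = "fisher"
    return AllelicTestResult(snp, a, b, c, d, or_, chi2, p, test)


def allelic_tests_all(gt: GenotypeTable) -> pd.DataFrame:
    """Allelic test for every SNP in the panel (vectorised chi-square path).

    SNPs with all genotypes missing in a phenotype group are dropped with a
    logged warning; zero-cell tables fall back to Fisher's exact test.
    """
    counts = _allele_counts(gt)
    usable = (counts["n_valid_case"] > 0) & (counts["n_valid_control"] > 0)
    if not usable.all():
        logger.warning(
            "dropping %d SNP(s) with all genotypes missing in a group: %s",
            (~usable).sum(),
            ", ".join(counts.index[~usable][:10]),
        )
        counts = counts[usable]
    a = counts["minor_case"].to_numpy()
    b = counts["major_case"].to_numpy()
    c = counts["minor_control"].to_numpy()
    d = counts["major_control"].to_numpy()
    chi2, p = _pearson_chi2_2x2(a, b, c, d)
    zero_cell = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (a * d).astype(float) / (b * c)
    hz = zero_cell  # Haldane–Anscombe 0.5 correction where any cell is 0
    or_[hz] = ((a[hz] + 0.5) * (d[hz] + 0.5)) / ((b[hz] + 0.5) * (c[hz] + 0.5))
    p = p.copy()
    for i in np.flatnonzero(zero_cell):
        p[i] = stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]])[1]
    df = pd.DataFrame(
        {
            "snp": counts.index,
            "gene": [gt.gene_of[s] for s in counts.index],
            "minor_case": a,
            "major_case": b,
            "minor_control": c,
            "major_control": d,
            "odds_ratio": or_,
            "chi2": chi2,
            "p_raw": p,
            "test": np.where(zero_cell, "fisher", "chi2"),
        }
    ).reset_index(drop=True)
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Order-preserving: adjusts in sorted order, then restores input order.
    Values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_assoc(
    gt: GenotypeTable,
    gene: str,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    family: str = "gene",
) -> pd.DataFrame:
    """Allelic association for every SNP of a candidate gene, with BH-FDR.

    ``family="gene"`` (default) adjusts over the gene's own SNPs — the
    hypothesis-based scope; ``family="panel"`` adjusts over the whole panel
    and then restricts the output to the gene.
    """
    if family not in ("gene", "panel"):
        raise ValueError(f"unknown FDR family {family!r}")
    snps = gt.snps_of_gene(gene)
    if not snps:
        raise KeyError(f"unknown gene {gene!r} (no SNPs mapped to it)")
    all_res = allelic_tests_all(gt)
    if family == "panel":
        all_res = all_res.assign(p_fdr=bh_fdr(all_res["p_raw"].to_numpy()))
        res = all_res[all_res["gene"] == gene].reset_index(drop=True)
    else:
        res = all_res[all_res["gene"] == gene].reset_index(drop=True)
        res = res.assign(p_fdr=bh_fdr(res["p_raw"].to_numpy()))
    if res.empty:
        raise ValueError(f"gene {gene!r}: no testable SNPs (all dropped)")
    res["significant"] = res["p_fdr"] < fdr_threshold
    return res[ASSOC_COLUMNS + ["test"]]


@dataclass(frozen=True)
class ResamplingResult:
    """Random-gene validation of a candidate-gene hit.

    ``empirical_p`` = (hits + 1)/(n_genes + 1), where a hit is a resampled
    SNP family with any FDR-significant SNP.
    """

    target_gene: str
    n_genes: int
    n_hits: int
    empirical_p: float
    seed: int
    drawn_genes: tuple[str, ...]
    significant: bool


def random_gene_resampling(
    gt: GenotypeTable,
    target_gene: str,
    n_genes: int = DEFAULT_N_RESAMPLED_GENES,
    seed: int = 0,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    alpha: float = 0.05,
) -> ResamplingResult:
    """Re-run the candidate-gene analysis on randomly drawn genes.

    Draws ``n_genes`` distinct genes other than the target; each drawn
    gene's SNP family is size-matched exactly to the target's SNP count
    (subsampled when larger, topped up from the pooled non-target SNPs when
    smaller). A draw is a hit when any SNP in its family passes
    BH-FDR < ``fdr_threshold``. The empirical p is (hits + 1)/(n_genes + 1)
    and the finding is called significant when it is below ``alpha``.
    """
    target_snps = gt.snps_of_gene(target_gene)
    if not target_snps:
        raise KeyError(f"unknown gene {target_gene!r}")
    k = len(target_snps)
    candidates = [g for g in gt.genes if g != target_gene]
    if len(candidates) < n_genes:
        raise ValueError(
            f"only {len(candidates)} candidate genes available; need {n_genes}"
        )
    rng = np.random.default_rng(seed)
    drawn = [candidates[i] for i in rng.choice(len(candidates), size=n_genes, replace=False)]

    all_res = allelic_tests_all(gt).set_index("snp")
    p_of = all_res["p_raw"]
    pool = [s for s in p_of.index if gt.gene_of[s] != target_gene]

    hits = 0
    for gene in drawn:
        snps = [s for s in gt.snps_of_gene(gene) if s in p_of.index]
        if len(snps) > k:
            snps = [snps[i] for i in rng.choice(len(snps), size=k, replace=False)]
        elif len(snps) < k:
            extra_pool = [s for s in pool if gt.gene_of[s] != gene]
            extra = rng.choice(len(extra_pool), size=k - len(snps), replace=False)
            snps = snps + [extra_pool[i] for i in extra]
        p_fdr = bh_fdr(p_of.loc[snps].to_numpy())
        hits += bool((p_fdr < fdr_threshold).any())
    empirical_p = (hits + 1) / (n_genes + 1)
    return ResamplingResult(
        target_gene=target_gene,
        n_genes=n_genes,
        n_hits=hits,
        empirical_p=empirical_p,
        seed=seed,
        drawn_genes=tuple(drawn),
        significant=empirical_p < alpha,
    )
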