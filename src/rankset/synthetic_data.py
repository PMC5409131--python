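"""Synthetic inputs with the statistical structure each analysis stage assumes.

Three generators, each a pure function of its parameters and seed:

* :func:`synthesize_expression` — a normalized log2 expression matrix for a
  two-condition, n-replicates-per-condition design (defaults 3 vs 3,
  mirroring a triplicate microarray comparison) plus a gene set whose
  members carry a configurable mean shift in the second condition;
* :func:`synthesize_genotypes` — a case/control SNP panel in Hardy–Weinberg
  proportions within each phenotype group, with exactly one designated SNP
  in a target gene whose minor-allele frequency differs between groups by a
  configurable ratio (default: 5x more common in controls);
* :func:`synthesize_cell_images` — disk-geometry nucleus/nucleolus image
  pairs with known area ratios, the nucleolar disk inflated by a known
  factor in "disease" cells.

Each generator returns its ground truth (affected transcripts, target SNP
and group frequencies, inflation) alongside the data so recovery tests can
score the pipeline against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, GeneSet, GenotypeTable, ImagePair

GROUP_A = "group_A"  # reference / control condition
GROUP_B = "group_B"  # perturbed / disease condition


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimulation:
    matrix: ExpressionMatrix
    gene_set: GeneSet
    # ground truth: affected transcript id -> shift applied in group B
    shifts: dict[str, float]
    seed: int


def synthesize_expression(
    G: int = 2000,
    n_per_group: int = 3,
    set_size: int = 61,
    delta: float = 0.0,
    frac_affected: float = 0.5,
    sign_mix: float = 0.5,
    noise_sd: float = 0.25,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> ExpressionSimulation:
    """Two-group log2 expression matrix with a planted gene-set effect.

    Baseline log2 means are drawn per transcript from
    N(baseline_mean, baseline_sd); within-group noise is i.i.d.
    N(0, noise_sd). A fraction ``frac_affected`` of the ``set_size`` set
    members receives a mean shift of magnitude ``delta`` (log2 units) in
    group B, signed + (up) with probability ``sign_mix`` and - otherwise.
    ``delta=0`` gives a fully null dataset. Defaults emulate a triplicate
    two-condition microarray with a 61-member pathway.
    """
    if not 0 < set_size <= G:
        raise ValueError(f"need 0 < set_size <= G, got set_size={set_size}, G={G}")
    for name, val in (("frac_affected", frac_affected), ("sign_mix", sign_mix)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if n_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    width = len(str(G))
    tids = tuple(f"tx{str(i + 1).zfill(width)}" for i in range(G))
    sample_ids = tuple(
        [f"A{j + 1}" for j in range(n_per_group)]
        + [f"B{j + 1}" for j in range(n_per_group)]
    )
    group_of = {s: (GROUP_A if s.startswith("A") else GROUP_B) for s in sample_ids}

    baseline = rng.normal(baseline_mean, baseline_sd, size=G)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(G, 2 * n_per_group))

    member_idx = np.sort(rng.choice(G, size=set_size, replace=False))
    n_affected = int(round(frac_affected * set_size))
    affected_idx = rng.choice(member_idx, size=n_affected, replace=False)
    signs = np.where(rng.random(n_affected) < sign_mix, 1.0, -1.0)
    shifts: dict[str, float] = {}
    for idx, s in zip(affected_idx, signs):
        shift = float(s * delta)
        values[idx, n_per_group:] += shift
        shifts[tids[idx]] = shift

    matrix = ExpressionMatrix(
        transcript_ids=tids,
        sample_ids=sample_ids,
        values=values,
        group_of=group_of,
    )
    gene_set = GeneSet(
        name="PLANTED_SET",
        description=f"synthetic set, delta={delta}, frac_affected={frac_affected}",
        members=tuple(tids[i] for i in member_idx),
    )
    return ExpressionSimulation(matrix=matrix, gene_set=gene_set, shifts=shifts, seed=seed)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeSimulation:
    table: GenotypeTable
    target_snp: str
    target_gene: str
    control_maf: float
    case_maf: float
    # true minor-allele odds ratio, case vs control
    true_odds_ratio: float
    seed: int


def synthesize_genotypes(
    n_cases: int = 4890,
    n_controls: int = 5191,
    n_genes: int = 50,
    snps_per_gene: int = 20,
    base_maf_range: tuple[float, float] = (0.05, 0.5),
    target_gene: str = "PTEN",
    freq_ratio: float = 5.0,
    target_control_maf: float = 0.01,
    seed: int = 0,
) -> GenotypeSimulation:
    """Case/control SNP panel with one frequency-differential SNP.

    Genotypes are drawn in Hardy–Weinberg proportions within each phenotype
    group (founders; no relatedness or LD). Every SNP shares its
    minor-allele frequency (drawn uniformly from ``base_maf_range``) across
    groups, except the first SNP of ``target_gene``: its control MAF is
    ``target_control_maf`` and its case MAF is control / ``freq_ratio``
    (default ratio 5 — the minor allele five times more common in controls).
    Default sample sizes mirror a large case/control exome-chip screen
    (4890 cases, 5191 controls).
    """
    if freq_ratio <= 0:
        raise ValueError("freq_ratio must be > 0")
    case_maf = target_control_maf / freq_ratio
    for name, maf in (("control", target_control_maf), ("case", case_maf)):
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"target {name} MAF {maf} outside (0, 0.5]")
    lo, hi = base_maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError(f"base_maf_range {base_maf_range} outside (0, 0.5]")
    if n_genes < 1 or snps_per_gene < 1:
        raise ValueError("need at least one gene and one SNP per gene")

    rng = np.random.default_rng(seed)
    gene_width = len(str(n_genes))
    genes = [target_gene] + [
        f"gene{str(i + 1).zfill(gene_width)}" for i in range(n_genes - 1)
    ]
    snp_ids: list[str] = []
    gene_of: dict[str, str] = {}
    for g in genes:
        for j in range(snps_per_gene):
            sid = f"{g}_snp{j + 1:03d}"
            snp_ids.append(sid)
            gene_of[sid] = g
    target_snp = snp_ids[0]
    n_snps = len(snp_ids)

    maf = rng.uniform(lo, hi, size=n_snps)
    maf_case = maf.copy()
    maf_control = maf.copy()
    maf_case[0] = case_maf
    maf_control[0] = target_control_maf

    dosage = np.empty((n_cases + n_controls, n_snps), dtype=np.int8)
    dosage[:n_cases] = rng.binomial(2, maf_case[None, :], size=(n_cases, n_snps))
    dosage[n_cases:] = rng.binomial(2, maf_control[None, :], size=(n_controls, n_snps))

    sample_ids = tuple(
        [f"case{i + 1:05d}" for i in range(n_cases)]
        + [f"ctrl{i + 1:05d}" for i in range(n_controls)]
    )
    phenotype = tuple(["case"] * n_cases + ["control"] * n_controls)
    table = GenotypeTable(
        snp_ids=tuple(snp_ids),
        gene_of=gene_of,
        sample_ids=sample_ids,
        phenotype=phenotype,
        dosage=dosage,
    )
    odds = lambda f: f / (1.0 - f)
    return GenotypeSimulation(
        table=table,
        target_snp=target_snp,
        target_gene=target_gene,
        control_maf=target_control_maf,
        case_maf=case_maf,
        true_odds_ratio=odds(case_maf) / odds(target_control_maf),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cell images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimulation:
    images: list[ImagePair]
    nucleus_radius_px: int
    nucleolus_radius_px: int
    inflation: float
    # analytic nucleolar/nuclear area ratio in percent
    expected_ratio_pct: float
    seed: int


def _disk_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def synthesize_cell_images(
    n_cells: int = 50,
    nucleus_radius_px: int = 20,
    nucleolus_radius_px: int = 10,
    inflation: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    nuclear_intensity: int = 220,
    nucleolar_intensity: int = 75,
    margin_px: int = 4,
) -> ImageSimulation:
    """Concentric-disk nucleus/nucleolus image pairs with known area ratio.

    The nuclear channel holds a disk of ``nuclear_intensity`` on a zero
    background; the protein channel a concentric disk of
    ``nucleolar_intensity`` (inside the default 50–100 measurement band)
    whose area is scaled by (1 + inflation), i.e. radius by
    sqrt(1 + inflation). Optional i.i.d. Gaussian pixel noise (sd ``noise``)
    is added to both channels and clipped to [0, 255].
    """
    if nucleolus_radius_px > nucleus_radius_px:
        raise ValueError("nucleolus radius exceeds nucleus radius")
    if nucleus_radius_px < 1:
        raise ValueError("nucleus radius must be >= 1 px")
    if inflation < 0:
        raise ValueError("inflation must be >= 0")
    rng = np.random.default_rng(seed)
    side = 2 * (nucleus_radius_px + margin_px) + 1
    shape = (side, side)
    r_ncl = nucleolus_radius_px * float(np.sqrt(1.0 + inflation))
    nuc = np.zeros(shape, dtype=float)
    nuc[_disk_mask(shape, nucleus_radius_px)] = nuclear_intensity
    pro = np.zeros(shape, dtype=float)
    pro[_disk_mask(shape, r_ncl)] = nucleolar_intensity

    images = []
    for _ in range(n_cells):
        if noise > 0:
            n_img = nuc + rng.normal(0.0, noise, size=shape)
            p_img = pro + rng.normal(0.0, noise, size=shape)
        else:
            n_img, p_img = nuc, pro
        images.append(
            ImagePair(
                nuclear_channel=np.clip(np.rint(n_img), 0, 255).astype(np.uint8),
                protein_channel=np.clip(np.rint(p_img), 0, 255).astype(np.uint8),
            )
        )
    expected = 100.0 * (nucleolus_radius_px / nucleus_radius_px) ** 2 * (1.0 + inflation)
    return ImageSimulation(
        images=images,
        nucleus_radius_px=nucleus_radius_px,
        nucleolus_radius_px=nucleolus_radius_px,
        inflation=inflation,
        expected_ratio_pct=expected,
        seed=seed,
    )
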