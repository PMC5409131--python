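import numpy as np
import pytest

from rankset.data_model import ExpressionMatrix, GeneSet, GenotypeTable, RankedList


def make_ranked(G: int, rank_mode: str = "abs_desc") -> RankedList:
    """A ranked list of G transcripts tx001.. with rank i for transcript i.

    t-statistics decrease with rank so the list is self-consistent under
    abs_desc; tests that only need rank placement use this directly.
    """
    ids = tuple(f"tx{i + 1:03d}" for i in range(G))
    t = np.array([float(G - i) for i in range(G)])
    return RankedList(
        transcript_ids=ids,
        t_statistic=t,
        p_t=np.full(G, 0.5),
        fold_change_signed=np.exp2(t / 10.0),
        rank=np.arange(1, G + 1),
        rank_mode=rank_mode,
    )


def set_at_ranks(ranked: RankedList, ranks) -> GeneSet:
    """Gene set whose members sit at the given ranks of ``ranked``."""
    by_rank = {r: tid for tid, r in zip(ranked.transcript_ids, ranked.rank)}
    return GeneSet(
        name="TESTSET",
        description="synthetic",
        members=tuple(by_rank[r] for r in ranks),
    )


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 transcripts x 4 samples, groups (A, A, B, B)."""
    return ExpressionMatrix(
        transcript_ids=("t1", "t2", "t3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [[1.0, 1.2, 2.0, 2.2], [5.0, 5.1, 5.0, 4.9], [3.0, 2.8, 1.0, 1.1]]
        ),
        group_of={"s1": "group_A", "s2": "group_A", "s3": "group_B", "s4": "group_B"},
    )


def make_genotypes(
    dosage, phenotype, snp_ids=None, gene_of=None
) -> GenotypeTable:
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    if snp_ids is None:
        snp_ids = tuple(f"rs{i + 1}" for i in range(n_snps))
    if gene_of is None:
        gene_of = {s: "GENE1" for s in snp_ids}
    return GenotypeTable(
        snp_ids=tuple(snp_ids),
        gene_of=gene_of,
        sample_ids=tuple(f"smp{i + 1}" for i in range(n_samples)),
        phenotype=tuple(phenotype),
        dosage=dosage,
    )
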