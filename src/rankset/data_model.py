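"""Core containers and text-format IO for the pipeline.

Formats handled here:

* expression matrices — TSV, transcripts in rows, samples in columns, log2
  scale, with a ``#group`` second header line assigning each sample to one of
  two contrast groups;
* gene sets — Broad GMT dialect (name TAB description TAB member ...);
* genotype tables — TSV, samples in rows with a ``phenotype`` column
  (case/control) and one column per SNP coded as minor-allele dosage
  0/1/2/NA, plus a two-column SNP-to-gene sidecar map;
* association tables — TSV with per-SNP allele counts, odds ratio,
  chi-square, raw and FDR-adjusted p.

Parsers never coerce silently: a malformed cell raises :class:`FormatError`
with row/column coordinates. Every writer round-trips through its reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUP_HEADER_PREFIX = "#group"
MISSING_GENOTYPE = -1  # in-memory sentinel; "NA" on disk


class FormatError(ValueError):
    """Malformed input file; message carries row/column coordinates."""


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale transcript-by-sample expression with a two-group contrast.

    Parameters
    ----------
    transcript_ids : sequence of str
        Unique row identifiers; order defines row order of ``values``.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_transcripts, n_samples)
        Finite log2 expression values.
    group_of : mapping sample_id -> group label
        Exactly two distinct labels, each with at least two samples.
    """

    transcript_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        tids = tuple(self.transcript_ids)
        sids = tuple(self.sample_ids)
        object.__setattr__(self, "transcript_ids", tids)
        object.__setattr__(self, "sample_ids", sids)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(tids)) != len(tids):
            dup = _first_duplicate(tids)
            raise FormatError(f"duplicate transcript id {dup!r}")
        if len(set(sids)) != len(sids):
            dup = _first_duplicate(sids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if vals.shape != (len(tids), len(sids)):
            raise FormatError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(tids)} transcripts x {len(sids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite expression value at transcript {tids[r]!r}, "
                f"sample {sids[c]!r}"
            )
        missing = [s for s in sids if s not in self.group_of]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group label")
        labels = sorted({self.group_of[s] for s in sids})
        if len(labels) != 2:
            raise FormatError(
                f"expected exactly 2 group labels, got {labels}"
            )
        for lab in labels:
            n = sum(1 for s in sids if self.group_of[s] == lab)
            if n < 2:
                raise FormatError(f"group {lab!r} has {n} sample(s); need >= 2")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, sorted."""
        return tuple(sorted({self.group_of[s] for s in self.sample_ids}))

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples in ``label``."""
        if label not in self.groups:
            raise KeyError(f"unknown group label {label!r}")
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == label]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.transcript_ids), columns=list(self.sample_ids)
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate present")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a two-group expression matrix.

    Line 1: ``transcript_id<TAB>sample...``; line 2: ``#group<TAB>label...``
    assigning each sample a group; remaining lines: id + numeric values.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        group_line = fh.readline().rstrip("\n")
        if not header or not group_line:
            raise FormatError(f"{path}: truncated header (need 2 header lines)")
        sample_ids = header.split("\t")[1:]
        gparts = group_line.split("\t")
        if gparts[0] != GROUP_HEADER_PREFIX:
            raise FormatError(
                f"{path}: line 2 must start with {GROUP_HEADER_PREFIX!r}, "
                f"got {gparts[0]!r}"
            )
        if len(gparts) - 1 != len(sample_ids):
            raise FormatError(
                f"{path}: group line has {len(gparts) - 1} labels for "
                f"{len(sample_ids)} samples"
            )
        group_of = dict(zip(sample_ids, gparts[1:]))
        tids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            tids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} "
                        f"in column {col} (sample {sample_ids[col - 2]!r})"
                    ) from None
            rows.append(row)
    return ExpressionMatrix(
        transcript_ids=tuple(tids),
        sample_ids=tuple(sample_ids),
        values=np.array(rows, dtype=float),
        group_of=group_of,
    )


def write_expression_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("transcript_id\t" + "\t".join(X.sample_ids) + "\n")
        fh.write(
            GROUP_HEADER_PREFIX
            + "\t"
            + "\t".join(X.group_of[s] for s in X.sample_ids)
            + "\n"
        )
        for tid, row in zip(X.transcript_ids, X.values):
            fh.write(tid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """Named collection of transcript identifiers (e.g. a KEGG pathway)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise FormatError(f"gene set {self.name!r} has no members")
        if len(set(members)) != len(members):
            raise FormatError(
                f"gene set {self.name!r} has duplicate member "
                f"{_first_duplicate(members)!r}"
            )

    @property
    def size(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, name TAB description TAB members."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                sets.append(
                    GeneSet(name=parts[0], description=parts[1], members=tuple(parts[2:]))
                )
            except FormatError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------

RANK_MODES = ("abs_desc", "signed_desc", "signed_asc")


@dataclass(frozen=True)
class RankedList:
    """Per-transcript differential-expression summary for the transcriptome.

    ``rank`` is a permutation of 1..G; rank 1 is the most extreme transcript
    under ``rank_mode`` (``abs_desc``: largest \\|t\\|).
    """

    transcript_ids: tuple[str, ...]
    t_statistic: np.ndarray
    p_t: np.ndarray
    fold_change_signed: np.ndarray
    rank: np.ndarray
    rank_mode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))
        for name in ("t_statistic", "p_t", "fold_change_signed"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "rank", np.asarray(self.rank, dtype=int))
        G = len(self.transcript_ids)
        if self.rank_mode not in RANK_MODES:
            raise ValueError(f"unknown rank_mode {self.rank_mode!r}")
        if sorted(self.rank.tolist()) != list(range(1, G + 1)):
            raise ValueError("ranks are not a permutation of 1..G")

    @property
    def G(self) -> int:
        return len(self.transcript_ids)

    def rank_of(self) -> dict[str, int]:
        return dict(zip(self.transcript_ids, self.rank.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": list(self.transcript_ids),
                "t": self.t_statistic,
                "p": self.p_t,
                "fold_change": self.fold_change_signed,
                "rank": self.rank,
            }
        )


def write_ranked_tsv(ranked: RankedList, path: str | Path) -> None:
    df = ranked.to_frame()
    df.insert(5, "rank_mode", ranked.rank_mode)
    df.to_csv(path, sep="\t", index=False)


def read_ranked_tsv(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return RankedList(
        transcript_ids=tuple(df["transcript_id"]),
        t_statistic=df["t"].to_numpy(),
        p_t=df["p"].to_numpy(),
        fold_change_signed=df["fold_change"].to_numpy(),
        rank=df["rank"].to_numpy(),
        rank_mode=str(df["rank_mode"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# Set-test result
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SetTestResult:
    """Outcome of the rank-product gene-set test.

    ``log_rank_product`` is sum over members of log(rank/G), hence <= 0.
    For ``method='monte_carlo'``, ``p_value`` carries the add-one
    correction (k+1)/(n+1); ``raw_fraction`` is k/n for transparency.
    """

    set_name: str
    m: int
    G: int
    log_rank_product: float
    n_draws: int
    n_as_or_more_extreme: int
    p_value: float
    method: str  # "monte_carlo" | "exact"
    seed: int | None = None
    raw_fraction: float | None = None
    dropped_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("monte_carlo", "exact"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.log_rank_product > 1e-12:
            raise ValueError("log rank-product must be <= 0")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if self.method == "monte_carlo":
            expected = (self.n_as_or_more_extreme + 1) / (self.n_draws + 1)
            if abs(self.p_value - expected) > 1e-12:
                raise ValueError("monte-carlo p inconsistent with counts")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeTable:
    """Case/control minor-allele dosages.

    ``dosage`` holds 0/1/2 or :data:`MISSING_GENOTYPE`; rows are samples in
    the order of ``sample_ids``, columns are SNPs in the order of ``snp_ids``.
    """

    snp_ids: tuple[str, ...]
    gene_of: dict[str, str]
    sample_ids: tuple[str, ...]
    phenotype: tuple[str, ...]  # "case" | "control" per sample
    dosage: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "phenotype", tuple(self.phenotype))
        dos = np.asarray(self.dosage, dtype=np.int8)
        object.__setattr__(self, "dosage", dos)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError(f"duplicate SNP id {_first_duplicate(self.snp_ids)!r}")
        if dos.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise FormatError(
                f"dosage shape {dos.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(dos, (0, 1, 2, MISSING_GENOTYPE))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage {dos[r, c]} outside {{0,1,2,NA}} at sample "
                f"{self.sample_ids[r]!r}, SNP {self.snp_ids[c]!r}"
            )
        levels = set(self.phenotype)
        if not levels <= {"case", "control"}:
            raise FormatError(f"unknown phenotype level {sorted(levels - {'case', 'control'})[0]!r}")
        if levels != {"case", "control"}:
            raise FormatError("phenotype must contain both 'case' and 'control'")
        unknown = [s for s in self.snp_ids if s not in self.gene_of]
        if unknown:
            raise FormatError(f"SNP {unknown[0]!r} missing from gene map")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def is_case(self) -> np.ndarray:
        return np.array([p == "case" for p in self.phenotype])

    def snps_of_gene(self, gene: str) -> list[str]:
        return [s for s in self.snp_ids if self.gene_of[s] == gene]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snp_ids:
            seen.setdefault(self.gene_of[s], None)
        return list(seen)


def read_genotypes(path: str | Path, gene_map_path: str | Path) -> GenotypeTable:
    """Read a genotype TSV plus its SNP-to-gene sidecar map.

    Genotype file: header ``sample_id<TAB>phenotype<TAB>snp...``; rows of
    dosages in {0,1,2,NA}. Gene map: two columns ``snp_id<TAB>gene``, with a
    header line.
    """
    path = Path(path)
    gene_of: dict[str, str] = {}
    with Path(gene_map_path).open() as fh:
        next(fh)  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{gene_map_path}:{lineno}: expected 2 fields, got {len(parts)}"
                )
            gene_of[parts[0]] = parts[1]
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1] != "phenotype":
            raise FormatError(f"{path}: header must be sample_id, phenotype, snps...")
        snp_ids = header[2:]
        sample_ids: list[str] = []
        phenotype: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(snp_ids) + 2:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(snp_ids) + 2} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[0])
            phenotype.append(parts[1])
            row = []
            for col, cell in enumerate(parts[2:], start=3):
                if cell == "NA":
                    row.append(MISSING_GENOTYPE)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise FormatError(
                        f"{path}:{lineno}: dosage {cell!r} outside "
                        f"{{0,1,2,NA}} in column {col} (SNP {snp_ids[col - 3]!r})"
                    )
            rows.append(row)
    return GenotypeTable(
        snp_ids=tuple(snp_ids),
        gene_of=gene_of,
        sample_ids=tuple(sample_ids),
        phenotype=tuple(phenotype),
        dosage=np.array(rows, dtype=np.int8),
    )


def write_genotypes(
    gt: GenotypeTable, path: str | Path, gene_map_path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(gt.snp_ids) + "\n")
        for sid, pheno, row in zip(gt.sample_ids, gt.phenotype, gt.dosage):
            cells = ["NA" if v == MISSING_GENOTYPE else str(int(v)) for v in row]
            fh.write(f"{sid}\t{pheno}\t" + "\t".join(cells) + "\n")
    with Path(gene_map_path).open("w") as fh:
        fh.write("snp_id\tgene\n")
        for s in gt.snp_ids:
            fh.write(f"{s}\t{gt.gene_of[s]}\n")


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "snp",
    "gene",
    "minor_case",
    "major_case",
    "minor_control",
    "major_control",
    "odds_ratio",
    "chi2",
    "p_raw",
    "p_fdr",
    "significant",
]


def write_assoc_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ASSOC_COLUMNS)


def read_assoc_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp": str, "gene": str})


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagePair:
    """Paired single-cell nuclear-stain and protein-stain channels (8-bit)."""

    nuclear_channel: np.ndarray
    protein_channel: np.ndarray

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nuclear_channel)
        pro = np.asarray(self.protein_channel)
        for name, arr in (("nuclear", nuc), ("protein", pro)):
            if arr.ndim != 2:
                raise FormatError(f"{name} channel must be 2-D, got {arr.ndim}-D")
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError(f"{name} channel intensities outside [0, 255]")
        if nuc.shape != pro.shape:
            raise FormatError(
                f"channel shapes differ: nuclear {nuc.shape} vs protein {pro.shape}"
            )
        object.__setattr__(self, "nuclear_channel", nuc.astype(np.uint8))
        object.__setattr__(self, "protein_channel", pro.astype(np.uint8))


def read_image_pair(nuclear_path: str | Path, protein_path: str | Path) -> ImagePair:
    import imageio.v3 as iio

    return ImagePair(
        nuclear_channel=iio.imread(nuclear_path),
        protein_channel=iio.imread(protein_path),
    )


def write_image_pair(
    img: ImagePair, nuclear_path: str | Path, protein_path: str | Path
) -> None:
    import imageio.v3 as iio

    iio.imwrite(nuclear_path, img.nuclear_channel)
    iio.imwrite(protein_path, img.protein_channel)
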