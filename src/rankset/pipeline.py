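"""End-to-end orchestration of the two analysis arms.

The expression arm ranks the transcriptome by t-statistic and tests a gene
set's rank product against the permutation null. The genetics arm runs the
candidate-gene allelic association with BH-FDR and validates it by
random-gene resampling. Both consume a plain dict config (typically loaded
from YAML), write TSV results plus a JSON provenance sidecar (input hashes,
parameters, seed, package version), and log progress to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .data_model import (
    GeneSet,
    read_expression_tsv,
    read_genotypes,
    read_gmt,
    write_assoc_tsv,
    write_expression_tsv,
    write_genotypes,
    write_gmt,
    write_ranked_tsv,
)
from .differential_ranking import rank_expression
from .rankprod_set_test import DEFAULT_N_DRAWS, exact_set_test, set_test
from .snp_association import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_N_RESAMPLED_GENES,
    gene_assoc,
    random_gene_resampling,
)
from .synthetic_data import synthesize_expression, synthesize_genotypes

logger = logging.getLogger("rankset")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_provenance(
    out_path: Path, stage: str, params: Mapping[str, Any], inputs: Mapping[str, Path]
) -> None:
    record = {
        "tool": "rankset",
        "version": __version__,
        "stage": stage,
        "parameters": {k: v for k, v in params.items()},
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in inputs.items()},
    }
    out_path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def _require(config: Mapping[str, Any], key: str, stage: str) -> Any:
    if key not in config:
        raise PipelineError(stage, f"config is missing required key {key!r}")
    return config[key]


def run_expression_arm(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Rank the transcriptome and test a gene set's rank product.

    Config keys: either ``expression`` + ``gmt`` + ``set_name`` (file
    inputs) or ``simulate`` (parameters for
    :func:`~rankset.synthetic_data.synthesize_expression`); plus
    ``disease_group``, ``seed``, and optional ``t_variant``, ``rank_mode``,
    ``n_draws``, ``exact``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs: dict[str, Path] = {}

    stage = "load-expression"
    if "simulate" in config:
        sim_params = dict(config["simulate"])
        sim_params.setdefault("seed", seed)
        sim = synthesize_expression(**sim_params)
        X, gene_set = sim.matrix, sim.gene_set
        disease_group = config.get("disease_group", "group_B")
        expr_path = out_dir / "expression.tsv"
        gmt_path = out_dir / "gene_sets.gmt"
        write_expression_tsv(X, expr_path)
        write_gmt([gene_set], gmt_path)
        inputs["expression"] = expr_path
        inputs["gmt"] = gmt_path
    else:
        expr_path = Path(_require(config, "expression", stage))
        gmt_path = Path(_require(config, "gmt", stage))
        set_name = _require(config, "set_name", stage)
        disease_group = _require(config, "disease_group", stage)
        try:
            X = read_expression_tsv(expr_path)
            sets = {s.name: s for s in read_gmt(gmt_path)}
        except FileNotFoundError as e:
            raise PipelineError(stage, f"missing input file: {e.filename}") from e
        if set_name not in sets:
            raise PipelineError(stage, f"set {set_name!r} not found in {gmt_path}")
        gene_set = sets[set_name]
        inputs["expression"] = expr_path
        inputs["gmt"] = gmt_path

    stage = "rank-de"
    try:
        ranked = rank_expression(
            X,
            disease_group,
            t_variant=config.get("t_variant", "welch"),
            mode=config.get("rank_mode", "abs_desc"),
        )
    except (KeyError, ValueError) as e:
        raise PipelineError(stage, str(e)) from e
    ranked_path = out_dir / "ranked.tsv"
    write_ranked_tsv(ranked, ranked_path)
    logger.info("ranked G=%d transcripts (mode=%s)", ranked.G, ranked.rank_mode)

    stage = "set-test"
    n_draws = int(config.get("n_draws", DEFAULT_N_DRAWS))
    try:
        if config.get("exact", False):
            result = exact_set_test(ranked, gene_set)
        else:
            result = set_test(ranked, gene_set, n_draws=n_draws, seed=seed)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e
    logger.info(
        "set %s: m=%d (dropped %d), G=%d, logRP=%.4f, p=%.6g (%s, %d draws, seed=%s)",
        result.set_name,
        result.m,
        len(result.dropped_members),
        result.G,
        result.log_rank_product,
        result.p_value,
        result.method,
        result.n_draws,
        result.seed,
    )
    result_path = out_dir / "set_test.tsv"
    pd.DataFrame(
        [
            {
                "set": result.set_name,
                "m": result.m,
                "G": result.G,
                "log_rank_product": result.log_rank_product,
                "p_value": result.p_value,
                "method": result.method,
                "n_draws": result.n_draws,
                "seed": "" if result.seed is None else result.seed,
            }
        ]
    ).to_csv(result_path, sep="\t", index=False)
    write_provenance(
        out_dir / "provenance.json",
        "expression-arm",
        {
            "seed": seed,
            "n_draws": n_draws,
            "disease_group": disease_group,
            "t_variant": config.get("t_variant", "welch"),
            "rank_mode": config.get("rank_mode", "abs_desc"),
            "simulate": config.get("simulate"),
        },
        inputs,
    )
    return {
        "ranked_path": str(ranked_path),
        "result_path": str(result_path),
        "set_test": result,
    }


def run_genetics_arm(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Candidate-gene association plus random-gene resampling validation.

    Config keys: either ``genotypes`` + ``gene_map`` (file inputs) or
    ``simulate`` (parameters for
    :func:`~rankset.synthetic_data.synthesize_genotypes`); plus ``gene``,
    ``seed``, and optional ``fdr_threshold``, ``n_resampled_genes``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs: dict[str, Path] = {}

    stage = "load-genotypes"
    if "simulate" in config:
        sim_params = dict(config["simulate"])
        sim_params.setdefault("seed", seed)
        sim = synthesize_genotypes(**sim_params)
        gt = sim.table
        gene = config.get("gene", sim.target_gene)
        gt_path = out_dir / "genotypes.tsv"
        map_path = out_dir / "snp_gene_map.tsv"
        write_genotypes(gt, gt_path, map_path)
        inputs["genotypes"] = gt_path
        inputs["gene_map"] = map_path
    else:
        gt_path = Path(_require(config, "genotypes", stage))
        map_path = Path(_require(config, "gene_map", stage))
        gene = _require(config, "gene", stage)
        try:
            gt = read_genotypes(gt_path, map_path)
        except FileNotFoundError as e:
            raise PipelineError(stage, f"missing input file: {e.filename}") from e
        inputs["genotypes"] = gt_path
        inputs["gene_map"] = map_path

    fdr_threshold = float(config.get("fdr_threshold", DEFAULT_FDR_THRESHOLD))
    stage = "assoc"
    try:
        assoc = gene_assoc(gt, gene, fdr_threshold=fdr_threshold)
    except (KeyError, ValueError) as e:
        raise PipelineError(stage, str(e)) from e
    assoc_path = out_dir / "assoc.tsv"
    write_assoc_tsv(assoc, assoc_path)
    logger.info(
        "gene %s: %d SNPs tested, %d significant at FDR < %g",
        gene,
        len(assoc),
        int(assoc["significant"].sum()),
        fdr_threshold,
    )

    stage = "resample-genes"
    n_genes = int(config.get("n_resampled_genes", DEFAULT_N_RESAMPLED_GENES))
    try:
        resamp = random_gene_resampling(
            gt, gene, n_genes=n_genes, seed=seed, fdr_threshold=fdr_threshold
        )
    except (KeyError, ValueError) as e:
        raise PipelineError(stage, str(e)) from e
    resamp_path = out_dir / "resampling.tsv"
    pd.DataFrame(
        [
            {
                "target_gene": resamp.target_gene,
                "n_genes": resamp.n_genes,
                "n_hits": resamp.n_hits,
                "empirical_p": resamp.empirical_p,
                "significant": resamp.significant,
                "seed": resamp.seed,
            }
        ]
    ).to_csv(resamp_path, sep="\t", index=False)
    logger.info(
        "resampling: %d/%d random genes hit FDR < %g; empirical p = %.4g",
        resamp.n_hits,
        resamp.n_genes,
        fdr_threshold,
        resamp.empirical_p,
    )
    write_provenance(
        out_dir / "provenance.json",
        "genetics-arm",
        {
            "seed": seed,
            "gene": gene,
            "fdr_threshold": fdr_threshold,
            "n_resampled_genes": n_genes,
            "simulate": config.get("simulate"),
        },
        inputs,
    )
    return {
        "assoc_path": str(assoc_path),
        "resampling_path": str(resamp_path),
        "assoc": assoc,
        "resampling": resamp,
    }
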