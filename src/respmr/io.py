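"""Plain-text readers/writers for the pipeline's standard tables.

Everything is TSV/JSON/GMT so any stage can run standalone; the genotype
panel can be exported either as a dosage TSV or a minimal VCF (GT field).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .response import ExpressionMatrix
from .simulate import GenotypePanel

EXPRESSION_COLUMNS = ["gene_id", "individual_id", "replicate", "condition",
                      "group", "log2_expr"]
EQTL_COLUMNS = ["gene_id", "snp_id", "tissue", "beta", "se", "pvalue", "fdr"]
GWAS_COLUMNS = ["snp_id", "chrom", "pos_1based", "effect_allele",
                "other_allele", "beta", "se", "pvalue"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path) -> ExpressionMatrix:
    long = pd.read_csv(path, sep="\t")
    return ExpressionMatrix.from_long(long)


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{what} is missing columns {sorted(missing)}")


def write_eqtl_tsv(eqtl: pd.DataFrame, path) -> None:
    _check_columns(eqtl, EQTL_COLUMNS, "eQTL table")
    eqtl.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_eqtl_tsv(path) -> pd.DataFrame:
    eqtl = pd.read_csv(path, sep="\t")
    _check_columns(eqtl, EQTL_COLUMNS, "eQTL table")
    return eqtl


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    _check_columns(gwas, GWAS_COLUMNS, "GWAS table")
    gwas.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gwas_tsv(path) -> pd.DataFrame:
    gwas = pd.read_csv(path, sep="\t")
    _check_columns(gwas, GWAS_COLUMNS, "GWAS table")
    return gwas


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    """SNPs as rows, individuals as columns, plus the allele frequency."""
    cols = [f"S{i:05d}" for i in range(panel.n_individuals)]
    df = pd.DataFrame(panel.dosages.T, index=panel.snp_ids, columns=cols)
    df.insert(0, "allele_freq", np.round(panel.allele_freqs, 6))
    df.rename_axis("snp_id").to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    freqs = df.pop("allele_freq").to_numpy()
    return GenotypePanel(dosages=df.to_numpy(dtype=np.int8).T,
                         snp_ids=list(df.index), allele_freqs=freqs)


def write_vcf(panel: GenotypePanel, path, chrom: str = "1",
              spacing: int = 5000) -> None:
    """Minimal unphased-GT VCF export of the panel."""
    samples = [f"S{i:05d}" for i in range(panel.n_individuals)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j, snp in enumerate(panel.snp_ids):
        gts = "\t".join(_GT[int(d)] for d in panel.dosages[:, j])
        lines.append(f"{chrom}\t{1 + spacing * j}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypePanel:
    """Read a GT-only VCF back into a panel (alt-allele dosage)."""
    snp_ids, rows = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line:
            continue
        fields = line.split("\t")
        snp_ids.append(fields[2])
        rows.append([sum(int(a) for a in gt.replace("|", "/").split("/"))
                     for gt in fields[9:]])
    if not snp_ids:
        raise DataError("no variant records in VCF")
    dosages = np.array(rows, dtype=np.int8).T
    freqs = dosages.mean(axis=0) / 2.0
    return GenotypePanel(dosages=dosages, snp_ids=snp_ids, allele_freqs=freqs)


def read_gmt(path) -> dict:
    """GMT: one set per line, tab-separated -> name, description, genes."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes)
             for name, genes in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
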