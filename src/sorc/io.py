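"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel either as a TSV dosage matrix (header = variant ids,
first column = individual ids) or as VCF (biallelic SNVs, GT field);
gene maps, phenotypes, stability tables and rankings are TSV; simulation
truth and run manifests are JSON.  Round-trips are exact.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import TestResult
from .data_model import GeneMap, GenotypeMatrix, PhenotypeVector, VariantInfo
from .simulator import SimTruth
from .stability import RankingResult, StabilityTable

logger = logging.getLogger(__name__)


# -- genotype TSV -----------------------------------------------------------

def write_genotype_tsv(path, g: GenotypeMatrix) -> None:
    df = pd.DataFrame(g.values, index=g.individual_ids, columns=g.variant_ids)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_genotype_tsv(path, coding: str = "dosage") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int8),
        coding,
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


# -- VCF --------------------------------------------------------------------

def write_vcf(path, g: GenotypeMatrix) -> None:
    """Minimal diploid VCF with synthetic contig/positions (dosage input)."""
    if g.coding != "dosage":
        raise ValueError("VCF writer expects dosage coding")
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1,length=%d>\n' % (len(g.variant_ids) * 100 + 1000))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, vid in enumerate(g.variant_ids):
            gts = "\t".join(gt_of[int(d)] for d in g.values[:, j])
            fh.write(f"1\t{(j + 1) * 100}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a dosage matrix.

    Multiallelic and non-SNV records are skipped with a warning; missing
    genotypes are an error (the analysis does not model missingness).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types)
        if (gt == 2).any():  # cyvcf2 UNKNOWN
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        dosage = np.where(gt == 3, 2, gt).astype(np.int8)  # HOM_ALT -> 2
        cols.append(dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/non-SNV record(s)")
    if not cols:
        raise ValueError("no usable biallelic SNV records in VCF")
    return GenotypeMatrix(np.column_stack(cols), "dosage", individuals, ids)


# -- gene map ---------------------------------------------------------------

def write_genemap_tsv(path, genemap: GeneMap) -> None:
    with open(path, "w") as fh:
        for gene, members in genemap.genes.items():
            for v in members:
                fh.write(f"{v}\t{gene}\n")


def read_genemap_tsv(path, has_header: bool = False) -> GeneMap:
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None,
        names=["variant_id", "gene"], dtype=str,
    )
    genes: dict[str, list[str]] = {}
    for v, gene in zip(df["variant_id"], df["gene"]):
        genes.setdefault(gene, []).append(v)
    return GeneMap(genes)


# -- phenotypes -------------------------------------------------------------

def write_phenotype_tsv(path, phenotypes: Sequence[PhenotypeVector]) -> None:
    """One column per replicate, rows aligned on individual ids."""
    if not phenotypes:
        raise ValueError("no phenotype replicates to write")
    ids = phenotypes[0].individual_ids
    data = {}
    for ph in phenotypes:
        if ph.individual_ids != ids:
            raise ValueError("phenotype replicates disagree on individual ids")
        data[f"rep{ph.replicate_id:04d}"] = ph.values
    pd.DataFrame(data, index=ids).to_csv(path, sep="\t", index_label="individual_id")


def read_phenotype_tsv(path) -> list[PhenotypeVector]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    out = []
    for r, col in enumerate(df.columns):
        out.append(PhenotypeVector(df[col].to_numpy(float), ids, replicate_id=r))
    return out


# -- variant annotation -----------------------------------------------------

def write_variants_tsv(path, variants: Sequence[VariantInfo]) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "maf": v.maf,
            "is_rare": int(v.is_rare),
            "is_nonsynonymous": int(v.is_nonsynonymous),
            "is_functional": int(v.is_functional),
            "effect": v.effect,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    return [
        VariantInfo(
            variant_id=r.variant_id,
            gene=r.gene,
            maf=float(r.maf),
            is_rare=bool(r.is_rare),
            is_nonsynonymous=bool(r.is_nonsynonymous),
            is_functional=bool(r.is_functional),
            effect=float(r.effect),
        )
        for r in df.itertuples()
    ]


# -- results ----------------------------------------------------------------

def write_stability_tsv(path, st: StabilityTable, variants: dict[str, VariantInfo]) -> None:
    items = sorted(st.stabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        {
            "variant_id": v,
            "gene": variants[v].gene if v in variants else "",
            "maf": variants[v].maf if v in variants else float("nan"),
            "stability": s,
            "rank": i + 1,
        }
        for i, (v, s) in enumerate(items)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ranking_tsv(path, ranking: RankingResult) -> None:
    rows = [
        {"rank": i + 1, "id": unit, "score": score}
        for i, (unit, score) in enumerate(ranking.items)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_test_results_tsv(path, results: Sequence[TestResult]) -> None:
    ordered = sorted(results, key=lambda r: (-r.neg_log10_p, r.unit))
    rows = [
        {
            "rank": i + 1,
            "unit": r.unit,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "neg_log10_p": r.neg_log10_p,
            "df": r.df,
            "method": r.method,
        }
        for i, r in enumerate(ordered)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- truth / manifest -------------------------------------------------------

def write_truth_json(path, truth: SimTruth) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth_json(path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
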