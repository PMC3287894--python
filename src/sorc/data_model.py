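"""Core genotype/phenotype containers and rare/common bookkeeping.

The analysis operates on a cohort of ``N`` unrelated individuals typed at
``P`` biallelic variant sites grouped into genes.  Genotypes arrive either
as minor-allele dosages (0/1/2) or as carrier indicators (0/1, presence of
at least one minor allele).  Everything downstream -- collapsing, the
penalized selection, and the baseline tests -- works on carrier coding, so
this module owns the dosage -> carrier recoding, minor-allele folding,
minor-allele-frequency (MAF) computation, and the rare/common split at the
conventional 5% MAF threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_RARE_THRESHOLD = 0.05


class CodingError(ValueError):
    """Genotype values outside the declared coding's alphabet."""


class AlignmentError(ValueError):
    """Individual ids of two inputs do not match."""


@dataclass
class GenotypeMatrix:
    """``N x P`` integer genotype matrix with row/column identifiers.

    Parameters
    ----------
    values
        Integer matrix, individuals in rows, variants in columns.
        Entries are in ``{0, 1, 2}`` for ``coding="dosage"`` and in
        ``{0, 1}`` for ``coding="carrier"``.
    coding
        Either ``"dosage"`` (minor-allele count) or ``"carrier"``
        (minor-allele presence indicator).
    individual_ids, variant_ids
        Unique string labels for rows and columns.
    """

    values: np.ndarray
    coding: str
    individual_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("genotype matrix must be non-empty")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match row count")
        if len(self.variant_ids) != p:
            raise ValueError("variant_ids length does not match column count")
        if len(set(self.variant_ids)) != p:
            raise ValueError("duplicate variant ids")
        if self.coding not in ("dosage", "carrier"):
            raise ValueError(f"unknown coding {self.coding!r}")
        alphabet = (0, 1, 2) if self.coding == "dosage" else (0, 1)
        if not np.isin(self.values, alphabet).all():
            raise CodingError(
                f"genotype entries outside the {self.coding} alphabet {alphabet}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        """Genotype column for one variant."""
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None
        return self.values[:, j]


@dataclass
class VariantInfo:
    """Per-variant metadata.

    ``is_functional`` and ``effect`` are simulation ground truth only; real
    data leaves them at their defaults.  ``is_nonsynonymous`` is taken as
    given annotation (never computed here); only nonsynonymous variants
    enter the analysis.
    """

    variant_id: str
    gene: str
    maf: float = float("nan")
    is_rare: bool = False
    is_nonsynonymous: bool = True
    is_functional: bool = False
    effect: float = 0.0


@dataclass
class GeneMap:
    """Mapping gene -> ordered list of member variant ids.

    Every variant belongs to exactly one gene and every gene has at least
    one member.
    """

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene, members in self.genes.items():
            if not members:
                raise ValueError(f"gene {gene!r} has no member variants")
            for v in members:
                if v in seen:
                    raise ValueError(f"variant {v!r} mapped to more than one gene")
                seen.add(v)

    @property
    def variant_to_gene(self) -> dict[str, str]:
        return {v: g for g, members in self.genes.items() for v in members}

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene: str) -> list[str]:
        return self.genes[gene]


@dataclass
class PhenotypeVector:
    """Quantitative phenotype for one replicate, aligned to individuals."""

    values: np.ndarray
    individual_ids: list[str]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        if len(self.individual_ids) != self.values.size:
            raise ValueError("individual_ids length does not match phenotype length")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype contains non-finite values")

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeVector":
        """Reorder to the genotype matrix's individuals; hard-fail on mismatch."""
        if self.individual_ids == g.individual_ids:
            return self
        mine, theirs = set(self.individual_ids), set(g.individual_ids)
        if mine != theirs:
            missing = sorted(theirs - mine)[:5]
            extra = sorted(mine - theirs)[:5]
            raise AlignmentError(
                f"phenotype/genotype individual ids differ "
                f"(missing from phenotype: {missing}; extra: {extra})"
            )
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        order = [pos[iid] for iid in g.individual_ids]
        return PhenotypeVector(
            self.values[order], list(g.individual_ids), self.replicate_id
        )


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per variant column.

    For dosage coding the allele count is folded to the minor allele:
    ``maf_j = min(s_j, 2N - s_j) / (2N)`` with ``s_j`` the column sum.
    For carrier coding only the carrier fraction ``c_j`` is observable and
    the MAF is recovered by Hardy-Weinberg inversion
    ``maf_j = 1 - sqrt(1 - c_j)`` (an approximation), capped to [0, 0.5].
    """
    n = g.n_individuals
    if g.coding == "dosage":
        s = g.values.sum(axis=0, dtype=np.int64)
        maf = np.minimum(s, 2 * n - s) / (2.0 * n)
    else:
        c = g.values.mean(axis=0, dtype=float)
        maf = 1.0 - np.sqrt(np.clip(1.0 - c, 0.0, 1.0))
    return np.clip(maf, 0.0, 0.5)


def fold_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Re-orient dosage columns so the counted allele is the minor one.

    Columns whose allele frequency exceeds 0.5 are flipped (``2 - d``);
    carrier-coded input is returned unchanged (its orientation is assumed).
    """
    if g.coding != "dosage":
        return g
    s = g.values.sum(axis=0, dtype=np.int64)
    flip = s > g.n_individuals  # allele freq > 0.5
    if not flip.any():
        return g
    values = g.values.copy()
    values[:, flip] = 2 - values[:, flip]
    return GenotypeMatrix(values, "dosage", g.individual_ids, g.variant_ids)


def recode_to_carrier(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosage to carrier indicator (1 iff dosage >= 1).

    Idempotent on carrier input.  Dosages must already be oriented to the
    minor allele (see :func:`fold_to_minor`).
    """
    if g.coding == "carrier":
        return g
    values = (g.values > 0).astype(np.int8)
    return GenotypeMatrix(values, "carrier", g.individual_ids, g.variant_ids)


class RareCommonSplit(NamedTuple):
    rare: list[str]
    common: list[str]
    monomorphic: list[str]


def split_rare_common(
    variants: Sequence[VariantInfo],
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
) -> RareCommonSplit:
    """Partition variants into rare (0 < MAF < threshold) and common (MAF >= threshold).

    Monomorphic variants (MAF == 0) carry no information and are excluded
    from both sets; they are returned separately and logged.
    """
    if not 0.0 < rare_threshold <= 0.5:
        raise ValueError("rare_threshold must lie in (0, 0.5]")
    rare, common, mono = [], [], []
    for v in variants:
        if v.maf <= 0.0:
            mono.append(v.variant_id)
        elif v.maf < rare_threshold:
            rare.append(v.variant_id)
        else:
            common.append(v.variant_id)
    if mono:
        logger.info("dropped %d monomorphic variant(s)", len(mono))
    return RareCommonSplit(rare, common, mono)


@dataclass
class PreparedCohort:
    """Analysis-ready cohort: carrier genotypes plus the rare/common split.

    Produced by :func:`prepare`; consumed by the SORC engine and the
    baseline tests so that folding, recoding, MAF computation, and the
    nonsynonymous/monomorphic filters happen in exactly one place.
    """

    carrier: GenotypeMatrix
    variants: dict[str, VariantInfo]
    genemap: GeneMap
    rare_by_gene: dict[str, list[str]]
    common_ids: list[str]
    dropped_monomorphic: list[str]
    dropped_synonymous: list[str]
    rare_threshold: float

    @property
    def analyzed_ids(self) -> list[str]:
        out = [v for ids in self.rare_by_gene.values() for v in ids]
        return out + list(self.common_ids)

    def gene_of(self, variant_id: str) -> str:
        return self.variants[variant_id].gene


def prepare(
    g: GenotypeMatrix,
    genemap: GeneMap,
    variants: Sequence[VariantInfo] | None = None,
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
) -> PreparedCohort:
    """Fold, recode to carrier, compute MAF, and split rare/common.

    ``variants`` may supply annotation (gene, ``is_nonsynonymous``,
    simulation truth); when omitted, annotation is derived from the gene
    map with every variant treated as nonsynonymous.  Variants not present
    in the genotype matrix or the gene map, synonymous variants, and
    monomorphic variants are excluded from the analysis sets.
    """
    folded = fold_to_minor(g)
    maf = compute_maf(folded)
    carrier = recode_to_carrier(folded)
    maf_of = dict(zip(g.variant_ids, maf))

    v2g = genemap.variant_to_gene
    if variants is None:
        infos = [VariantInfo(v, gene=v2g[v]) for v in g.variant_ids if v in v2g]
    else:
        infos = [replace(v) for v in variants if v.variant_id in v2g]
    by_id: dict[str, VariantInfo] = {}
    for v in infos:
        if v.variant_id not in maf_of:
            continue
        v.maf = float(maf_of[v.variant_id])
        v.is_rare = 0.0 < v.maf < rare_threshold
        by_id[v.variant_id] = v

    candidates = [v for v in by_id.values() if v.is_nonsynonymous]
    dropped_syn = [v.variant_id for v in by_id.values() if not v.is_nonsynonymous]
    split = split_rare_common(candidates, rare_threshold)
    rare_set = set(split.rare)

    rare_by_gene: dict[str, list[str]] = {}
    for gene, members in genemap.genes.items():
        in_gene = [v for v in members if v in rare_set]
        if in_gene:
            rare_by_gene[gene] = in_gene

    return PreparedCohort(
        carrier=carrier,
        variants=by_id,
        genemap=genemap,
        rare_by_gene=rare_by_gene,
        common_ids=split.common,
        dropped_monomorphic=split.monomorphic,
        dropped_synonymous=dropped_syn,
        rare_threshold=rare_threshold,
    )
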