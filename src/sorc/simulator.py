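"""Synthetic mini-exome cohort generator.

Emulates the structure of a sequencing-based quantitative-trait cohort of
unrelated individuals: K genes each holding a handful of variants, a MAF
spectrum dominated by rare alleles (most below 1%), a few "functional"
genes whose rare variants carry linear effects on the trait, and many
phenotype replicates simulated over one fixed genotype matrix.  Genotypes
are drawn independently per site under Hardy-Weinberg equilibrium (no
linkage disequilibrium by default), which keeps analytic oracles clean.

Effects act on dosage (0/1/2) even though the analysis recodes genotypes
to carrier 0/1 -- deliberately mirroring the mismatch between an additive
generative model and burden-style coding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data_model import GeneMap, GenotypeMatrix, PhenotypeVector, VariantInfo


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Cohort generator settings.

    Defaults give a desk-scale analog of a mini-exome study: 50 genes of
    4-12 variants, N=700 individuals, 87% of variants rare (MAF < 5%,
    drawn from ``0.05 * Beta(0.4, 2)`` so most fall below 1%), 3 functional
    genes with 4 functional rare variants each, per-carrier-allele effects
    uniform on [0.17, 1.2] (trait units), unit trait noise, and 20
    phenotype replicates sharing the genotype matrix.
    """

    n_individuals: int = 700
    n_genes: int = 50
    variants_per_gene: tuple[int, int] = (4, 12)  # inclusive (min, max)
    rare_fraction: float = 0.87
    rare_beta: tuple[float, float] = (0.4, 2.0)  # MAF = 0.05 * Beta(a, b)
    rare_threshold: float = 0.05
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    functional_genes: int = 3
    functional_variants_per_gene: int = 4
    effect_range: tuple[float, float] = (0.17, 1.2)
    noise_sd: float = 1.0
    n_phenotype_replicates: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_genes < 1:
            raise ConfigError("n_individuals and n_genes must be >= 1")
        lo, hi = self.variants_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError("variants_per_gene must satisfy 1 <= min <= max")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ConfigError("rare_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.functional_genes > self.n_genes:
            raise ConfigError("functional_genes exceeds n_genes")
        if self.n_phenotype_replicates < 1:
            raise ConfigError("need at least one phenotype replicate")


@dataclass
class SimTruth:
    """Generative ground truth: which variants are functional and how."""

    effects: dict[str, float]  # functional variant -> per-allele effect
    true_maf: dict[str, float]
    functional_genes: list[str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            effects={k: float(v) for k, v in d["effects"].items()},
            true_maf={k: float(v) for k, v in d["true_maf"].items()},
            functional_genes=list(d["functional_genes"]),
            seed=int(d["seed"]),
        )


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GeneMap, list[VariantInfo], SimTruth]:
    """Draw one genotype cohort plus annotation and ground truth.

    Per variant a true MAF is drawn from the spectrum and genotypes are
    i.i.d. Binomial(2, maf) across individuals.  Functional variants are
    sampled from rare variants of the designated functional genes,
    restricted to sites actually observed in the cohort (realized minor-
    allele count >= 1).  ``VariantInfo.maf`` holds the *empirical* MAF an
    analyst would compute; the true MAF lives in :class:`SimTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals

    gene_names = [f"GENE{k + 1:03d}" for k in range(cfg.n_genes)]
    lo, hi = cfg.variants_per_gene
    sizes = rng.integers(lo, hi + 1, size=cfg.n_genes)

    variant_ids: list[str] = []
    genes: dict[str, list[str]] = {}
    gene_of: dict[str, str] = {}
    for gene, m in zip(gene_names, sizes):
        members = [f"{gene}_V{j + 1:02d}" for j in range(m)]
        genes[gene] = members
        variant_ids.extend(members)
        for v in members:
            gene_of[v] = gene
    p_total = len(variant_ids)

    is_rare = rng.random(p_total) < cfg.rare_fraction
    a, b = cfg.rare_beta
    maf = np.where(
        is_rare,
        cfg.rare_threshold * rng.beta(a, b, size=p_total),
        rng.uniform(*cfg.common_maf_range, size=p_total),
    )
    genotypes = rng.binomial(2, maf, size=(n, p_total)).astype(np.int8)

    g = GenotypeMatrix(
        genotypes,
        "dosage",
        [f"IND{i + 1:04d}" for i in range(n)],
        variant_ids,
    )
    genemap = GeneMap(genes)
    true_maf = dict(zip(variant_ids, maf.astype(float)))

    # pick functional genes among those with enough observed rare variants
    mac = genotypes.sum(axis=0)
    observed_rare = {
        v for v, r, c in zip(variant_ids, is_rare, mac) if r and c >= 1
    }
    eligible = [
        gene
        for gene in gene_names
        if sum(1 for v in genes[gene] if v in observed_rare)
        >= cfg.functional_variants_per_gene
    ]
    if len(eligible) < cfg.functional_genes:
        raise ConfigError(
            "functional variant demand exceeds the observed rare variants; "
            "increase gene sizes or lower functional_variants_per_gene"
        )
    chosen = sorted(
        str(x) for x in rng.choice(eligible, size=cfg.functional_genes, replace=False)
    )
    effects: dict[str, float] = {}
    for gene in chosen:
        pool = [v for v in genes[gene] if v in observed_rare]
        picked = rng.choice(pool, size=cfg.functional_variants_per_gene, replace=False)
        for v in sorted(str(x) for x in picked):
            effects[v] = float(rng.uniform(*cfg.effect_range))

    emp_maf = np.minimum(mac, 2 * n - mac) / (2.0 * n)
    infos = [
        VariantInfo(
            variant_id=v,
            gene=gene_of[v],
            maf=float(emp_maf[j]),
            is_rare=0.0 < emp_maf[j] < cfg.rare_threshold,
            is_nonsynonymous=True,
            is_functional=v in effects,
            effect=effects.get(v, 0.0),
        )
        for j, v in enumerate(variant_ids)
    ]
    truth = SimTruth(
        effects=effects,
        true_maf=true_maf,
        functional_genes=list(chosen),
        seed=cfg.seed,
    )
    return g, genemap, infos, truth


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: SimTruth,
    noise_sd: float = 1.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[PhenotypeVector]:
    """Quantitative-trait replicates over a fixed genotype matrix.

    ``Y = sum_v effect_v * dosage_v + eps`` with fresh i.i.d.
    ``Normal(0, noise_sd^2)`` noise per replicate.
    """
    missing = [v for v in truth.effects if v not in g.variant_ids]
    if missing:
        raise ValueError(f"truth variants absent from genotypes: {missing[:5]}")
    rng = np.random.default_rng(seed)
    pos = {v: j for j, v in enumerate(g.variant_ids)}
    genetic = np.zeros(g.n_individuals)
    for v, beta in truth.effects.items():
        genetic = genetic + beta * g.values[:, pos[v]].astype(float)
    out = []
    for r in range(n_replicates):
        y = genetic + rng.normal(0.0, noise_sd, size=g.n_individuals)
        out.append(PhenotypeVector(y, list(g.individual_ids), replicate_id=r))
    return out
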