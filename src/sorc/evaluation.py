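"""Synthetic-cohort benchmark harness.

Runs the full method comparison on a simulated mini-exome cohort: SORC and
the three baseline rankers over a set of phenotype replicates sharing one
genotype matrix, scored against the simulator's ground truth.  This is the
desk-scale analog of a workshop-style evaluation: genes are "identified"
when they rank within the top T, and methods are compared by how often
their top-ranked genes are truly functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baselines import run_baseline
from .data_model import PreparedCohort, prepare
from .simulator import SimConfig, SimTruth, simulate_cohort, simulate_phenotypes
from .stability import (
    RankingResult,
    StabilityTable,
    count_identifications,
    rank_genes,
    run_sorc_prepared,
)

BASELINE_METHODS = ("single", "collapse", "cmc")


@dataclass
class ProfileResult:
    """Everything the benchmark computes for one simulated cohort."""

    truth: SimTruth
    cohort: PreparedCohort
    stability_tables: list[StabilityTable]
    sorc_gene_rankings: list[RankingResult]
    baseline_gene_rankings: dict[str, list[RankingResult]]

    @property
    def n_replicates(self) -> int:
        return len(self.sorc_gene_rankings)


def run_profile(
    seed: int,
    cfg: SimConfig | None = None,
    R: int = 50,
    cv_folds: int = 10,
    baselines: tuple[str, ...] = BASELINE_METHODS,
) -> ProfileResult:
    """Simulate one cohort and run all methods over every phenotype replicate.

    ``seed`` drives the cohort draw, the phenotype noise, and the SORC
    engine (three distinct derived seeds, all below 2**31).
    """
    if cfg is None:
        cfg = SimConfig()
    derived = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    cfg.seed = int(derived[0])
    g, genemap, variants, truth = simulate_cohort(cfg)
    phenotypes = simulate_phenotypes(
        g, truth, cfg.noise_sd, cfg.n_phenotype_replicates, seed=int(derived[1])
    )
    cohort = prepare(g, genemap, variants, cfg.rare_threshold)

    tables, sorc_rankings = [], []
    baseline_rankings: dict[str, list[RankingResult]] = {m: [] for m in baselines}
    for ph in phenotypes:
        st = run_sorc_prepared(
            cohort, ph, R=R, cv_folds=cv_folds,
            seed=int(derived[2]) + ph.replicate_id,
        )
        tables.append(st)
        sorc_rankings.append(rank_genes(st, genemap))
        for m in baselines:
            _, ranking = run_baseline(cohort, ph, m)
            baseline_rankings[m].append(ranking)
    return ProfileResult(truth, cohort, tables, sorc_rankings, baseline_rankings)


def top1_functional_rate(result: ProfileResult) -> float:
    """Fraction of replicates whose top-ranked SORC gene is truly functional."""
    functional = set(result.truth.functional_genes)
    hits = sum(1 for r in result.sorc_gene_rankings if r.ids[0] in functional)
    return hits / result.n_replicates


def stability_contrast(result: ProfileResult) -> dict:
    """Mean stability of functional vs non-functional variants, per replicate,
    with a paired one-sided test that functional variants score higher."""
    functional = set(result.truth.effects)
    f_means, n_means = [], []
    for st in result.stability_tables:
        f = [s for v, s in st.stabilities.items() if v in functional]
        n = [s for v, s in st.stabilities.items() if v not in functional]
        f_means.append(float(np.mean(f)))
        n_means.append(float(np.mean(n)))
    diff = np.asarray(f_means) - np.asarray(n_means)
    t = stats.ttest_rel(f_means, n_means, alternative="greater")
    return {
        "functional_mean": float(np.mean(f_means)),
        "nonfunctional_mean": float(np.mean(n_means)),
        "mean_difference": float(np.mean(diff)),
        "paired_p": float(t.pvalue),
    }


def mean_functional_in_top(
    rankings: list[RankingResult], functional_genes: set[str], top_T: int = 10
) -> float:
    """Average count of truly functional genes inside the top-T list."""
    counts = [
        sum(1 for g in r.top_ids(top_T) if g in functional_genes) for r in rankings
    ]
    return float(np.mean(counts))


def identification_table(result: ProfileResult, top_T: int = 15) -> dict[str, int]:
    """How often each gene is identified (top-T) by SORC across replicates."""
    return count_identifications(result.sorc_gene_rankings, top_T)
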