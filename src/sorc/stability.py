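"""The SORC engine: per-repetition penalized selection and stability ranking.

Each repetition draws a fresh random-collapsing plan for every gene, builds
the design ``[X | U]`` (collapsed rare indicators plus individual common
carriers), and fits an L1-penalized least-squares regression

    min over (b, g) of  ||Y - Xb - Ug||^2 + lambda * (||b||_1 + ||g||_1)

with an unpenalized intercept, choosing ``lambda`` on a geometric grid by
K-fold cross-validation (minimum mean CV error).  A selected X column marks
every rare variant in its subgroup as selected that repetition; a selected
U column marks its single common variant.  After ``R`` repetitions a
variant's *stability* is the fraction of repetitions in which it was
selected, and variants (or genes, via their best member) are ranked by
stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .collapsing import CollapsedDesign, CollapsePlan, build_design, draw_plan
from .data_model import (
    GeneMap,
    GenotypeMatrix,
    PhenotypeVector,
    PreparedCohort,
    VariantInfo,
    prepare,
)

logger = logging.getLogger(__name__)

#: coefficients below this magnitude (standardized scale) count as zero
ZERO_TOL = 1e-8


class DegenerateFoldError(ValueError):
    """Phenotype has too few distinct values to support the CV fold count."""


@dataclass
class SelectionResult:
    """Outcome of one repetition's penalized selection."""

    repetition: int
    selected_rare: set[str]
    selected_common: set[str]
    lambda_used: float
    n_nonzero: int
    selected_columns: tuple[int, ...] = ()
    #: fitted coefficients on the full design column space (standardized
    #: scale when standardization is on; zero for dropped constant columns)
    coef: np.ndarray | None = None
    intercept: float = 0.0


@dataclass
class StabilityTable:
    """Per-variant selection frequencies over R repetitions."""

    stabilities: dict[str, float]
    R: int

    def __getitem__(self, variant_id: str) -> float:
        return self.stabilities[variant_id]


@dataclass
class RankingResult:
    """Items (variants or genes) with scores, in non-increasing order."""

    items: list[tuple[str, float]]
    tie_rule: str
    top: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.items]

    def top_ids(self, t: int) -> list[str]:
        return [i for i, _ in self.items[:t]]


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (standardized matrix restricted to
    non-constant columns, boolean keep mask)."""
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    keep = sd > 0
    Z = (M[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def lasso_select(
    y: PhenotypeVector | np.ndarray,
    design: CollapsedDesign,
    cv_folds: int = 10,
    fold_seed: int = 0,
    *,
    repetition: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    zero_tol: float = ZERO_TOL,
    standardize: bool = True,
    fixed_lambda: float | None = None,
) -> SelectionResult:
    """One penalized selection pass on a collapsed design.

    ``lambda`` is chosen by ``cv_folds``-fold cross-validation over a
    geometric grid of ``n_lambdas`` points from the data-driven maximum
    down to ``lambda_min_ratio`` times it, unless ``fixed_lambda`` pins it
    (on the scale of the ``||Y - Mb||^2 + lambda ||b||_1`` objective).
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    M = design.matrix
    n = M.shape[0]
    if yv.shape[0] != n:
        raise ValueError("phenotype length does not match design rows")
    if fixed_lambda is None:
        if not 2 <= cv_folds <= n:
            raise ValueError("cv_folds must satisfy 2 <= cv_folds <= N")
        if np.unique(yv).size < cv_folds:
            raise DegenerateFoldError(
                "phenotype has fewer distinct values than CV folds"
            )

    if standardize:
        Z, keep = _standardize(M)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.debug("dropped %d constant design column(s)", n_dropped)
    else:
        Z, keep = M, np.ones(M.shape[1], dtype=bool)
    if Z.shape[1] == 0:
        raise ValueError("design has no non-constant columns")

    # sklearn objective: (1/2n)||y - Zw||^2 + alpha ||w||_1, so
    # lambda = 2 n alpha on the unnormalized-RSS scale.
    if fixed_lambda is not None:
        model = Lasso(alpha=fixed_lambda / (2.0 * n), fit_intercept=True,
                      max_iter=50_000, tol=1e-10)
        model.fit(Z, yv)
        lam = float(fixed_lambda)
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=int(fold_seed))
        model = LassoCV(
            alphas=n_lambdas,
            eps=lambda_min_ratio,
            cv=cv,
            fit_intercept=True,
            max_iter=10_000,
        )
        model.fit(Z, yv)
        lam = float(2.0 * n * model.alpha_)

    coef = np.zeros(M.shape[1])
    coef[keep] = model.coef_
    nonzero = np.flatnonzero(np.abs(coef) > zero_tol)

    n_x = design.X.shape[1]
    selected_rare: set[str] = set()
    selected_common: set[str] = set()
    for j in nonzero:
        if j < n_x:
            _, subgroup = design.column_map[j]
            selected_rare.update(subgroup)
        else:
            selected_common.add(design.u_column_map[j - n_x])
    return SelectionResult(
        repetition=repetition,
        selected_rare=selected_rare,
        selected_common=selected_common,
        lambda_used=lam,
        n_nonzero=int(nonzero.size),
        selected_columns=tuple(int(j) for j in nonzero),
        coef=coef,
        intercept=float(model.intercept_),
    )


def run_sorc_prepared(
    cohort: PreparedCohort,
    y: PhenotypeVector,
    R: int = 100,
    cv_folds: int = 10,
    seed: int = 0,
    *,
    plans_by_repetition: Sequence[Mapping[str, CollapsePlan]] | None = None,
    collect_plans: bool = False,
    collect_selections: bool = False,
    **lasso_kwargs,
) -> StabilityTable | tuple:
    """Run SORC on an analysis-ready cohort.

    Two independent RNG streams are spawned from ``seed``: one drives the
    random partitions (consumed in sorted gene order), the other the CV
    fold assignment, so the collapsing sequence is invariant to
    ``cv_folds``.  ``plans_by_repetition`` replays a recorded plan sequence
    instead of drawing fresh ones.  A failed repetition aborts the run.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    yv = y.aligned_to(cohort.carrier)
    part_ss, fold_ss = np.random.SeedSequence(seed).spawn(2)
    part_rng = np.random.default_rng(part_ss)
    fold_rng = np.random.default_rng(fold_ss)

    counts: dict[str, int] = {v: 0 for v in cohort.analyzed_ids}
    all_plans: list[dict[str, CollapsePlan]] = []
    selections: list[SelectionResult] = []
    for r in range(R):
        if plans_by_repetition is not None:
            plans = dict(plans_by_repetition[r])
        else:
            plans = {
                gene: draw_plan(gene, cohort.rare_by_gene[gene], part_rng)
                for gene in sorted(cohort.rare_by_gene)
            }
        fold_seed = int(fold_rng.integers(2**31))
        design = build_design(cohort.carrier, plans, cohort.common_ids)
        sel = lasso_select(
            yv, design, cv_folds=cv_folds, fold_seed=fold_seed,
            repetition=r, **lasso_kwargs,
        )
        logger.debug(
            "repetition %d: lambda=%.4g, %d nonzero columns", r, sel.lambda_used,
            sel.n_nonzero,
        )
        for v in sel.selected_rare | sel.selected_common:
            if v in counts:
                counts[v] += 1
        if collect_plans:
            all_plans.append(plans)
        if collect_selections:
            selections.append(sel)

    table = StabilityTable({v: c / R for v, c in counts.items()}, R)
    if not (collect_plans or collect_selections):
        return table
    out = [table]
    if collect_plans:
        out.append(all_plans)
    if collect_selections:
        out.append(selections)
    return tuple(out)


def run_sorc(
    g: GenotypeMatrix,
    genemap: GeneMap,
    variants: Sequence[VariantInfo] | None,
    y: PhenotypeVector,
    R: int = 100,
    cv_folds: int = 10,
    seed: int = 0,
    rare_threshold: float = 0.05,
    **kwargs,
) -> StabilityTable:
    """End-to-end SORC: prepare the cohort, then stability selection."""
    cohort = prepare(g, genemap, variants, rare_threshold)
    return run_sorc_prepared(cohort, y, R=R, cv_folds=cv_folds, seed=seed, **kwargs)


def rank_variants(st: StabilityTable, T: int | None = None) -> RankingResult:
    """Variants by stability, descending; ties broken lexicographically."""
    if T is not None and T < 1:
        raise ValueError("T must be >= 1")
    items = sorted(st.stabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [v for v, _ in items[:T]] if T is not None else []
    return RankingResult(items, "stability desc, variant_id asc", top)


def rank_genes(st: StabilityTable, genemap: GeneMap) -> RankingResult:
    """Genes scored by the best (maximum) member stability.

    Ties are broken by the number of members with stability >= 0.5, then
    by gene id, so the ordering is deterministic.
    """
    v2g = genemap.variant_to_gene
    members: dict[str, list[float]] = {}
    for v, s in st.stabilities.items():
        gene = v2g.get(v)
        if gene is None:
            raise KeyError(f"variant {v!r} not mapped to a gene")
        members.setdefault(gene, []).append(s)
    scored = [
        (gene, max(vals), sum(1 for s in vals if s >= 0.5))
        for gene, vals in members.items()
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return RankingResult(
        [(gene, score) for gene, score, _ in scored],
        "max stability desc, count(stability >= 0.5) desc, gene asc",
    )


def count_identifications(
    per_replicate_rankings: Sequence[RankingResult], top_T: int = 15
) -> dict[str, int]:
    """How often each gene ranks within the top ``top_T`` across phenotype
    replicates ("identified").  Sorted by count descending, then gene id."""
    if not per_replicate_rankings:
        raise ValueError("need at least one replicate ranking")
    counts: dict[str, int] = {}
    for ranking in per_replicate_rankings:
        for gene in ranking.ids:
            counts.setdefault(gene, 0)
        for gene in ranking.top_ids(top_T):
            counts[gene] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return dict(ordered)
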