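"""Comparison approaches: single-marker, gene-collapsing, and CMC tests.

All three are rankers on -log10(p): the single-marker test regresses the
trait on one carrier column (two-sided t on the slope); the collapsing
method tests the whole-gene burden indicator the same way; the CMC method
(combined multivariate and collapsing) builds a per-gene design of
MAF-binned rare burden indicators plus uncollapsed common carriers and
applies the overall regression F-test.  No multiple-testing correction is
applied anywhere -- the methods are compared purely as rankers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .collapsing import collapse_indicator, fixed_maf_partition
from .data_model import GenotypeMatrix, PhenotypeVector, PreparedCohort, VariantInfo
from .stability import RankingResult

#: p-values are floored here so -log10(p) stays finite at underflow
P_FLOOR = 1e-300
#: relative tolerance for the collinear-column drop
COLLINEAR_TOL = 1e-10


class MonomorphicError(ValueError):
    """Test requested on a constant (information-free) column."""


class InsufficientDFError(ValueError):
    """Too few residual degrees of freedom for the multivariate test."""


@dataclass
class TestResult:
    unit: str
    statistic: float
    p_value: float
    neg_log10_p: float
    df: str
    method: str = ""


def _as_array(y: PhenotypeVector | np.ndarray) -> np.ndarray:
    return y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)


def single_marker_test(
    y: PhenotypeVector | np.ndarray, column: np.ndarray, unit: str = ""
) -> TestResult:
    """Simple linear regression of the trait on one 0/1 carrier column;
    exact two-sided t-test on the slope with N - 2 df."""
    yv = _as_array(y)
    x = np.asarray(column, dtype=float)
    if np.ptp(x) == 0:
        raise MonomorphicError(f"column for {unit!r} is constant")
    res = stats.linregress(x, yv)
    p = float(res.pvalue)
    if not np.isfinite(p):  # perfect fit: slope t-statistic overflows
        p = P_FLOOR
    p = min(max(p, P_FLOOR), 1.0)
    stat = float(res.slope / res.stderr) if res.stderr > 0 else np.inf
    return TestResult(
        unit=unit,
        statistic=stat,
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
        df=f"t({yv.size - 2})",
        method="single",
    )


def gene_collapse_test(
    y: PhenotypeVector | np.ndarray,
    g: GenotypeMatrix,
    gene: str,
    rare_ids: Sequence[str],
) -> TestResult:
    """Whole-gene burden test: collapse all the gene's rare variants into
    one indicator, then the single-marker t-test on it."""
    if not rare_ids:
        raise MonomorphicError(f"gene {gene!r} has no rare polymorphic variants")
    indicator = collapse_indicator(g, rare_ids)
    if np.ptp(indicator) == 0:
        raise MonomorphicError(f"gene {gene!r} burden indicator is constant")
    out = single_marker_test(y, indicator, unit=gene)
    out.method = "collapse"
    return out


def _drop_collinear(cols: list[np.ndarray]) -> list[int]:
    """Greedy rank filter: keep columns (input order priority) whose
    residual after projection on the kept set exceeds tolerance."""
    kept: list[int] = []
    basis: list[np.ndarray] = []  # orthonormal
    for j, c in enumerate(cols):
        r = c - c.mean()  # intercept is always in the model
        norm0 = np.linalg.norm(r)
        if norm0 == 0:
            continue
        for q in basis:
            r = r - (q @ r) * q
        if np.linalg.norm(r) > COLLINEAR_TOL * max(norm0, 1.0):
            basis.append(r / np.linalg.norm(r))
            kept.append(j)
    return kept


def cmc_test(
    y: PhenotypeVector | np.ndarray,
    g: GenotypeMatrix,
    gene: str,
    rare_variants: Sequence[VariantInfo],
    common_ids: Sequence[str],
    maf_cut: float | None = None,
    rare_threshold: float = 0.05,
) -> TestResult:
    """CMC multivariate test for one gene on a quantitative trait.

    Design: MAF-binned rare burden indicators (single whole-gene bin by
    default, optional two-bin split at ``maf_cut``) plus the gene's
    uncollapsed common carrier columns.  Constant and collinear columns are
    dropped (input-order priority); the statistic is the overall F-test of
    the multiple linear regression, p from ``F(q, N - q - 1)``.
    """
    yv = _as_array(y)
    cols: list[np.ndarray] = []
    if any(0.0 < v.maf < rare_threshold for v in rare_variants):
        plan = fixed_maf_partition(gene, rare_variants, maf_cut, rare_threshold)
        for subgroup in plan.subgroups:
            cols.append(collapse_indicator(g, subgroup).astype(float))
    for v in common_ids:
        cols.append(g.column(v).astype(float))
    cols = [c for c in cols if np.ptp(c) > 0]
    if not cols:
        raise MonomorphicError(f"gene {gene!r} has no polymorphic design columns")
    kept = _drop_collinear(cols)
    if not kept:
        raise MonomorphicError(f"gene {gene!r} design is constant after filtering")
    Xd = np.column_stack([cols[j] for j in kept])
    q = Xd.shape[1]
    n = yv.size
    if n <= q + 1:
        raise InsufficientDFError(f"gene {gene!r}: N={n} <= q+1={q + 1}")
    fit = sm.OLS(yv, sm.add_constant(Xd)).fit()
    p = float(fit.f_pvalue)
    p = min(max(p, P_FLOOR), 1.0)
    return TestResult(
        unit=gene,
        statistic=float(fit.fvalue),
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
        df=f"F({q},{n - q - 1})",
        method="cmc",
    )


def rank_by_neglogp(
    results: Sequence[TestResult],
    level: str = "variant",
    gene_of: Mapping[str, str] | None = None,
) -> RankingResult:
    """Rank units by -log10(p) descending, ties by id.

    With ``level="gene"`` and a variant->gene mapping, variant-level
    results are reduced to genes by the best (maximum) member score.
    """
    if not results:
        raise ValueError("no test results to rank")
    if level == "gene" and gene_of is not None:
        best: dict[str, float] = {}
        for r in results:
            gene = gene_of.get(r.unit, r.unit)
            best[gene] = max(best.get(gene, -np.inf), r.neg_log10_p)
        items = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    else:
        items = sorted(
            ((r.unit, r.neg_log10_p) for r in results), key=lambda kv: (-kv[1], kv[0])
        )
    return RankingResult(list(items), "-log10(p) desc, id asc")


def run_baseline(
    cohort: PreparedCohort,
    y: PhenotypeVector,
    method: str,
    maf_cut: float | None = None,
) -> tuple[list[TestResult], RankingResult]:
    """Apply one baseline across the cohort; returns per-unit results and
    the gene-level ranking (skipping degenerate units)."""
    yv = y.aligned_to(cohort.carrier)
    g = cohort.carrier
    results: list[TestResult] = []
    if method == "single":
        for v in cohort.analyzed_ids:
            col = g.column(v)
            if np.ptp(col) == 0:
                continue
            results.append(single_marker_test(yv, col, unit=v))
        ranking = rank_by_neglogp(
            results, level="gene", gene_of={v: cohort.gene_of(v) for v in cohort.analyzed_ids}
        )
    elif method == "collapse":
        for gene, rare_ids in cohort.rare_by_gene.items():
            try:
                results.append(gene_collapse_test(yv, g, gene, rare_ids))
            except MonomorphicError:
                continue
        ranking = rank_by_neglogp(results)
    elif method == "cmc":
        common_by_gene: dict[str, list[str]] = {}
        for v in cohort.common_ids:
            common_by_gene.setdefault(cohort.gene_of(v), []).append(v)
        genes = sorted(set(cohort.rare_by_gene) | set(common_by_gene))
        for gene in genes:
            rare_vi = [
                cohort.variants[v] for v in cohort.rare_by_gene.get(gene, [])
            ]
            try:
                results.append(
                    cmc_test(
                        yv, g, gene, rare_vi, common_by_gene.get(gene, []),
                        maf_cut=maf_cut, rare_threshold=cohort.rare_threshold,
                    )
                )
            except (MonomorphicError, InsufficientDFError):
                continue
        ranking = rank_by_neglogp(results)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return results, ranking
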