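"""The SORC engine: penalized selection, stability aggregation, ranking."""

import numpy as np
import pytest
from scipy import stats

from sorc import (
    GeneMap,
    GenotypeMatrix,
    PhenotypeVector,
    SimConfig,
    prepare,
    simulate_cohort,
    simulate_phenotypes,
)
from sorc.collapsing import CollapsedDesign
from sorc.stability import (
    DegenerateFoldError,
    StabilityTable,
    _standardize,
    count_identifications,
    lasso_select,
    rank_genes,
    rank_variants,
    run_sorc,
    run_sorc_prepared,
)


def _design_from_columns(cols: np.ndarray) -> CollapsedDesign:
    """Each column its own single-variant gene; no common block."""
    n, p = cols.shape
    return CollapsedDesign(
        X=cols.astype(np.int8),
        column_map=[(f"g{j}", (f"v{j}",)) for j in range(p)],
        U=np.empty((n, 0), dtype=np.int8),
        u_column_map=[],
    )


def _lambda_max(cols: np.ndarray, y: np.ndarray) -> float:
    Z, _ = _standardize(cols.astype(float))
    yc = y - y.mean()
    return 2.0 * np.abs(Z.T @ yc).max()


class TestLassoSelect:
    def test_lambda_above_max_selects_nothing(self, rng):
        cols = rng.integers(0, 2, size=(80, 6))
        y = rng.normal(size=80)
        design = _design_from_columns(cols)
        lam = _lambda_max(cols, y) * 1.001
        sel = lasso_select(y, design, fixed_lambda=lam)
        assert sel.selected_rare == set() and sel.n_nonzero == 0

    def test_kkt_subgradient_on_toy_instance(self, rng):
        cols = rng.integers(0, 2, size=(60, 5))
        y = 1.5 * cols[:, 0] + rng.normal(size=60)
        design = _design_from_columns(cols)
        lam = 0.3 * _lambda_max(cols, y)
        sel = lasso_select(y, design, fixed_lambda=lam)
        Z, keep = _standardize(cols.astype(float))
        w = sel.coef[keep]
        r = y - sel.intercept - Z @ w
        grad = 2.0 * Z.T @ r
        tol = 1e-6 * max(1.0, lam)
        for gj, wj in zip(grad, w):
            if wj == 0:
                assert abs(gj) <= lam + tol
            else:
                assert abs(gj - lam * np.sign(wj)) <= tol

    def test_strong_signal_recovered_and_agrees_with_ols_oracle(self):
        # Y = 2 x1 + eps, eps ~ N(0, 0.25); 10 pure-noise carrier columns
        hits, oracle_hits = 0, 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            cols = r.integers(0, 2, size=(200, 11))
            y = 2.0 * cols[:, 0] + r.normal(0, 0.5, size=200)
            sel = lasso_select(
                y, _design_from_columns(cols), cv_folds=5, fold_seed=seed
            )
            hits += "v0" in sel.selected_rare
            # OLS oracle: per-column t-test at Bonferroni 0.05/11
            p = stats.linregress(cols[:, 0].astype(float), y).pvalue
            oracle_hits += p < 0.05 / 11
        assert hits >= 95
        assert oracle_hits >= 95

    def test_degenerate_phenotype_raises(self, rng):
        cols = rng.integers(0, 2, size=(30, 3))
        y = np.repeat([0.0, 1.0, 2.0], 10)  # 3 distinct values < 5 folds
        with pytest.raises(DegenerateFoldError):
            lasso_select(y, _design_from_columns(cols), cv_folds=5)


def _single_variant_cohort(n=300, p=8, seed=5, effect=1.2):
    """Every gene holds exactly one variant; the first has a large effect."""
    r = np.random.default_rng(seed)
    dosage = r.binomial(2, r.uniform(0.01, 0.04, size=p), size=(n, p)).astype(np.int8)
    dosage[:, 0] = r.binomial(2, 0.03, size=n)
    g = GenotypeMatrix(dosage, "dosage", [f"i{i}" for i in range(n)],
                       [f"v{j}" for j in range(p)])
    genemap = GeneMap({f"g{j}": [f"v{j}"] for j in range(p)})
    y = PhenotypeVector(
        effect * dosage[:, 0] + r.normal(0, 1.0, size=n), list(g.individual_ids)
    )
    return g, genemap, y


class TestRunSorc:
    def test_r1_stabilities_are_zero_or_one(self, small_cohort, small_sim):
        _, _, _, _, phen = small_sim
        st = run_sorc_prepared(small_cohort, phen[0], R=1, cv_folds=5, seed=1)
        assert set(st.stabilities.values()) <= {0.0, 1.0}

    def test_stability_lattice_and_attribution_sum(self, small_cohort, small_sim):
        _, _, _, _, phen = small_sim
        R = 7
        st, sels = run_sorc_prepared(
            small_cohort, phen[0], R=R, cv_folds=5, seed=2, collect_selections=True
        )
        lattice = {k / R for k in range(R + 1)}
        assert set(st.stabilities.values()) <= lattice
        total = sum(len(s.selected_rare | s.selected_common) for s in sels)
        assert sum(st.stabilities.values()) * R == pytest.approx(total)

    def test_seed_determinism(self, small_cohort, small_sim):
        _, _, _, _, phen = small_sim
        a = run_sorc_prepared(small_cohort, phen[0], R=4, cv_folds=5, seed=9)
        b = run_sorc_prepared(small_cohort, phen[0], R=4, cv_folds=5, seed=9)
        assert a.stabilities == b.stabilities

    def test_collapsing_sequence_invariant_to_cv_folds(self, small_cohort, small_sim):
        _, _, _, _, phen = small_sim
        _, plans5 = run_sorc_prepared(
            small_cohort, phen[0], R=3, cv_folds=5, seed=4, collect_plans=True
        )
        _, plans10 = run_sorc_prepared(
            small_cohort, phen[0], R=3, cv_folds=10, seed=4, collect_plans=True
        )
        assert [
            {g: p.subgroups for g, p in rep.items()} for rep in plans5
        ] == [{g: p.subgroups for g, p in rep.items()} for rep in plans10]

    def test_strong_single_variant_gene_has_stability_one(self):
        g, genemap, y = _single_variant_cohort()
        st = run_sorc(g, genemap, None, y, R=10, cv_folds=5, seed=3)
        assert st.stabilities["v0"] == 1.0

    def test_pure_noise_phenotype_yields_low_stabilities(self):
        cfg = SimConfig(n_individuals=300, n_genes=12, functional_genes=0,
                        n_phenotype_replicates=1, seed=21)
        g, genemap, variants, truth = simulate_cohort(cfg)
        assert truth.effects == {}
        y = simulate_phenotypes(g, truth, 1.0, 1, seed=22)[0]
        cohort = prepare(g, genemap, variants)
        st = run_sorc_prepared(cohort, y, R=20, cv_folds=5, seed=23)
        vals = np.array(list(st.stabilities.values()))
        assert np.median(vals) <= 0.1
        assert vals.mean() < 0.2

    def test_functional_variants_more_stable_than_nonfunctional(self):
        # one functional gene, paired across phenotype replicates
        cfg = SimConfig(n_individuals=400, n_genes=12, functional_genes=1,
                        functional_variants_per_gene=3, n_phenotype_replicates=10,
                        seed=31)
        g, genemap, variants, truth = simulate_cohort(cfg)
        phen = simulate_phenotypes(g, truth, 1.0, 10, seed=32)
        cohort = prepare(g, genemap, variants)
        f_means, n_means = [], []
        for ph in phen:
            st = run_sorc_prepared(cohort, ph, R=15, cv_folds=5, seed=33)
            f = [s for v, s in st.stabilities.items() if v in truth.effects]
            n = [s for v, s in st.stabilities.items() if v not in truth.effects]
            f_means.append(np.mean(f))
            n_means.append(np.mean(n))
        t = stats.ttest_rel(f_means, n_means, alternative="greater")
        assert t.pvalue < 0.01


class TestRanking:
    def test_rank_variants_tie_broken_lexicographically(self):
        st = StabilityTable({"a": 1.0, "d": 0.1, "c": 0.95, "b": 0.95}, R=20)
        r = rank_variants(st, T=2)
        assert r.ids == ["a", "b", "c", "d"]
        assert r.top == ["a", "b"]

    def test_rank_variants_all_equal_is_lexicographic(self):
        st = StabilityTable({"z": 0.5, "a": 0.5, "m": 0.5}, R=2)
        assert rank_variants(st).ids == ["a", "m", "z"]

    def test_ordered_stabilities_are_non_increasing(self):
        vals = [1, 1, 1, 0.95, 0.94, 0.92, 0.88, 0.87]
        st = StabilityTable({f"v{j}": s for j, s in enumerate(vals)}, R=100)
        scores = [s for _, s in rank_variants(st).items]
        assert scores == sorted(scores, reverse=True)

    def test_rank_genes_max_rule(self):
        st = StabilityTable({"a1": 0.2, "a2": 1.0, "b1": 0.9}, R=10)
        gm = GeneMap({"A": ["a1", "a2"], "B": ["b1"]})
        assert rank_genes(st, gm).ids == ["A", "B"]

    def test_rank_genes_tie_broken_by_strong_member_count(self):
        st = StabilityTable(
            {"a1": 1.0, "a2": 0.6, "a3": 0.7, "b1": 1.0, "b2": 0.1}, R=10
        )
        gm = GeneMap({"B": ["b1", "b2"], "A": ["a1", "a2", "a3"]})
        assert rank_genes(st, gm).ids == ["A", "B"]

    def test_rank_genes_matches_sort_oracle(self, rng):
        genes = {f"g{k:02d}": [f"g{k:02d}v{j}" for j in range(3)] for k in range(50)}
        gm = GeneMap(genes)
        st = StabilityTable(
            {v: float(rng.integers(0, 11)) / 10 for vs in genes.values() for v in vs},
            R=10,
        )
        expected = sorted(
            genes,
            key=lambda g: (
                -max(st[v] for v in genes[g]),
                -sum(st[v] >= 0.5 for v in genes[g]),
                g,
            ),
        )
        assert rank_genes(st, gm).ids == expected

    def test_rank_genes_unmapped_variant_raises(self):
        st = StabilityTable({"orphan": 1.0}, R=1)
        with pytest.raises(KeyError):
            rank_genes(st, GeneMap({"A": ["a1"]}))


class TestCountIdentifications:
    def _ranking(self, ids):
        from sorc.stability import RankingResult

        return RankingResult([(i, 1.0) for i in ids], "fixed")

    def test_gene_in_every_top(self):
        rankings = [self._ranking(["X", "Y", "Z"]) for _ in range(3)]
        counts = count_identifications(rankings, top_T=2)
        assert counts["X"] == 3 and counts["Z"] == 0

    def test_matches_bruteforce_tally(self, rng):
        genes = [f"g{k}" for k in range(30)]
        rankings = []
        for _ in range(20):
            order = list(rng.permutation(genes))
            rankings.append(self._ranking(order))
        counts = count_identifications(rankings, top_T=5)
        for g in genes:
            expected = sum(r.ids.index(g) < 5 for r in rankings)
            assert counts[g] == expected

    def test_requires_at_least_one_ranking(self):
        with pytest.raises(ValueError):
            count_identifications([], 5)
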