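"""Differential-expression contracts: case/control construction, BH step-up
against a definitional oracle, voom weight behaviour, moderated-statistic
calibration and power, aware-DE set algebra, enrichment, and the restricted
(covariate-free) DE mode."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adiposcreen._stats import bh_adjust
from adiposcreen.de import (
    aware_de_sets,
    build_case_control,
    de_restricted,
    fit_moderated,
    hypergeometric_enrichment,
    voom_weights,
)
from adiposcreen.prep import CountMatrix, ExpressionMatrix, log_cpm, tmm_factors
from adiposcreen.synth import PlantedDE, SimConfig, simulate_study


def bh_oracle(p):
    """Definitional BH: adj_p_i = min_{j: p_j >= p_i} min(1, m p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for i in range(m):
        cands = [
            min(1.0, m * p[j] / (np.searchsorted(p[order], p[j], side="right")))
            for j in range(m)
            if p[j] >= p[i]
        ]
        adj[i] = min(cands)
    return adj


class TestBenjaminiHochberg:
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_definitional_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


def _pheno(grades):
    return pd.DataFrame(grades, columns=["steatosis", "fibrosis", "NASH"]).rename(
        index=lambda i: f"s{i}"
    )


class TestCaseControl:
    def test_case_control_and_excluded(self):
        ph = _pheno([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        cc = build_case_control(ph, "steatosis")
        assert cc.case_ids == ["s0"]
        assert cc.control_ids == ["s1"]
        # s2 has a nonzero fibrosis grade: neither case nor control
        assert "s2" not in cc.sample_ids

    def test_all_zero_is_control_for_every_trait(self):
        ph = _pheno([[0, 0, 0], [1, 1, 1]])
        for trait in ("steatosis", "fibrosis", "NASH"):
            cc = build_case_control(ph, trait)
            assert cc.control_ids == ["s0"]
            assert cc.case_ids == ["s1"]

    def test_no_controls_raises(self):
        ph = _pheno([[1, 0, 0], [0, 2, 0]])
        with pytest.raises(ValueError):
            build_case_control(ph, "steatosis")


class TestVoomWeights:
    def _design(self, n):
        return pd.DataFrame(
            {"intercept": 1.0, "group": [0] * (n // 2) + [1] * (n - n // 2)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_weights_positive_and_nb_trend(self):
        cfg = SimConfig(
            n_samples=80, n_genes_adipose=500, n_genes_liver=500,
            n_shared_genes=400, n_variants=5, seed=5,
        )
        bundle = simulate_study(cfg)
        counts = bundle.adipose_counts
        expr = log_cpm(counts, tmm_factors(counts))
        design = self._design(80)
        design.index = counts.sample_ids
        w = voom_weights(expr, design)
        assert (w > 0).all()
        # lower-count genes are noisier on the log scale -> smaller weights
        mean_count = counts.values.mean(axis=1).to_numpy()
        rho = stats.spearmanr(mean_count, w.mean(axis=1)).statistic
        assert rho > 0.5

    def test_flat_weights_for_tiny_gene_sets(self, rng):
        expr = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((4, 20)), columns=[f"s{i}" for i in range(20)])
        )
        with pytest.warns(UserWarning):
            w = voom_weights(expr, self._design(20))
        assert np.allclose(w, 1.0)


class TestFitModerated:
    def _fit_null(self, seed, n=40, genes=1500):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((genes, n)), columns=samples)
        )
        design = pd.DataFrame(
            {"intercept": 1.0, "group": rng.integers(0, 2, n)}, index=samples
        )
        return fit_moderated(expr, design, "group")

    def test_null_pvalues_uniform(self):
        ks_ps = [
            stats.kstest(self._fit_null(seed)["p"], "uniform").pvalue
            for seed in range(10)
        ]
        assert np.median(ks_ps) > 0.01

    def test_planted_signal_recovered_with_sign(self):
        rng = np.random.default_rng(7)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        group = np.r_[np.zeros(100), np.ones(100)]
        vals = rng.standard_normal((400, n))
        vals[:20] += 1.5 * group  # planted up-in-cases
        expr = ExpressionMatrix(pd.DataFrame(vals, columns=samples))
        design = pd.DataFrame({"intercept": 1.0, "group": group}, index=samples)
        tab = fit_moderated(expr, design, "group")
        planted = tab.iloc[:20]
        assert (planted["adj_p"] < 0.05).mean() >= 0.95
        assert (planted["logFC"] > 0).all()

    def test_moderation_shrinks_toward_pooled(self, rng):
        # equal true variances: the moderated t should be no less significant
        # on average than the per-gene t for true effects
        tab = self._fit_null(3, n=20, genes=800)
        assert np.isfinite(tab["t"]).all()

    def test_empirical_fdr_controlled(self):
        rates = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n, genes, n_true = 100, 600, 60
            samples = [f"s{i}" for i in range(n)]
            group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            vals = rng.standard_normal((genes, n))
            vals[:n_true] += 1.2 * group
            expr = ExpressionMatrix(pd.DataFrame(vals, columns=samples))
            design = pd.DataFrame({"intercept": 1.0, "group": group}, index=samples)
            tab = fit_moderated(expr, design, "group")
            disc = tab["adj_p"] < 0.05
            if disc.sum():
                fd = disc[n_true:].sum() / disc.sum()
                rates.append(fd)
        assert np.mean(rates) <= 1.5 * 0.05


class TestAwareSets:
    def _tables(self, sig_map, all_genes):
        out = {}
        for trait, sig in sig_map.items():
            adj = pd.Series(1.0, index=all_genes)
            adj[list(sig)] = 0.001
            out[trait] = pd.DataFrame({"adj_p": adj})
        return out

    def test_set_difference(self):
        genes = list("ABCDE")
        de_a = self._tables({"steatosis": {"A", "B", "C"}, "fibrosis": set(), "NASH": set()}, genes)
        de_b = self._tables({"steatosis": {"B"}, "fibrosis": set(), "NASH": set()}, genes)
        aware = aware_de_sets(de_a, de_b)
        assert aware.aware_union == {"A", "C"}

    def test_disjoint_tissues(self):
        genes = list("ABCDEF")
        de_a = self._tables({"steatosis": {"A", "B"}, "fibrosis": set(), "NASH": set()}, genes)
        de_b = self._tables({"steatosis": {"E", "F"}, "fibrosis": set(), "NASH": set()}, genes)
        assert aware_de_sets(de_a, de_b).aware_union == {"A", "B"}

    def test_any_trait_vs_strict_mode(self):
        genes = list("ABC")
        de_a = self._tables({"steatosis": {"A"}, "fibrosis": set(), "NASH": set()}, genes)
        de_b = self._tables({"steatosis": set(), "fibrosis": {"A"}, "NASH": set()}, genes)
        # default removes genes DE in B for ANY trait
        assert aware_de_sets(de_a, de_b).per_trait["steatosis"] == set()
        strict = aware_de_sets(de_a, de_b, strict_per_trait=True)
        assert strict.per_trait["steatosis"] == {"A"}


class TestHypergeometricEnrichment:
    def test_exact_combinatorial_value(self):
        universe = set(range(10))
        marked = set(range(5))
        hits = set(range(5))
        p, fold = hypergeometric_enrichment(hits, marked, universe)
        assert p == pytest.approx(1 / 252, rel=1e-9)
        assert fold == pytest.approx(2.0)

    def test_hits_equal_universe_gives_p_one(self):
        universe = set(range(20))
        p, _ = hypergeometric_enrichment(universe, set(range(4)), universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), set(), set())


class TestDeRestricted:
    def _counts(self, rng, n_genes=40, n=14):
        base = rng.integers(50, 500, size=(n_genes, 1))
        vals = rng.poisson(np.tile(base, (1, n)))
        return CountMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(n)])
        )

    def test_group_total_rule_one_group_suffices(self, rng):
        counts = self._counts(rng)
        counts.values.iloc[0] = 0
        counts.values.iloc[0, 7:] = 3  # group totals (0, 21): retained
        counts.values.iloc[1] = 0  # totals (0, 0): dropped
        groups = pd.Series(["ctl"] * 7 + ["kd"] * 7, index=counts.sample_ids)
        tab = de_restricted(counts, groups, [f"g{i}" for i in range(5)])
        assert "g0" in tab.index
        assert "g1" not in tab.index

    def test_single_gene_bh_is_identity(self, rng):
        counts = self._counts(rng)
        groups = pd.Series(["ctl"] * 7 + ["kd"] * 7, index=counts.sample_ids)
        with pytest.warns(UserWarning):  # < 10 genes -> flat voom weights
            tab = de_restricted(counts, groups, ["g3"])
        assert tab.loc["g3", "adj_p"] == pytest.approx(tab.loc["g3", "p"])

    def test_planted_knockdown_detected(self):
        rng = np.random.default_rng(12)
        counts = self._counts(rng, n_genes=60)
        kd = counts.sample_ids[7:]
        counts.values.loc["g5", kd] = rng.poisson(
            counts.values.loc["g5", kd].to_numpy() * 0.25
        )
        groups = pd.Series(["ctl"] * 7 + ["kd"] * 7, index=counts.sample_ids)
        tab = de_restricted(counts, groups, [f"g{i}" for i in range(20)])
        assert tab.loc["g5", "p"] < 0.05
        assert tab.loc["g5", "logFC"] < 0
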