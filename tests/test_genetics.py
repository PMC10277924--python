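"""Genetic association contracts: cis-window semantics and slope recovery for
eQTL mapping, LD r-squared identities, the Wakefield log-ABF closed form, and
colocalization posteriors against a linear-space oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adiposcreen.genetics import (
    coloc_abf,
    ld_r2,
    map_cis_eqtls,
    mask_second_signal,
    wakefield_abf,
)


def _gene_coords(genes):
    return pd.DataFrame(
        {"chrom": "chr1", "start": [g * 3_000_000 for g in range(len(genes))],
         "end": [g * 3_000_000 + 10_000 for g in range(len(genes))]},
        index=genes,
    )


def _variant_meta(positions):
    return pd.DataFrame(
        {"chrom": "chr1", "pos": positions},
        index=[f"v{i}" for i in range(len(positions))],
    )


class TestMapCisEqtls:
    def test_window_inclusion_rules(self, rng):
        coords = _gene_coords(["g0"])  # g0 spans [0, 10_000]
        meta = _variant_meta([500_000, 2_100_000])  # in window; 2 Mb beyond end
        samples = [f"s{i}" for i in range(50)]
        expr = pd.DataFrame(rng.standard_normal((1, 50)), index=["g0"], columns=samples)
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, (50, 2)), index=samples, columns=meta.index
        )
        tab = map_cis_eqtls(expr, dos, coords, meta, window=1_000_000)
        assert set(tab["variant"]) == {"v0"}

    def test_end_only_anchor_narrows_window(self, rng):
        coords = pd.DataFrame(
            {"chrom": ["chr1"], "start": [5_000_000], "end": [5_010_000]}, index=["g0"]
        )
        # v0 is within 1 Mb of the gene start but beyond 1 Mb of the end
        meta = _variant_meta([4_005_000, 4_500_000])
        samples = [f"s{i}" for i in range(40)]
        expr = pd.DataFrame(rng.standard_normal((1, 40)), index=["g0"], columns=samples)
        dos = pd.DataFrame(rng.binomial(2, 0.4, (40, 2)), index=samples, columns=meta.index)
        both = map_cis_eqtls(expr, dos, coords, meta, cis_anchor="both")
        end_only = map_cis_eqtls(expr, dos, coords, meta, cis_anchor="end_only")
        assert set(both["variant"]) == {"v0", "v1"}
        assert set(end_only["variant"]) == {"v1"}

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(4)
        n, slope, maf = 250, 0.7, 0.3
        g = rng.binomial(2, maf, n).astype(float)
        y = slope * g + rng.standard_normal(n)
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(y[None, :], index=["g0"], columns=samples)
        dos = pd.DataFrame({"v0": g}, index=samples)
        tab = map_cis_eqtls(expr, dos, _gene_coords(["g0"]), _variant_meta([100]))
        row = tab.iloc[0]
        assert abs(row.slope - slope) < 3 * row.se
        assert row.fdr < 0.05

    def test_slope_estimate_unbiased(self):
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 500
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.7 * g + rng.standard_normal(n)
            gc = g - g.mean()
            errs.append((gc @ (y - y.mean())) / (gc @ gc) - 0.7)
        assert abs(np.mean(errs)) < 0.02

    def test_null_pvalues_uniform(self):
        ks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, m = 150, 40
            samples = [f"s{i}" for i in range(n)]
            expr = pd.DataFrame(
                rng.standard_normal((1, n)), index=["g0"], columns=samples
            )
            dos = pd.DataFrame(
                rng.binomial(2, 0.3, (n, m)), index=samples,
                columns=[f"v{i}" for i in range(m)],
            )
            meta = _variant_meta(list(range(100, 100 + m)))
            tab = map_cis_eqtls(expr, dos, _gene_coords(["g0"]), meta)
            ks.append(stats.kstest(tab["p"], "uniform").pvalue)
        assert np.median(ks) > 0.01

    def test_monomorphic_variant_skipped(self, rng):
        samples = [f"s{i}" for i in range(30)]
        expr = pd.DataFrame(rng.standard_normal((1, 30)), index=["g0"], columns=samples)
        dos = pd.DataFrame(
            {"v0": np.zeros(30), "v1": rng.binomial(2, 0.4, 30)}, index=samples
        )
        tab = map_cis_eqtls(expr, dos, _gene_coords(["g0"]), _variant_meta([10, 20]))
        assert set(tab["variant"]) == {"v1"}


class TestLdR2:
    def test_identity_and_complement(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        dos = pd.DataFrame({"a": g, "b": g.copy(), "c": 2 - g})
        r2 = ld_r2(dos)
        assert r2.at["a", "b"] == pytest.approx(1.0)
        assert r2.at["a", "c"] == pytest.approx(1.0)  # affine invariance

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(9)
        n = 5000
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, (n, 20)), columns=[f"v{i}" for i in range(20)]
        )
        r2 = ld_r2(dos).to_numpy()
        off = r2[np.triu_indices(20, 1)]
        assert (off < 0.01).mean() >= 0.95

    def test_zero_variance_is_missing(self, rng):
        dos = pd.DataFrame({"a": np.ones(50), "b": rng.binomial(2, 0.4, 50)})
        r2 = ld_r2(dos)
        assert np.isnan(r2.at["a", "b"])

    def test_pairwise_complete_with_missing(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        h = g.copy()
        h[:20] = np.nan
        r2 = ld_r2(pd.DataFrame({"a": g, "b": h}))
        assert r2.at["a", "b"] == pytest.approx(1.0)


class TestWakefieldAbf:
    def test_closed_form_value(self):
        # r = 0.0225/0.0325; log ABF = 0.5*(ln(1-r) + r z^2), z = 5
        got = wakefield_abf(0.5, 0.1, prior_sd=0.15)
        r = 0.0225 / 0.0325
        expected = 0.5 * (np.log(1 - r) + r * 25)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(8.06, abs=0.01)

    def test_null_beta_negative_log_abf(self):
        assert wakefield_abf(0.0, 0.2) < 0

    def test_monotone_in_abs_z(self):
        zs = np.linspace(0, 10, 50)
        vals = wakefield_abf(zs * 0.1, np.full(50, 0.1))
        assert (np.diff(vals) > 0).all()

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_abf(0.1, 0.0)


def coloc_oracle(l1, l2, p1, p2, p12):
    """Linear-space enumeration of the five hypotheses."""
    b1, b2 = np.exp(l1), np.exp(l2)
    s1, s2 = b1.sum(), b2.sum()
    s12 = (b1 * b2).sum()
    h = np.array([1.0, p1 * s1, p2 * s2, p1 * p2 * (s1 * s2 - s12), p12 * s12])
    return h / h.sum()


def _stats_frame(betas, ses):
    return pd.DataFrame(
        {"beta": betas, "se": ses}, index=[f"v{i}" for i in range(len(betas))]
    )


class TestColoc:
    def test_log_space_matches_linear_oracle(self, rng):
        for _ in range(10):
            n = 20
            s1 = _stats_frame(rng.normal(0, 0.1, n), rng.uniform(0.02, 0.1, n))
            s2 = _stats_frame(rng.normal(0, 0.1, n), rng.uniform(0.02, 0.1, n))
            res = coloc_abf(s1, s2)
            l1 = wakefield_abf(s1["beta"], s1["se"], 0.15)
            l2 = wakefield_abf(s2["beta"], s2["se"], 0.15)
            exp = coloc_oracle(l1, l2, 1e-4, 1e-4, 1e-5)
            assert np.abs(res.pp - exp).max() < 1e-8

    def test_all_null_gives_pp0(self, rng):
        n = 100
        s1 = _stats_frame(rng.normal(0, 0.001, n), np.full(n, 0.05))
        s2 = _stats_frame(rng.normal(0, 0.001, n), np.full(n, 0.05))
        res = coloc_abf(s1, s2)
        assert res.pp[0] > 0.95

    def test_shared_causal_variant_gives_pp4(self, rng):
        n = 100
        b1 = rng.normal(0, 0.001, n)
        b2 = rng.normal(0, 0.001, n)
        b1[7] = 8 * 0.05
        b2[7] = 8 * 0.05
        res = coloc_abf(_stats_frame(b1, np.full(n, 0.05)), _stats_frame(b2, np.full(n, 0.05)))
        assert res.pp4 > 0.9
        assert res.lead1 == "v7" and res.lead2 == "v7"

    def test_distinct_signals_give_pp3(self, rng):
        n = 100
        b1 = rng.normal(0, 0.001, n)
        b2 = rng.normal(0, 0.001, n)
        b1[3] = 8 * 0.05
        b2[60] = 8 * 0.05
        res = coloc_abf(_stats_frame(b1, np.full(n, 0.05)), _stats_frame(b2, np.full(n, 0.05)))
        assert res.pp[3] > res.pp[4]

    def test_posteriors_sum_to_one_and_variant_order_invariant(self, rng):
        n = 30
        s1 = _stats_frame(rng.normal(0, 0.1, n), rng.uniform(0.02, 0.1, n))
        s2 = _stats_frame(rng.normal(0, 0.1, n), rng.uniform(0.02, 0.1, n))
        a = coloc_abf(s1, s2)
        perm = rng.permutation(n)
        b = coloc_abf(s1.iloc[perm], s2.iloc[perm])
        assert a.pp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(a.pp, b.pp)


class TestMaskSecondSignal:
    def _ld(self, r2_vals, names):
        return pd.DataFrame(r2_vals, index=names, columns=names)

    def test_lead_neighbourhood_removed(self):
        names = ["a", "b", "c"]
        ld = self._ld([[1, 0.9, 0.05], [0.9, 1, 0.05], [0.05, 0.05, 1]], names)
        stats_tab = pd.DataFrame({"beta": [1, 1, 1], "se": [1, 1, 1]}, index=names)
        kept = mask_second_signal(stats_tab, ld, "a", r2_mask=0.2)
        assert list(kept.index) == ["c"]

    def test_zero_mask_removes_all_correlated(self):
        names = ["a", "b", "c"]
        ld = self._ld([[1, 0.01, 0.0], [0.01, 1, 0.0], [0.0, 0.0, 1]], names)
        stats_tab = pd.DataFrame({"beta": [1, 1, 1], "se": [1, 1, 1]}, index=names)
        kept = mask_second_signal(stats_tab, ld, "a", r2_mask=0.0)
        assert list(kept.index) == ["c"]

    def test_independent_second_signal_detected_in_pass_two(self, rng):
        n = 60
        names = [f"v{i}" for i in range(n)]
        b1 = rng.normal(0, 0.001, n)
        b2 = rng.normal(0, 0.001, n)
        # two shared signals at independent variants
        for v in (5, 40):
            b1[v] = 0.4
            b2[v] = 0.4
        s1 = pd.DataFrame({"beta": b1, "se": np.full(n, 0.05)}, index=names)
        s2 = pd.DataFrame({"beta": b2, "se": np.full(n, 0.05)}, index=names)
        ld = pd.DataFrame(np.eye(n), index=names, columns=names)
        first = coloc_abf(s1, s2)
        lead = first.lead1
        m1 = mask_second_signal(s1, ld, lead)
        m2 = mask_second_signal(s2, ld, lead)
        second = coloc_abf(m1.loc[m1.index.intersection(m2.index)], m2)
        assert first.pp4 > 0.9
        assert second.pp4 > 0.9

    def test_single_signal_region_pass_two_null(self, rng):
        n = 60
        names = [f"v{i}" for i in range(n)]
        b = rng.normal(0, 0.001, n)
        b[10] = 0.4
        s1 = pd.DataFrame({"beta": b, "se": np.full(n, 0.05)}, index=names)
        s2 = pd.DataFrame({"beta": b + rng.normal(0, 0.001, n), "se": np.full(n, 0.05)}, index=names)
        ld = pd.DataFrame(np.eye(n), index=names, columns=names)
        lead = coloc_abf(s1, s2).lead1
        second = coloc_abf(mask_second_signal(s1, ld, lead), mask_second_signal(s2, ld, lead))
        assert second.pp[0] > 0.9
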