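"""NB Wald engine: size factors, dispersions, test calibration, shrinkage,
BH, VST, relevance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirmet import diffexp, synthetic_data as sd
from mirmet.diffexp import (
    DEConfig,
    bh_adjust,
    de_analysis,
    estimate_dispersions,
    relevance_filter,
    shrink_lfc,
    size_factors,
    vst,
    wald_test,
)

from conftest import null_two_group_design


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        a = np.array([10, 100, 1000, 40])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        s = size_factors(counts)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_permutation_equivariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 4)),
                              columns=list("abcd"))
        s = size_factors(counts)
        s_perm = size_factors(counts[["c", "a", "d", "b"]])
        assert np.allclose(s_perm[list("abcd")], s)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(80, 6)))
        s = size_factors(counts)
        assert abs(np.exp(np.mean(np.log(s))) - 1.0) < 1e-6

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 4)),
                              columns=list("abcd"))
        scaled = counts.copy()
        scaled["a"] = scaled["a"] * 3
        s0 = size_factors(counts)
        s1 = size_factors(scaled)
        # ratio of a's factor to others triples (up to the geomean rescale)
        assert np.isclose((s1["a"] / s1["b"]) / (s0["a"] / s0["b"]), 3.0)

    def test_no_allpositive_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestDispersions:
    def test_poisson_counts_near_floor(self, rng):
        mu = 500.0
        counts = pd.DataFrame(rng.poisson(mu, size=(300, 50)))
        s = size_factors(counts)
        groups = pd.Series(["a"] * 25 + ["b"] * 25, index=counts.columns)
        model = estimate_dispersions(counts, s, groups)
        assert model.genewise.median() <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.2
        mu = rng.uniform(100, 2000, size=400)
        lam = rng.gamma(1 / alpha, mu[:, None] * alpha, size=(400, 30))
        counts = pd.DataFrame(rng.poisson(lam))
        s = size_factors(counts)
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=counts.columns)
        model = estimate_dispersions(counts, s, groups)
        in_band = ((model.final >= 0.1) & (model.final <= 0.4)).mean()
        assert in_band >= 0.9

    def test_constant_counts_floored(self):
        counts = pd.DataFrame(np.full((5, 6), 100))
        s = size_factors(counts)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        model = estimate_dispersions(counts, s, groups)
        assert (model.genewise == 1e-8).all()

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(np.full((5, 3), 100))
        s = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["a", "a", "b"], index=counts.columns)
        with pytest.raises(ValueError):
            estimate_dispersions(counts, s, groups)


class TestWald:
    def test_identical_groups_null_identity(self):
        counts = pd.DataFrame(
            np.tile(np.array([100, 400, 50])[:, None], (1, 8)),
            columns=[f"s{i}" for i in range(8)])
        s = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = wald_test(counts, s, disp, list(counts.columns[:4]),
                        list(counts.columns[4:]))
        assert np.allclose(res["LFC_mle"], 0.0, atol=1e-8)
        assert np.allclose(res["p_value"], 1.0)

    def test_planted_lfc_recovery(self):
        lfcs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu_a, alpha, n = 500.0, 0.05, 15
            mu = np.concatenate([np.full(n, mu_a), np.full(n, mu_a * 4)])
            lam = rng.gamma(1 / alpha, mu * alpha, size=(50, 2 * n))
            counts = pd.DataFrame(rng.poisson(lam))
            s = pd.Series(1.0, index=counts.columns)
            disp = pd.Series(alpha, index=counts.index)
            res = wald_test(counts, s, disp, list(counts.columns[:n]),
                            list(counts.columns[n:]))
            lfcs.append(res["LFC_mle"].mean())
        assert 1.8 <= np.mean(lfcs) <= 2.2

    def test_positive_lfc_means_higher_in_case(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(np.concatenate(
            [rng.poisson(100, size=(20, 10)), rng.poisson(400, size=(20, 10))],
            axis=1))
        counts.columns = [f"s{i}" for i in range(20)]
        s = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.01, index=counts.index)
        res = wald_test(counts, s, disp, list(counts.columns[:10]),
                        list(counts.columns[10:]))
        assert (res["LFC_mle"] > 1.5).all()


class TestShrinkage:
    def test_limits_and_identity(self):
        res = pd.DataFrame({"LFC_mle": [2.0, 2.0, 1.0],
                            "SE": [1e-9, 1.0, 0.3]})
        shrunk = shrink_lfc(res, prior_var=1.0)
        assert np.isclose(shrunk.iloc[0], 2.0)        # SE -> 0
        assert np.isclose(shrunk.iloc[1], 1.0)        # SE^2 == prior -> half
        assert (shrunk.abs() <= res["LFC_mle"].abs() + 1e-12).all()

    def test_shrinkage_monotone_everywhere(self, rng):
        res = pd.DataFrame({"LFC_mle": rng.normal(0, 2, 100),
                            "SE": rng.uniform(0.05, 1.0, 100)})
        shrunk = shrink_lfc(res)
        assert (shrunk.abs() <= res["LFC_mle"].abs() + 1e-12).all()
        assert (np.sign(shrunk) == np.sign(res["LFC_mle"])).all()


def brute_force_bh(p):
    """Literal step-up: q_(i) = min_{k>=i} p_(k) * m / k, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(p[order[k]] * m / (k + 1) for k in range(rank_i, m)), 1.0)
    return q


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust(np.array([0.3]))[0] == 0.3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force(self, pvals):
        p = np.array(pvals)
        assert np.allclose(bh_adjust(p), brute_force_bh(p))

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_adjust(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestVST:
    def _model(self, a0=0.05, a1=2.0):
        return diffexp.DispersionModel(
            genewise=pd.Series(dtype=float), a0=a0, a1=a1,
            final=pd.Series(dtype=float), base_mean=pd.Series(dtype=float))

    def test_monotone(self):
        n = pd.DataFrame({"s": np.linspace(1, 1e5, 200)})
        s = pd.Series({"s": 1.0})
        out = vst(n, s, self._model())
        assert (np.diff(out["s"]) > 0).all()

    def test_log2_asymptote(self):
        s = pd.Series({"s": 1.0})
        m = self._model()
        d = {}
        for n in (1e6, 1e7):
            v = vst(pd.DataFrame({"s": [n]}), s, m).iloc[0, 0]
            d[n] = v - np.log2(n)
        assert abs(d[1e7] - d[1e6]) < 0.01

    def test_stabilizes_nb_variance(self, rng):
        a0, a1 = 0.05, 2.0
        means = np.geomspace(50, 5000, 40)
        alpha = a0 + a1 / means
        lam = rng.gamma(1 / alpha[:, None],
                        (means * alpha)[:, None], size=(40, 200))
        counts = pd.DataFrame(rng.poisson(lam))
        s = pd.Series(1.0, index=counts.columns)
        v = vst(counts, s, self._model(a0, a1))
        var_raw = counts.var(axis=1)
        var_vst = v.var(axis=1)
        assert var_raw.max() / var_raw.min() > 50
        assert var_vst.max() / var_vst.min() < 5

    def test_degenerate_trend_falls_back(self):
        counts = pd.DataFrame({"s": [0, 10, 100]})
        s = pd.Series({"s": 1.0})
        with pytest.warns(UserWarning):
            out = vst(counts, s, self._model(a0=0.0))
        assert np.allclose(out["s"], np.log2(counts["s"] + 1))


class TestRelevance:
    def _frame(self, fdr, lfc, rpm_a, rpm_b):
        return pd.DataFrame({"fdr": [fdr], "LFC_shrunk": [lfc],
                             "mean_rpm_case": [rpm_a],
                             "mean_rpm_control": [rpm_b]})

    @pytest.mark.parametrize(
        "fdr, lfc, rpm_a, rpm_b, expected",
        [
            (0.01, 0.58, 500, 500, False),   # boundary LFC: strict >
            (0.01, 1.00, 120, 50, True),     # one tissue above 100 suffices
            (0.06, 2.00, 1000, 1000, False), # FDR gate
            (0.01, -0.59, 50, 120, True),    # down-regulation symmetric
            (0.01, 1.00, 100, 100, False),   # boundary RPM: strict >
        ],
    )
    def test_gate_logic(self, fdr, lfc, rpm_a, rpm_b, expected):
        out = relevance_filter(self._frame(fdr, lfc, rpm_a, rpm_b))
        assert bool(out.iloc[0]) is expected


class TestEndToEnd:
    def test_null_pipeline_uniform_p(self):
        design = null_two_group_design(seed=42, n_per_group=20,
                                       n_mirnas=1000, dispersion=0.1)
        cm, _ = sd.simulate_counts(design)
        res = de_analysis(cm, "nCR", "pCRC")
        p = res["p_value"].dropna()
        assert 0.02 < (p < 0.05).mean() < 0.08
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_all_zero_genes_excluded(self):
        design = null_two_group_design(seed=7, n_per_group=5, n_mirnas=40)
        cm, _ = sd.simulate_counts(design)
        cm.counts.iloc[0] = 0
        res = de_analysis(cm, "nCR", "pCRC")
        assert cm.counts.index[0] not in res.index
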