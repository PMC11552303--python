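"""TMM normalisation, dispersion, the conditional exact test and PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from conftest import make_count_df
from cosegsel.rnaseq import (
    CountMatrix,
    bh_fdr,
    call_de,
    de_test,
    estimate_dispersion,
    exact_nb_pvalue,
    nb_exact_test,
    pca_summary,
    tmm_factors,
    tmm_fpkm,
)

# Reference factors for make_count_df(default_rng(42)) computed once with
# edgeR::calcNormFactors (method="TMM", edgeR 4.0.16) and frozen.
EDGER_FACTORS = [1.1393178458, 1.1340344701, 0.6839043435, 1.1317056456]


def _cm(counts: pd.DataFrame, lengths=None, groups=None) -> CountMatrix:
    lengths = pd.Series(1000, index=counts.index) if lengths is None else lengths
    groups = groups or {c: c for c in counts.columns}
    return CountMatrix(counts, lengths, pd.Series(groups))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 200, 3000], "B": [10, 200, 3000]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_gives_equal_factors(self, rng):
        base = rng.poisson(50, size=500) + 1
        counts = pd.DataFrame({"A": base, "B": base * 2})
        f = tmm_factors(counts)
        assert f["A"] == pytest.approx(f["B"], abs=1e-9)

    def test_matches_edger_reference(self):
        counts = make_count_df(np.random.default_rng(42))
        f = tmm_factors(counts)
        assert np.allclose(f.values, EDGER_FACTORS, atol=1e-6)

    def test_effective_libsizes_invariant_to_depth_scaling(self):
        counts = make_count_df(np.random.default_rng(42))
        f1 = tmm_factors(counts)
        eff1 = counts.sum() * f1
        scaled = counts.astype(float).copy()
        scaled["S2"] *= 3.0
        f2 = tmm_factors(scaled)
        eff2 = scaled.sum() * f2
        ratio = (eff2 / eff1) / (eff2 / eff1).iloc[0]
        expected = pd.Series([1.0, 3.0, 1.0, 1.0], index=counts.columns)
        # near-invariant: only the reference half of the precision weights
        # fails to rescale, a sub-0.1% effect on this fixture
        assert np.allclose(ratio, expected / expected.iloc[0], rtol=1e-3)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestFPKM:
    def test_direct_value(self):
        # count 100, length 1000 bp, effective library 1e7 -> FPKM 10
        counts = pd.DataFrame({"S": [100, 0]}, index=["g1", "g2"])
        cm = _cm(counts, lengths=pd.Series([1000, 2000], index=["g1", "g2"]))
        factors = pd.Series([1e7 / 100], index=["S"])  # lib size is 100
        f = tmm_fpkm(cm, factors)
        assert f.loc["g1", "S"] == pytest.approx(10.0)
        assert f.loc["g2", "S"] == 0.0

    def test_doubling_length_halves_fpkm(self, rng):
        counts = pd.DataFrame({"S": rng.poisson(100, 50) + 1})
        lens = pd.Series(rng.integers(500, 2000, 50), index=counts.index)
        cm1 = _cm(counts, lengths=lens)
        cm2 = _cm(counts, lengths=lens * 2)
        factors = pd.Series([1.0], index=["S"])
        assert np.allclose(tmm_fpkm(cm1, factors), 2 * tmm_fpkm(cm2, factors))


class TestDispersion:
    def test_constant_replicates_give_zero(self):
        counts = pd.DataFrame(
            {"A1": [5, 50, 500], "A2": [5, 50, 500], "A3": [5, 50, 500]})
        cm = _cm(counts, groups={c: "A" for c in counts.columns})
        phi = estimate_dispersion(cm)
        assert np.allclose(phi, 0.0)

    def test_poisson_counts_give_near_zero(self, rng):
        mu = rng.lognormal(4, 1, 2000)
        counts = pd.DataFrame({f"A{i}": rng.poisson(mu) for i in range(5)})
        cm = _cm(counts, groups={c: "A" for c in counts.columns})
        phi = estimate_dispersion(cm)
        assert np.median(phi) < 0.02

    def test_nb_dispersion_recovered(self, rng):
        phi_true = 0.1
        mu = rng.lognormal(4.5, 1, 2000)
        counts = pd.DataFrame({
            f"A{i}": rng.poisson(rng.gamma(1 / phi_true, mu * phi_true))
            for i in range(5)
        })
        cm = _cm(counts, groups={c: "A" for c in counts.columns})
        phi = estimate_dispersion(cm)
        assert 0.05 <= np.median(phi) <= 0.2

    def test_unreplicated_needs_user_phi(self):
        counts = pd.DataFrame({"A1": [5, 10], "B1": [7, 3]})
        cm = _cm(counts, groups={"A1": "A", "B1": "B"})
        with pytest.raises(ValueError):
            estimate_dispersion(cm)
        phi = estimate_dispersion(cm, user_phi=0.2)
        assert (phi == 0.2).all()


def binomial_conditional_pvalue(a: int, t: int, n_a: int, n_b: int) -> float:
    """Independent oracle: enumerate all t+1 splits of the Poisson-limit
    conditional Binomial(t, n_a/(n_a+n_b)) and sum those no more likely than
    the observed split."""
    p = n_a / (n_a + n_b)
    probs = np.array([math.comb(t, k) * p**k * (1 - p) ** (t - k)
                      for k in range(t + 1)])
    obs = probs[a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-10)].sum() / probs.sum()))


class TestExactTest:
    def test_total_zero_gives_one(self):
        assert exact_nb_pvalue(0, 0, 3, 3, 0.1) == 1.0

    def test_balanced_split_is_not_significant(self):
        assert exact_nb_pvalue(40, 80, 4, 4, 0.0) == pytest.approx(1.0)
        assert exact_nb_pvalue(40, 80, 4, 4, 0.2) == pytest.approx(1.0)

    def test_matches_binomial_oracle_when_poisson(self):
        for n_a, n_b in ((3, 3), (2, 5)):
            for t in range(1, 51):
                for a in range(t + 1):
                    mine = exact_nb_pvalue(a, t, n_a, n_b, 0.0)
                    oracle = binomial_conditional_pvalue(a, t, n_a, n_b)
                    assert mine == pytest.approx(oracle, abs=1e-10)

    @given(st.integers(0, 60), st.integers(0, 60), st.floats(0, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_in_groups(self, a, b, phi):
        p_ab = exact_nb_pvalue(a, a + b, 3, 3, phi)
        p_ba = exact_nb_pvalue(b, a + b, 3, 3, phi)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)

    def test_p_decreases_with_imbalance(self):
        t = 60
        ps = [exact_nb_pvalue(a, t, 4, 4, 0.05) for a in range(t // 2, t + 1)]
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))

    def test_library_equalisation(self, rng):
        """A pure depth difference between groups must not create signal."""
        mu = rng.lognormal(4, 1, 300)
        ca = pd.DataFrame({f"A{i}": rng.poisson(mu) for i in range(3)})
        cb = pd.DataFrame({f"B{i}": rng.poisson(mu * 4) for i in range(3)})
        p = nb_exact_test(ca, cb, 0.0, ca.sum().to_numpy(), cb.sum().to_numpy())
        assert (p < 0.05).mean() < 0.08


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_in_unit_interval_and_ge_p_under_uniform_rank(self, ps):
        q = bh_fdr(ps)
        assert ((q >= 0) & (q <= 1.0 + 1e-12)).all()


class TestCalls:
    @pytest.mark.parametrize("lfc,fdr,expected", [
        (2.5, 0.01, "up_A"),
        (2.5, 0.06, "ns"),
        (2.0, 0.01, "ns"),     # boundary strict
        (-2.5, 0.04, "up_B"),
        (-1.9, 0.001, "ns"),
    ])
    def test_threshold_rules(self, lfc, fdr, expected):
        df = pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]})
        assert call_de(df)["call"].iloc[0] == expected

    def test_de_test_recovers_known_shifts(self, rng):
        """Genes shifted 16-fold between groups are called, unshifted ones
        are not, and the zero-count gene is dropped before FDR."""
        n = 400
        mu = rng.lognormal(4, 1, n)
        shift = np.ones(n)
        shift[:20] = 16.0
        ca = {f"A{i}": rng.poisson(mu * shift) for i in range(4)}
        cb = {f"B{i}": rng.poisson(mu) for i in range(4)}
        counts = pd.DataFrame({**ca, **cb})
        counts.iloc[50] = 0
        cm = _cm(counts, groups={c: c[0] for c in counts.columns})
        res = de_test(cm, "A", "B")
        assert counts.index[50] not in res.index
        up_a = set(res.index[res["call"] == "up_A"])
        assert len(up_a & set(range(20))) >= 16
        assert len(up_a - set(range(20))) <= 2


class TestPCA:
    def test_two_noiseless_groups_put_everything_on_pc1(self):
        m = pd.DataFrame([[1, 9, 4]] * 3 + [[5, 2, 8]] * 3,
                         index=[f"s{i}" for i in range(6)])
        coords, var = pca_summary(m, log=False)
        assert var[0] == pytest.approx(1.0)

    def test_variance_fractions_conserved(self, rng):
        m = pd.DataFrame(rng.lognormal(2, 1, size=(6, 40)))
        _, var = pca_summary(m)
        assert var.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(x >= y - 1e-12 for x, y in zip(var, var[1:]))

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((4, 10)))
        with pytest.raises(ValueError):
            pca_summary(m)

    def test_parental_groups_separate_on_pc1(self, small_config):
        from cosegsel.simcross import CountSample, simulate_counts

        design = [CountSample(f"V{i}", "VIR_parent", "V") for i in range(3)] + \
            [CountSample(f"A{i}", "AVR_parent", "A") for i in range(3)]
        cm = simulate_counts(design, small_config)
        coords, _ = pca_summary(tmm_fpkm(cm).T)
        pc1 = coords["PC1"]
        assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()  # two sides
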