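"""Discovery / replication / Fisher-combination checks against closed-form
oracles and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import twinewas as tw
from twinewas import association


def _pair_matrix(diffs, base=5.0):
    """Matrix with one bin whose within-pair differences are ``diffs``."""
    k = len(diffs)
    rows, idx = [], []
    for i, d in enumerate(diffs):
        rows += [[base + d], [base]]
        idx += [f"p{i}_aff", f"p{i}_un"]
    matrix = pd.DataFrame(rows, index=idx, columns=["chr1_0"])
    pairs = pd.DataFrame({
        "family_id": [f"p{i}" for i in range(k)],
        "affected_sample": [f"p{i}_aff" for i in range(k)],
        "unaffected_sample": [f"p{i}_un" for i in range(k)],
    })
    return matrix, pairs


class TestDiscovery:
    def test_identical_pairs_t_zero_p_one(self):
        matrix, pairs = _pair_matrix([0.0, 0.0, 0.0])
        res = association.discover_discordant(matrix, pairs)
        assert res["t_disc"].iloc[0] == 0.0
        assert res["p_disc"].iloc[0] == 1.0

    def test_paired_t_closed_form(self):
        # d = {1,2,3}: t = 2 / (1/sqrt(3)) = 3.464, p = 0.0742 on 2 df
        matrix, pairs = _pair_matrix([1.0, 2.0, 3.0])
        res = association.discover_discordant(matrix, pairs)
        assert res["t_disc"].iloc[0] == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res["p_disc"].iloc[0] == pytest.approx(0.0742, abs=2e-4)

    def test_invariant_to_pair_constant_shift(self, rng):
        diffs = rng.normal(size=12)
        m1, pairs = _pair_matrix(diffs)
        m2 = m1.copy()
        shifts = np.repeat(rng.normal(scale=10, size=12), 2)
        m2["chr1_0"] = m2["chr1_0"].to_numpy() + shifts  # family effect
        r1 = association.discover_discordant(m1, pairs)
        r2 = association.discover_discordant(m2, pairs)
        assert r1["t_disc"].iloc[0] == pytest.approx(r2["t_disc"].iloc[0], rel=1e-12)

    def test_too_few_pairs_rejected(self):
        matrix, pairs = _pair_matrix([1.0])
        with pytest.raises(tw.InputError):
            association.discover_discordant(matrix, pairs)

    def test_null_type_one_error(self):
        cfg = tw.SimConfig(n_bins=10_000, frac_stable_bins=0.0,
                           causal_bin_effects=(), zero_inflation=0.0,
                           repeat_fraction=0.0, seed=41)
        matrix, cohort, _ = tw.simulate_cohort(cfg)
        m1, coh1 = tw.visit1(matrix, cohort)
        pairs = association.select_discordant_pairs(coh1, 50, seed=1)
        res = association.discover_discordant(m1, pairs)
        frac = (res["p_disc"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < 4 * se


class TestSelectDiscordantPairs:
    def test_deterministic_and_discordant(self, small_sim):
        _, _, cohort, _ = small_sim
        coh1 = cohort[cohort["visit"] == 1]
        p1 = association.select_discordant_pairs(coh1, 50, seed=7)
        p2 = association.select_discordant_pairs(coh1, 50, seed=7)
        pd.testing.assert_frame_equal(p1, p2)
        assert len(p1) == 50
        status = coh1.set_index("sample_id")["cwp"]
        assert (status.loc[p1["affected_sample"]] == 1).all()
        assert (status.loc[p1["unaffected_sample"]] == 0).all()


class TestAgeAdjustment:
    @staticmethod
    def _cohort_for(index, age):
        return pd.DataFrame({"sample_id": index, "age": age, "visit": 1})

    def test_exact_linear_signal_removed(self):
        age = np.linspace(20, 70, 40)
        matrix = pd.DataFrame({"b0": 2 + 0.1 * age}, index=[f"s{i}" for i in range(40)])
        adj = association.adjust_age(matrix, self._cohort_for(matrix.index, age))
        assert np.allclose(adj["b0"], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        age = rng.uniform(20, 80, 60)
        matrix = pd.DataFrame(rng.normal(size=(60, 5)),
                              index=[f"s{i}" for i in range(60)])
        matrix.columns = [f"b{j}" for j in range(5)]
        adj = association.adjust_age(matrix, self._cohort_for(matrix.index, age))
        resid = adj.to_numpy()
        assert np.abs(resid.T @ age).max() < 1e-7
        assert np.abs(resid.T @ age**2).max() < 1e-6

    def test_quadratic_coefficients_recovered(self, rng):
        age = rng.uniform(20, 80, 500)
        noise = rng.normal(scale=0.5, size=500)
        y = 1.0 + 0.05 * age - 4e-4 * age**2 + noise
        x = np.column_stack([np.ones(500), age, age**2])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        cov = np.linalg.inv(x.T @ x) * 0.25
        se = np.sqrt(np.diag(cov))
        for b, truth, s in zip(beta, [1.0, 0.05, -4e-4], se):
            assert abs(b - truth) < 2.5 * s

    def test_constant_age_rejected(self):
        matrix = pd.DataFrame({"b0": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(tw.CollinearityError):
            association.adjust_age(matrix, self._cohort_for(matrix.index, [50.0] * 3))


class TestReplication:
    @staticmethod
    def _cohort_groups(aff_vals, unaff_vals):
        n_a, n_u = len(aff_vals), len(unaff_vals)
        idx = [f"a{i}" for i in range(n_a)] + [f"u{i}" for i in range(n_u)]
        matrix = pd.DataFrame({"b0": list(aff_vals) + list(unaff_vals)}, index=idx)
        cohort = pd.DataFrame({"sample_id": idx, "cwp": [1] * n_a + [0] * n_u,
                               "visit": 1})
        return matrix, cohort

    def test_welch_closed_form(self):
        matrix, cohort = self._cohort_groups([0, 1, 2], [3, 4, 5])
        res = association.replicate(matrix, cohort)
        assert res["t_rep"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert res["p_rep"].iloc[0] == pytest.approx(0.0213, abs=2e-3)

    def test_identical_groups_null(self):
        matrix, cohort = self._cohort_groups([1, 2, 3], [1, 2, 3])
        res = association.replicate(matrix, cohort)
        assert res["t_rep"].iloc[0] == 0.0
        assert res["p_rep"].iloc[0] == pytest.approx(1.0)

    def test_single_member_group_rejected(self):
        matrix, cohort = self._cohort_groups([1.0], [2.0, 3.0])
        with pytest.raises(tw.InputError):
            association.replicate(matrix, cohort)


class TestFisherCombine:
    def test_closed_form_at_nominal_boundary(self):
        chi2, p, conc, ok = association.fisher_combine(
            [0.049], [0.049], [1.0], [2.0])
        ref = -2 * (np.log(0.049) + np.log(0.049))
        assert ok[0]
        assert chi2[0] == pytest.approx(ref, rel=1e-12)
        assert p[0] == pytest.approx(stats.chi2.sf(ref, 4), rel=1e-12)
        # hand-computed value at the nominal boundary p = (0.05, 0.05)
        chi2_05 = -4 * np.log(0.05)
        assert chi2_05 == pytest.approx(11.98, abs=0.01)
        assert stats.chi2.sf(chi2_05, 4) == pytest.approx(0.0175, abs=2e-4)

    def test_gate_blocks_nonsignificant_and_discordant(self):
        chi2, p, conc, ok = association.fisher_combine(
            [1.0, 0.01], [1.0, 0.01], [1.0, 1.0], [1.0, -1.0])
        assert not ok.any()
        assert np.isnan(p).all()
        assert not conc[1]

    def test_gate_disabled_degenerate(self):
        chi2, p, _, ok = association.fisher_combine([1.0], [1.0], [1], [1], gate=False)
        assert ok[0] and chi2[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0], [-0.1], [1.5]):
            with pytest.raises(tw.InputError):
                association.fisher_combine(bad, [0.5], [1], [1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p1=st.floats(1e-10, 1.0), p2=st.floats(1e-10, 1.0),
           eps=st.floats(1e-6, 0.5))
    def test_symmetric_and_monotone(self, p1, p2, eps):
        def pf(a, b):
            _, p, _, _ = association.fisher_combine([a], [b], [1], [1], gate=False)
            return p[0]

        assert pf(p1, p2) == pytest.approx(pf(p2, p1), rel=1e-12)
        smaller = p1 * (1 - eps)
        assert pf(smaller, p2) <= pf(p1, p2) + 1e-15


class TestRankTop:
    def _records(self, pf):
        n = len(pf)
        return pd.DataFrame({
            "p_fisher": pf, "chi2_fisher": [10.0] * n, "combined": [True] * n,
        }, index=[f"chr1_{250 * i}" for i in range(n)])

    def test_k_larger_than_records(self):
        recs = self._records([0.3, 0.1, 0.2])
        top = association.rank_top(recs, k=10)
        assert list(top["p_fisher"]) == [0.1, 0.2, 0.3]

    def test_tie_broken_by_coordinate_deterministically(self):
        recs = self._records([0.2, 0.2, 0.1])
        t1 = association.rank_top(recs, 2)
        t2 = association.rank_top(recs.sample(frac=1, random_state=0), 2)
        assert list(t1.index) == ["chr1_500", "chr1_0"]
        assert list(t1.index) == list(t2.index)

    def test_causal_bins_rank_high(self):
        gamma = 0.15
        cfg = tw.SimConfig(n_bins=2000, frac_stable_bins=1.0, zero_inflation=0.0,
                           causal_bin_effects=tuple((j, gamma) for j in range(4)),
                           repeat_fraction=0.0, seed=47)
        matrix, cohort, truth = tw.simulate_cohort(cfg)
        m1, coh1 = tw.visit1(matrix, cohort)
        pairs = association.select_discordant_pairs(coh1, 50, seed=5)
        disc = association.discover_discordant(m1, pairs)
        keep = ~m1.index.isin(set(pairs["affected_sample"])
                              | set(pairs["unaffected_sample"]))
        rep = association.replicate(association.adjust_age(m1.loc[keep], coh1), coh1)
        # ungated chi2 gives a complete ranking for the enrichment check
        chi2, _, _, _ = association.fisher_combine(
            disc["p_disc"], rep["p_rep"], disc["t_disc"], rep["t_rep"], gate=False)
        ranks = pd.Series(-chi2, index=disc.index).rank()
        causal_ranks = ranks.loc[truth.causal_bin_ids]
        assert causal_ranks.mean() < 0.25 * len(ranks)


def test_discovery_replication_disjoint(small_sim):
    _, matrix, cohort, _ = small_sim
    m1, coh1 = tw.visit1(matrix, cohort)
    pairs = association.select_discordant_pairs(coh1, 50, seed=3)
    disc_samples = set(pairs["affected_sample"]) | set(pairs["unaffected_sample"])
    rep_samples = set(m1.index) - disc_samples
    assert disc_samples.isdisjoint(rep_samples)
    assert len(rep_samples) == 1708 - 100
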