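"""Normalisation utilities and the joint-exceedance permutation DE test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sagakit import permde
from sagakit import synthetic_data as sd
from sagakit.permde import DifferencePairs, PermParams


def frame(values, index=None):
    values = np.atleast_2d(np.asarray(values, float))
    return pd.DataFrame(values, index=index or [f"g{i}" for i in range(len(values))],
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestQuantileNormalize:
    def test_rank_mean_definition(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [2, 4, 6]})
        out = permde.quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out["b"], [1.5, 3.0, 4.5])

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(permde.quantile_normalize(m), m)

    def test_all_columns_share_sorted_values(self, rng):
        m = pd.DataFrame(rng.uniform(size=(50, 6)))
        out = permde.quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_rank_means(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        out = permde.quantile_normalize(m)
        assert out["a"].nunique() == 1
        assert out["a"].iloc[0] == pytest.approx(out["b"].mean())


class TestLog2AndProbesets:
    def test_log2_values_and_roundtrip(self):
        m = frame([[8.0, 1.0]])
        out = permde.log2_transform(m)
        np.testing.assert_allclose(out.to_numpy(), [[3.0, 0.0]])
        m0 = frame([[0.0, 7.0]])
        assert permde.log2_transform(m0, offset=1.0).iloc[0, 0] == 0.0
        back = np.exp2(permde.log2_transform(m))
        np.testing.assert_allclose(back.to_numpy(), m.to_numpy(), atol=1e-12)

    def test_log2_nonpositive_lists_genes(self):
        with pytest.raises(ValueError, match="g0"):
            permde.log2_transform(frame([[-1.0, 2.0]]))

    def test_probeset_mean_and_identity(self):
        m = frame([[1.0, 5.0], [3.0, 7.0]], index=["p1", "p2"])
        out = permde.summarize_probesets(m, {"p1": "G", "p2": "G"})
        np.testing.assert_allclose(out.loc["G"], [2.0, 6.0])
        ident = permde.summarize_probesets(m, {"p1": "A", "p2": "B"})
        assert len(ident) == 2
        unmapped = permde.summarize_probesets(m, {"p1": "A"})
        assert unmapped.attrs["unmapped_probes"] == 1

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            permde.summarize_probesets(frame([[1.0]]), {})


def make_matrix(leader, follower, photo, nonphoto, n_genes=1):
    design = sd.make_design()
    vals = np.tile(np.concatenate([leader, follower, photo, nonphoto]),
                   (n_genes, 1)).astype(float)
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                        columns=design.sample_id), design


class TestDifferencePairs:
    def test_constant_groups_give_constant_diffs(self):
        mat, design = make_matrix([5, 5, 5], [3, 3, 3], [1, 1, 1], [0, 0, 0])
        pairs = permde.make_difference_pairs(mat, design, "leader")
        assert pairs.treatment.shape == (1, 9)
        np.testing.assert_allclose(pairs.treatment, 2.0)
        np.testing.assert_allclose(pairs.control, 1.0)

    def test_direction_reversal_negates_treatment(self, rng):
        spec = sd.ExpressionSimSpec(n_genes=10, seed=0)
        mat, design, _ = sd.generate_expression(spec)
        fwd = permde.make_difference_pairs(mat, design, "leader")
        rev = permde.make_difference_pairs(mat, design, "follower")
        np.testing.assert_allclose(np.sort(fwd.treatment, axis=1),
                                   np.sort(-rev.treatment, axis=1))

    def test_incomplete_design_rejected(self):
        mat, design = make_matrix([1, 1, 1], [1, 1, 1], [1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="missing groups"):
            permde.make_difference_pairs(mat, design[design.group != "leader"])


class TestGeneStats:
    def test_one_sample_t_textbook_value(self):
        pairs = DifferencePairs(pd.Index(["g"]), np.array([[1.0, 2, 3]]),
                                np.array([[0.0, 0, 0]]), "leader")
        stats = permde.gene_stats(pairs)
        assert stats.t_one.iloc[0] == pytest.approx(2 * np.sqrt(3))
        assert stats.t_two.iloc[0] == pytest.approx(2 * np.sqrt(3))

    def test_matches_scipy_on_random_values(self, rng):
        treat = rng.normal(0.5, 1, size=(20, 9))
        ctrl = rng.normal(0, 1, size=(20, 9))
        pairs = DifferencePairs(pd.Index(range(20)), treat, ctrl, "leader")
        stats = permde.gene_stats(pairs)
        np.testing.assert_allclose(stats.t_one,
                                   sps.ttest_1samp(treat, 0, axis=1).statistic)
        np.testing.assert_allclose(
            stats.t_two,
            sps.ttest_ind(treat, np.abs(ctrl), axis=1, equal_var=True).statistic)

    def test_degenerate_all_identical_gives_zero(self):
        pairs = DifferencePairs(pd.Index(["g"]), np.full((1, 9), 2.0),
                                np.full((1, 9), 2.0), "leader")
        stats = permde.gene_stats(pairs)
        assert stats.t_one.iloc[0] == np.inf  # positive mean, zero variance
        assert stats.t_two.iloc[0] == 0.0     # equal means, zero variance

    def test_welch_equals_pooled_in_balanced_design(self, rng):
        # with equal set sizes the Welch and pooled statistics coincide
        # (only their degrees of freedom differ)
        treat = rng.normal(0, 3, size=(5, 9))
        ctrl = rng.normal(0, 0.1, size=(5, 9))
        pairs = DifferencePairs(pd.Index(range(5)), treat, ctrl, "leader")
        pooled = permde.gene_stats(pairs, welch=False)
        welch = permde.gene_stats(pairs, welch=True)
        np.testing.assert_allclose(pooled.t_two, welch.t_two)


class TestPermutationP:
    def test_complete_degeneracy_gives_p_one(self):
        mat, design = make_matrix([5] * 3, [5] * 3, [5] * 3, [5] * 3)
        pairs = permde.make_difference_pairs(mat, design)
        for scheme in ("regroup", "pool"):
            p = permde.permutation_p(pairs, PermParams(scheme=scheme,
                                                       exhaustive=True))
            assert p.iloc[0] == 1.0

    def test_pool_exhaustive_matches_bruteforce_oracle(self, rng):
        """Vectorised pool-scheme enumeration vs per-assignment scipy t-tests."""
        treat = rng.normal(0.5, 1, size=(5, 4))
        ctrl = rng.normal(0, 1, size=(5, 4))
        pairs = DifferencePairs(pd.Index(range(5)), treat, ctrl, "leader")
        p = permde.permutation_p(pairs, PermParams(scheme="pool",
                                                   exhaustive=True))
        for g in range(5):
            pool = np.concatenate([treat[g], ctrl[g]])
            t1o = sps.ttest_1samp(treat[g], 0).statistic
            t2o = sps.ttest_ind(treat[g], np.abs(ctrl[g]),
                                equal_var=True).statistic
            count = 0
            for comb in itertools.combinations(range(8), 4):
                sel = np.zeros(8, bool)
                sel[list(comb)] = True
                t1 = sps.ttest_1samp(pool[sel], 0).statistic
                t2 = sps.ttest_ind(pool[sel], np.abs(pool[~sel]),
                                   equal_var=True).statistic
                count += (t1 >= t1o - 1e-12) and (t2 >= t2o - 1e-12)
            assert p.iloc[g] == pytest.approx(count / 70)

    def test_pool_sampled_close_to_exhaustive_on_reduced_design(self, rng):
        """B=500 sampled assignments agree with the C(8,4)=70 enumeration."""
        treat = rng.normal(0.3, 1, size=(50, 4))
        ctrl = rng.normal(0, 1, size=(50, 4))
        pairs = DifferencePairs(pd.Index(range(50)), treat, ctrl, "leader")
        p_ex = permde.permutation_p(pairs, PermParams(scheme="pool",
                                                      exhaustive=True))
        p_s = permde.permutation_p(pairs, PermParams(scheme="pool", B=500,
                                                     seed=11))
        se = np.sqrt(p_ex * (1 - p_ex) / 500) + 1e-3
        assert (np.abs(p_s - p_ex) <= 3 * se + 2 / 70).all()

    def test_regroup_sampled_close_to_exhaustive(self, rng):
        treat_top = rng.normal(0.5, 1, size=(30, 6))
        treat_bot = rng.normal(0, 1, size=(30, 6))
        mat = pd.DataFrame(
            np.concatenate([treat_top[:, :3], treat_bot[:, :3],
                            treat_top[:, 3:], treat_bot[:, 3:]], axis=1),
            columns=sd.make_design().sample_id)
        pairs = permde.make_difference_pairs(mat, sd.make_design())
        p_ex = permde.permutation_p(pairs, PermParams(B=500))  # 400 <= B: all
        p_s = permde.permutation_p(pairs, PermParams(B=150, seed=5))
        se = np.sqrt(p_ex * (1 - p_ex) / 150) + 1e-3
        assert (np.abs(p_s - p_ex) <= 3 * se + 2 / 150).all()

    def test_shift_invariance(self):
        spec = sd.ExpressionSimSpec(n_genes=20, delta=0.5, seed=6)
        mat, design, _ = sd.generate_expression(spec)
        pairs1 = permde.make_difference_pairs(mat, design)
        pairs2 = permde.make_difference_pairs(mat + 100.0, design)
        p1 = permde.permutation_p(pairs1, PermParams(seed=0))
        p2 = permde.permutation_p(pairs2, PermParams(seed=0))
        np.testing.assert_allclose(p1, p2)

    def test_planted_effect_vs_artifact_selection(self):
        """Strong leader-up genes are detected; matched photoconversion
        artifact genes (same shift in both contrasts) are not."""
        spec = sd.ExpressionSimSpec(n_genes=200, delta=1.5, baseline_sd=0.25,
                                    f_null=0.0, f_leader_up=0.5,
                                    f_follower_up=0.0, f_artifact=0.5, seed=8)
        mat, design, truth = sd.generate_expression(spec)
        pairs = permde.make_difference_pairs(mat, design)
        p = permde.permutation_p(pairs, PermParams(seed=8))
        leader_sel = (p[truth == "leader_up"] < 0.05).mean()
        artifact_notsel = (p[truth == "artifact"] >= 0.05).mean()
        assert leader_sel >= 0.9
        assert artifact_notsel >= 0.8


class TestRunDe:
    def test_selection_threshold_rule(self):
        spec = sd.ExpressionSimSpec(n_genes=100, delta=2.0, baseline_sd=0.2,
                                    f_null=0.6, f_leader_up=0.2,
                                    f_follower_up=0.2, f_artifact=0.0, seed=10)
        mat, design, truth = sd.generate_expression(spec)
        res = permde.run_de(mat, design, PermParams(seed=10))
        assert res.selected_leader.equals(res.p_leader < 0.05)
        assert res.selected_follower.equals(res.p_follower < 0.05)
        # strong effects in the right direction
        assert res.selected_leader[truth == "leader_up"].mean() >= 0.9
        assert res.selected_follower[truth == "follower_up"].mean() >= 0.9
        assert res.selected_leader[truth == "follower_up"].sum() == 0

    def test_metadata_and_reproducibility(self):
        spec = sd.ExpressionSimSpec(n_genes=30, seed=2)
        mat, design, _ = sd.generate_expression(spec)
        r1 = permde.run_de(mat, design, PermParams(seed=3))
        r2 = permde.run_de(mat, design, PermParams(seed=3))
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.attrs["scheme"] == "regroup"
        assert "assignment_digest_leader" in r1.attrs
        assert {"bh_q_leader", "bh_q_follower"} <= set(r1.columns)
        assert (r1.bh_q_leader >= r1.p_leader - 1e-12).all()

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            PermParams(B=0)
        with pytest.raises(ValueError):
            PermParams(alpha=1.5)
        with pytest.raises(ValueError):
            PermParams(scheme="bootstrap")
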