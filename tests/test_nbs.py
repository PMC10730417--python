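"""Edge-wise GLM statistics, suprathreshold clustering and the NBS."""

import numpy as np
import pandas as pd
import pytest

from fcnet import connectivity as conn
from fcnet import nbs
from fcnet import synthetic as syn


def _null_stack(n_per_group=10, n_nodes=12, T=100, seed=0, **spec_kw):
    spec = syn.CohortSpec(
        n_per_group={"A": n_per_group, "B": n_per_group},
        n_nodes=n_nodes,
        n_timepoints=T,
        base_within_r=0.3,
        base_between_r=0.1,
        global_offset={},
        covariate_model={},
        seed=seed,
        **spec_kw,
    )
    recs, meta = syn.generate_cohort(spec)
    stack = np.stack([conn.pearson_fc(r.timeseries).values for r in recs])
    return stack, meta


class TestDesign:
    def test_columns_and_contrast(self):
        meta = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B", "B"],
                "age": [30, 40, 35, 32, 38],
                "sex": ["F", "M", "F", "F", "M"],
            }
        )
        d = nbs.design_matrix(meta)
        assert d.columns == ["intercept", "group[B]", "age", "sex"]
        c = d.contrast_vector(("A", "B"))
        np.testing.assert_array_equal(c, [0, 1, 0, 0])
        c_rev = d.contrast_vector(("B", "A"))
        np.testing.assert_array_equal(c_rev, [0, -1, 0, 0])

    def test_rank_deficient_design_rejected(self):
        meta = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B", "A", "B"],
                "age": [1.0] * 6,  # constant, collinear with the intercept
                "sex": ["F", "M"] * 3,
            }
        )
        with pytest.raises(ValueError, match="rank"):
            nbs.design_matrix(meta)

    def test_more_columns_than_subjects_rejected(self):
        meta = pd.DataFrame(
            {"group": ["A", "B", "A"], "age": [1, 2, 3], "sex": ["F", "M", "F"]}
        )
        with pytest.raises(ValueError):
            nbs.design_matrix(meta)


class TestEdgeStats:
    def test_identical_groups_give_zero_statistics(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.2, (6, 8, 8))
        base = (base + base.transpose(0, 2, 1)) / 2
        for s in base:
            np.fill_diagonal(s, 1.0)
        stack = np.concatenate([base, base])  # same subjects relabeled
        meta = pd.DataFrame(
            {
                "group": ["A"] * 6 + ["B"] * 6,
                "age": list(range(6)) * 2,
                "sex": ["F", "M", "F", "M", "F", "M"] * 2,
            }
        )
        design = nbs.design_matrix(meta)
        stats = nbs.edge_stats(stack, design, ("A", "B"))
        np.testing.assert_allclose(stats, 0.0, atol=1e-10)

    def test_planted_extreme_edge_dominates(self):
        stack, meta = _null_stack(n_per_group=20, seed=2)
        grp = (meta["group"] == "B").to_numpy()
        iu = np.triu_indices(stack.shape[1], 1)
        pooled_sd = stack[:, iu[0], iu[1]].std()
        stack[grp, 2, 7] += 10 * pooled_sd
        stack[grp, 7, 2] += 10 * pooled_sd
        design = nbs.design_matrix(meta)
        stats = nbs.edge_stats(stack, design, ("A", "B"))
        vec = np.abs(stats[iu])
        assert np.argmax(vec) == np.flatnonzero((iu[0] == 2) & (iu[1] == 7))[0]

    def test_covariate_adjustment_removes_age_confound(self):
        # age differs between groups and drives every edge: the unadjusted
        # group contrast is inflated, the adjusted one is near null
        adj_ts, unadj_ts = [], []
        for rep in range(10):
            rng = np.random.default_rng(600 + rep)
            stack, meta = _null_stack(n_per_group=15, n_nodes=10, seed=50 + rep)
            meta = meta.copy()
            meta["age"] = np.r_[rng.normal(28, 3, 15), rng.normal(42, 3, 15)]
            age = meta["age"].to_numpy()
            stack += 0.004 * (age - age.mean())[:, None, None]
            for s in stack:
                np.fill_diagonal(s, 1.0)
            design = nbs.design_matrix(meta)
            t_adj = nbs.edge_stats(stack, design, ("A", "B"))
            no_cov = nbs.design_matrix(meta, covariates=())
            t_unadj = nbs.edge_stats(stack, no_cov, ("A", "B"))
            iu = np.triu_indices(10, 1)
            adj_ts.append(np.abs(t_adj[iu]).mean())
            unadj_ts.append(np.abs(t_unadj[iu]).mean())
        assert np.mean(adj_ts) < np.mean(unadj_ts)


class TestComponents:
    def _mat(self, n, edges, value=5.0):
        m = np.zeros((n, n))
        for i, j in edges:
            m[i, j] = m[j, i] = value
        return m

    def test_empty_when_nothing_suprathreshold(self):
        comps = nbs.suprathreshold_components(np.zeros((5, 5)), 3.0)
        assert comps == []

    def test_five_edge_path_over_six_nodes(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
        comps = nbs.suprathreshold_components(self._mat(8, edges), 3.0)
        assert len(comps) == 1
        assert comps[0].n_edges == 5 and comps[0].n_nodes == 6

    def test_two_disjoint_pairs(self):
        comps = nbs.suprathreshold_components(self._mat(6, [(0, 1), (3, 4)]), 3.0)
        assert [c.n_edges for c in comps] == [1, 1]

    def test_raising_threshold_never_grows_components(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 2, (15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        prev = None
        for thr in (1.0, 2.0, 3.0):
            comps = nbs.suprathreshold_components(m, thr)
            total = sum(c.n_edges for c in comps)
            biggest = max((c.n_edges for c in comps), default=0)
            if prev is not None:
                assert total <= prev[0] and biggest <= prev[1]
            prev = (total, biggest)


class TestNBSTest:
    def test_seed_determinism(self):
        stack, meta = _null_stack(seed=3)
        design = nbs.design_matrix(meta)
        cfg = nbs.NBSConfig(threshold=2.0, n_perm=200)
        r1 = nbs.nbs_test(stack, design, ("A", "B"), cfg, seed=7)
        r2 = nbs.nbs_test(stack, design, ("A", "B"), cfg, seed=7)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert [c.p_value for c in r1.components] == [c.p_value for c in r2.components]

    def test_null_max_rank_roughly_uniform(self):
        # under exchangeability the observed max size should not sit in the
        # extreme tail systematically; check p-values spread over replicates
        ps = []
        for rep in range(20):
            stack, meta = _null_stack(n_per_group=8, n_nodes=10, seed=200 + rep)
            design = nbs.design_matrix(meta)
            cfg = nbs.NBSConfig(threshold=2.0, n_perm=100)
            res = nbs.nbs_test(stack, design, ("A", "B"), cfg, seed=rep)
            if res.components:
                ps.append(min(c.p_value for c in res.components))
        assert len(ps) > 10
        assert min(ps) > 1 / 101 - 1e-9
        assert np.mean(ps) > 0.1  # not piled at the significant end

    def test_resolution_warning(self):
        stack, meta = _null_stack(n_per_group=6, n_nodes=8, seed=5)
        design = nbs.design_matrix(meta)
        cfg = nbs.NBSConfig(threshold=2.0, n_perm=100, alpha=0.005)
        res = nbs.nbs_test(stack, design, ("A", "B"), cfg, seed=0)
        assert res.warnings


class TestMedianThreshold:
    def test_study_grids(self):
        assert nbs.median_threshold(3.6, 4.2, 0.1) == pytest.approx(3.9)
        assert nbs.median_threshold(7.0, 7.8, 0.1) == pytest.approx(7.4)

    def test_single_point(self):
        assert nbs.median_threshold(5.0, 5.0, 0.1) == 5.0

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            nbs.median_threshold(3.6, 4.25, 0.1)
        with pytest.raises(ValueError):
            nbs.median_threshold(4.2, 3.6, 0.1)


class TestPosthoc:
    def test_bonferroni_alpha_arithmetic(self):
        assert round(0.05 / 3, 4) == 0.0167

    def test_three_identical_groups_nothing_significant(self):
        spec = syn.CohortSpec(
            n_per_group={"A": 8, "B": 8, "C": 8},
            n_nodes=10,
            n_timepoints=100,
            global_offset={},
            covariate_model={},
            seed=11,
        )
        recs, meta = syn.generate_cohort(spec)
        stack = np.stack([conn.pearson_fc(r.timeseries).values for r in recs])
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        results = nbs.posthoc_pairwise(
            stack,
            meta,
            pairs,
            thresholds={p: 3.0 for p in pairs},
            n_perm=200,
            seed=0,
        )
        for pair, res in results.items():
            assert not res.significant(), pair

    def test_unknown_pair_label_rejected(self):
        stack, meta = _null_stack(seed=6)
        with pytest.raises(ValueError, match="ZZ"):
            nbs.posthoc_pairwise(
                stack, meta, [("A", "ZZ")], thresholds={("A", "ZZ"): 3.0}, n_perm=100
            )


class TestComponentSummaries:
    def test_single_edge_component(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(0, 0.2, (5, 6, 6))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        vals = nbs.component_mask_strength(stack, np.array([[1, 4]]))
        np.testing.assert_allclose(vals, stack[:, 1, 4])

    def test_all_edges_equals_global_strength(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(0, 0.2, (4, 7, 7))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in stack:
            np.fill_diagonal(s, 1.0)
        iu = np.triu_indices(7, 1)
        edges = np.column_stack(iu)
        vals = nbs.component_mask_strength(stack, edges)
        expected = [conn.global_fc_strength(s) for s in stack]
        np.testing.assert_allclose(vals, expected, atol=1e-12)

    def test_path_component_nodal_strength(self):
        stack = np.zeros((2, 4, 4))
        stack[:, 0, 1] = stack[:, 1, 0] = 0.3
        stack[:, 1, 2] = stack[:, 2, 1] = 0.5
        edges = np.array([[0, 1], [1, 2]])
        vals, nodes = nbs.nodal_strength_in_component(stack, edges)
        assert nodes.tolist() == [0, 1, 2]
        np.testing.assert_allclose(vals[0], [0.3, 0.8, 0.5])

    def test_nodal_strength_handshake(self):
        rng = np.random.default_rng(4)
        stack = rng.normal(0, 0.2, (3, 8, 8))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        edges = np.array([[0, 1], [1, 2], [2, 5], [5, 0]])
        vals, _ = nbs.nodal_strength_in_component(stack, edges)
        edge_sum = stack[:, edges[:, 0], edges[:, 1]].sum(axis=1)
        np.testing.assert_allclose(vals.sum(axis=1), 2 * edge_sum, atol=1e-12)

    def test_node_outside_component_rejected(self):
        stack = np.zeros((2, 4, 4))
        with pytest.raises(ValueError, match="not part"):
            nbs.nodal_strength_in_component(stack, np.array([[0, 1]]), nodes=[3])

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            nbs.component_mask_strength(np.zeros((2, 4, 4)), np.empty((0, 2), int))
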