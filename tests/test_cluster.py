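import itertools

import numpy as np
import pandas as pd
import pytest

from progmet.cluster import (
    MetageneDefinition,
    assign_tertiles,
    average_pairwise_correlation,
    build_metagene,
    extract_subclusters,
    hcluster,
    mean_center,
    tertile_cutpoints,
)

from conftest import make_expr


def brute_force_average_linkage(D):
    """O(n^3) oracle: clusters merge at the mean of ORIGINAL pairwise
    distances between their members (equivalent to Lance-Williams UPGMA)."""
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    heights = []
    partitions = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        key = min(merged)
        clusters[key] = merged
        heights.append(d)
        partitions.append(frozenset(clusters.values()))
    return heights, partitions


def block_matrix(rng, sizes, within_loading, n_samples=200, background=0):
    rows = []
    for k, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        rows.append(within_loading * f[None, :] + rng.normal(size=(size, n_samples)))
    if background:
        rows.append(rng.normal(size=(background, n_samples)))
    return make_expr(np.vstack(rows))


class TestMeanCenter:
    def test_simple_row(self):
        m = make_expr([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(mean_center(m).values, [[-1.0, 0.0, 1.0]])

    def test_idempotent(self, rng):
        m = make_expr(rng.normal(8, 2, size=(10, 6)))
        once = mean_center(m)
        twice = mean_center(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
        assert np.all(np.abs(once.values.mean(axis=1)) < 1e-12)

    def test_columns_not_centered(self, rng):
        m = make_expr(rng.normal(8, 2, size=(10, 6)))
        out = mean_center(m)
        assert np.abs(out.values.mean(axis=0)).max() > 1e-6


class TestHcluster:
    def test_identical_rows_merge_at_zero(self, rng):
        base = rng.normal(size=12)
        m = make_expr([base, base, rng.normal(size=12)])
        d = hcluster(m)
        assert d.merges[0][2] == pytest.approx(0.0, abs=1e-12)
        assert set(d.merges[0][:2]) == {0, 1}

    def test_anticorrelated_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_expr([x, -x, 2 * x, -3 * x])
        d = hcluster(m)
        # perfectly correlated pairs (0,2) and (1,3) merge first at 0,
        # then the two pairs merge at distance 2 (correlation -1)
        assert d.merges[0][2] == pytest.approx(0.0, abs=1e-12)
        assert d.merges[1][2] == pytest.approx(0.0, abs=1e-12)
        assert d.merges[2][2] == pytest.approx(2.0, abs=1e-12)
        first_two = [set(mg[:2]) for mg in d.merges[:2]]
        assert {frozenset(s) for s in first_two} == {frozenset({0, 2}), frozenset({1, 3})}

    @pytest.mark.parametrize("n_probes", [2, 3, 5, 6, 8])
    def test_matches_brute_force_oracle(self, n_probes, rng):
        for _ in range(6):
            m = make_expr(rng.normal(size=(n_probes, 15)))
            corr = np.corrcoef(m.values)
            D = 1.0 - corr
            np.fill_diagonal(D, 0.0)
            heights, partitions = brute_force_average_linkage(D)
            d = hcluster(m)
            np.testing.assert_allclose([h for _, _, h in d.merges], heights, atol=1e-10)
            # compare leaf partitions after each merge
            clusters = {i: frozenset([i]) for i in range(n_probes)}
            for step, (l, r, _) in enumerate(d.merges):
                members = frozenset(d.members(n_probes + step))
                for k in list(clusters):
                    if clusters[k] <= members:
                        del clusters[k]
                clusters[min(members)] = members
                assert frozenset(clusters.values()) == partitions[step]

    def test_heights_monotone(self, rng):
        m = make_expr(rng.normal(size=(30, 25)))
        d = hcluster(m)
        h = [mg[2] for mg in d.merges]
        assert np.all(np.diff(h) >= -1e-10)

    def test_zero_variance_row_named(self):
        m = make_expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], probe_ids=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hcluster(m)

    def test_uncentered_metric(self, rng):
        m = make_expr(np.abs(rng.normal(5, 1, size=(6, 10))))
        d = hcluster(m, metric="uncentered_pearson")
        assert len(d.merges) == 5

    def test_newick_export(self, rng):
        m = make_expr(rng.normal(size=(5, 8)))
        nwk = hcluster(m).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4


class TestExtractSubclusters:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        # loading sqrt(3): limit within-r = 3/4
        m = block_matrix(rng, [30, 25, 20], np.sqrt(3.0))
        d = hcluster(m)
        subs = extract_subclusters(d, m, r_threshold=0.6, min_size=10)
        assert len(subs) == 3
        sizes = sorted(s.size for s in subs)
        assert sizes == [20, 25, 30]
        for s in subs:
            assert s.average_pairwise_correlation >= 0.6

    def test_independent_probes_empty(self, rng):
        m = make_expr(rng.normal(size=(60, 100)))
        subs = extract_subclusters(hcluster(m), m, r_threshold=0.6, min_size=10)
        assert subs == []

    def test_block_below_threshold_not_returned(self):
        rng = np.random.default_rng(1)
        # loading 1: limit within-r = 0.5 < 0.6
        m = block_matrix(rng, [30], 1.0, n_samples=500)
        subs = extract_subclusters(hcluster(m), m, r_threshold=0.6, min_size=10)
        assert subs == []

    def test_disjoint_and_threshold_invariant(self):
        rng = np.random.default_rng(2)
        m = block_matrix(rng, [25, 20], np.sqrt(3.0), background=40)
        subs = extract_subclusters(hcluster(m), m, r_threshold=0.6, min_size=10)
        seen = set()
        for s in subs:
            assert s.average_pairwise_correlation >= 0.6
            # recompute independently
            sub = m.subset_probes(s.probes)
            assert average_pairwise_correlation(sub.values) == pytest.approx(
                s.average_pairwise_correlation
            )
            assert not (seen & set(s.probes))
            seen |= set(s.probes)


class TestBuildMetagene:
    def _expr(self, vals):
        return make_expr(np.array(vals, dtype=float))

    def test_two_stage_averaging(self):
        # gene G1 probes (2, 4), gene G2 probe (9): collapse -> (3, 9) -> 6
        expr = make_expr([[2.0, 2.0], [4.0, 4.0], [9.0, 9.0]], probe_ids=["a", "b", "c"])
        pm = pd.Series(["G1", "G1", "G2"], index=["a", "b", "c"])
        vals, mdef = build_metagene(expr, ["a", "b", "c"], pm, "mg")
        np.testing.assert_allclose(vals.to_numpy(), [6.0, 6.0])
        assert mdef.collapse_groups == {"G1": ["a", "b"], "G2": ["c"]}

    def test_single_gene_equals_probe_mean(self, rng):
        values = rng.normal(size=(3, 5))
        expr = make_expr(values)
        pm = pd.Series(["G"] * 3, index=expr.probe_ids)
        vals, _ = build_metagene(expr, expr.probe_ids, pm, "mg")
        np.testing.assert_allclose(vals.to_numpy(), values.mean(axis=0))

    def test_gene_weight_constant_under_probe_duplication(self, rng):
        # a gene's weight in the metagene is 1/n_genes no matter how many
        # probes it has (the naive all-probe mean would over-weight G1)
        values = rng.normal(size=(3, 6))
        expr = make_expr(np.vstack([values, values[0]]), probe_ids=["a", "b", "c", "a2"])
        pm = pd.Series(["G1", "G1", "G2", "G1"], index=["a", "b", "c", "a2"])
        v, _ = build_metagene(expr, ["a", "b", "c", "a2"], pm, "mg")
        g1 = (2 * values[0] + values[1]) / 3.0
        np.testing.assert_allclose(v.to_numpy(), (g1 + values[2]) / 2.0)

    def test_exact_duplicate_row_invariance(self):
        expr = make_expr([[2.0, 4.0], [2.0, 4.0], [7.0, 1.0]], probe_ids=["a", "a2", "c"])
        pm = pd.Series(["G1", "G1", "G2"], index=["a", "a2", "c"])
        v_with, _ = build_metagene(expr, ["a", "a2", "c"], pm, "mg")
        v_without, _ = build_metagene(expr, ["a", "c"], pm, "mg")
        np.testing.assert_allclose(v_with.to_numpy(), v_without.to_numpy())

    def test_empty_probes_error(self):
        expr = make_expr([[1.0, 2.0]])
        with pytest.raises(ValueError, match="empty"):
            build_metagene(expr, [], pd.Series(dtype=object), "mg")

    def test_metagene_tracks_latent_factor(self, small_cohort):
        from progmet.simulate import probe_map_for

        expr, _, truth = small_cohort
        pm = probe_map_for(expr)
        for module in ("proliferation", "bp"):
            probes = truth.module_probes(pm, module)
            vals, _ = build_metagene(expr, probes, pm, module)
            r = np.corrcoef(vals.to_numpy(), truth.factors[module])[0, 1]
            assert r >= 0.9

    def test_json_round_trip(self, tmp_path):
        mdef = MetageneDefinition(
            "mg", ["a", "b"], {"G": ["a", "b"]}, tertile_cutpoints=(1.5, 2.5)
        )
        mdef.to_json(tmp_path / "m.json")
        back = MetageneDefinition.from_json(tmp_path / "m.json")
        assert back == mdef


class TestCrossSplitStability:
    def test_metagene_stable_across_halves(self, small_cohort):
        from progmet.simulate import probe_map_for

        expr, _, truth = small_cohort
        pm = probe_map_for(expr)
        probes = truth.module_probes(pm, "tnk")
        full, _ = build_metagene(expr, probes, pm, "tnk")
        rng = np.random.default_rng(4)
        perm = rng.permutation(expr.n_samples)
        half_ids = [expr.sample_ids[i] for i in perm[: expr.n_samples // 2]]
        half, _ = build_metagene(expr.subset_samples(half_ids), probes, pm, "tnk")
        r = np.corrcoef(half.to_numpy(), full[half.index].to_numpy())[0, 1]
        assert r > 0.95


class TestTertiles:
    def test_one_to_nine(self):
        q1, q2 = tertile_cutpoints(np.arange(1.0, 10.0))
        assert q1 == pytest.approx(3.667, abs=1e-3)
        assert q2 == pytest.approx(6.333, abs=1e-3)

    def test_all_equal_error(self):
        with pytest.raises(ValueError):
            tertile_cutpoints([2.0, 2.0, 2.0, 2.0])

    def test_equal_group_sizes_divisible(self, rng):
        v = rng.permutation(np.arange(300, dtype=float))
        cuts = tertile_cutpoints(v)
        levels = assign_tertiles(v, cuts)
        counts = levels.value_counts()
        assert set(counts) == {100}

    def test_boundary_rules(self):
        cuts = (1.0, 2.0)
        levels = assign_tertiles(np.array([1.0, 1.0 + 1e-9, 2.0, 2.0 + 1e-9]), cuts)
        assert list(levels) == [1, 2, 2, 3]

    def test_training_cutpoints_self_consistent(self, rng):
        v = pd.Series(rng.normal(size=101), index=[f"S{i}" for i in range(101)])
        cuts = tertile_cutpoints(v)
        levels = assign_tertiles(v, cuts)
        assert set(levels.unique()) == {1, 2, 3}
        # re-deriving cut-points from the same data reproduces the partition
        levels2 = assign_tertiles(v, tertile_cutpoints(v))
        pd.testing.assert_series_equal(levels, levels2)

    def test_invalid_cutpoints(self):
        with pytest.raises(ValueError):
            assign_tertiles(np.array([1.0]), (2.0, 2.0))
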