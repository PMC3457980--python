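import numpy as np
import pandas as pd
import pytest

from fetbead import (
    MultiscaleConfig,
    cluster_samples,
    filter_expressed,
    highlight_clusters,
    multiscale_bootstrap,
    quantile_normalize,
    sd_select,
    simulate_experiment,
)
from fetbead.clustering import _agglomerate, _correlation_distance
from fetbead.synthetic import SimulationConfig


def two_group_matrix(seed=0, n_probes=200, effect=3.0, noise=0.2):
    """Six samples in two well-separated groups of three."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1.5, n_probes)
    shift = np.where(np.arange(n_probes) < n_probes // 3, effect, 0.0)
    cols = {}
    for s in ("A1", "A2", "A3"):
        cols[s] = base + rng.normal(0, noise, n_probes)
    for s in ("B1", "B2", "B3"):
        cols[s] = base + shift + rng.normal(0, noise, n_probes)
    return pd.DataFrame(cols)


class TestSdSelect:
    def make(self):
        return pd.DataFrame(
            {"s1": [1.0, 1.0, 5.0], "s2": [1.0, 2.0, 10.0], "s3": [1.0, 3.0, 15.0]},
            index=["const", "mid", "wide"],
        )

    def test_constant_probe_removed(self):
        out = sd_select(self.make(), min_sd=1e-9)
        assert "const" not in out.index

    def test_top_k_all_is_identity(self):
        df = self.make()
        out = sd_select(df, top_k=3)
        assert out.equals(df)

    def test_direct_threshold(self):
        # SDs are 0, 1, 5; min_sd=2 keeps one probe -> error (need >= 2)
        df = self.make()
        sd = df.std(axis=1, ddof=1)
        assert np.allclose(sorted(sd), [0.0, 1.0, 5.0])
        kept = sd_select(df, min_sd=0.5)
        assert list(kept.index) == ["mid", "wide"]

    def test_all_constant_is_instructive_error(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError, match="lower the threshold"):
            sd_select(df, min_sd=0.1)

    def test_exactly_one_criterion(self):
        with pytest.raises(ValueError):
            sd_select(self.make(), min_sd=1.0, top_k=2)
        with pytest.raises(ValueError):
            sd_select(self.make())


class TestClusterSamples:
    def test_duplicated_columns_merge_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"dup1": x, "dup2": x, "other": rng.normal(0, 1, 50)})
        tree = cluster_samples(df)
        first_merge = min(tree.internal_nodes(), key=lambda n: n.height)
        assert first_merge.members == frozenset({"dup1", "dup2"})
        assert first_merge.height == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_separates_from_noise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 500)
        df = pd.DataFrame(
            {"A": x, "B": x + rng.normal(0, 0.1, 500), "C": rng.normal(0, 1, 500)}
        )
        tree = cluster_samples(df)
        assert tree.find({"A", "B"}) is not None

    def test_anticorrelated_pair_merges_last(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 0.05, 200)
        df = pd.DataFrame({"plus": x, "near": y, "minus": -x})
        D = _correlation_distance(df.to_numpy())
        assert D[0, 2] == pytest.approx(2.0, abs=0.1)
        tree = cluster_samples(df)
        first = min(tree.internal_nodes(), key=lambda n: n.height)
        assert first.members == frozenset({"plus", "near"})

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            cluster_samples(df)

    def test_deterministic_tie_break(self):
        # four equidistant points: the lexicographically smallest pair merges first
        D = np.ones((4, 4)) - np.eye(4)
        tree = _agglomerate(D, ["d", "c", "b", "a"])
        first = min(tree.internal_nodes(), key=lambda n: n.height)
        assert first.members == frozenset({"a", "b"})

    def test_tree_is_laminar_and_rooted_at_all_leaves(self):
        tree = cluster_samples(two_group_matrix())
        assert tree.is_laminar()
        assert tree.root.members == frozenset(
            {"A1", "A2", "A3", "B1", "B2", "B3"}
        )


@pytest.fixture(scope="module")
def supported_tree():
    df = two_group_matrix(seed=4)
    return multiscale_bootstrap(df, MultiscaleConfig(replicates=200, seed=9)), df


class TestMultiscaleBootstrap:

    def test_supports_in_unit_interval(self, supported_tree):
        tree, _ = supported_tree
        for node in tree.internal_nodes():
            assert 0.0 <= node.au <= 1.0
            assert 0.0 <= node.bp <= 1.0

    def test_true_split_strongly_supported(self, supported_tree):
        tree, _ = supported_tree
        split = tree.find({"A1", "A2", "A3"})
        assert split is not None
        assert split.au >= 0.95

    def test_bp_close_to_raw_appearance_fraction_at_scale_one(self, supported_tree):
        tree, _ = supported_tree
        for node in tree.internal_nodes():
            count, total = node.bp_table[1.0]
            raw = count / total
            se = np.sqrt(max(raw * (1 - raw), 1e-12) / total)
            assert abs(node.bp - raw) <= max(3 * se, 0.02)

    def test_replicate_trees_always_laminar(self):
        from fetbead.clustering import _replicate_clusters

        df = two_group_matrix(seed=5, n_probes=60)
        X = df.to_numpy()
        rng = np.random.default_rng(0)
        labels = list(df.columns)
        for _ in range(50):
            idx = rng.integers(0, X.shape[0], X.shape[0])
            clusters = _replicate_clusters(X[idx], labels)
            sets = list(clusters)
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    a, b = sets[i], sets[j]
                    assert not (a & b) or a <= b or b <= a

    def test_invariant_to_sample_order(self):
        df = two_group_matrix(seed=6)
        cfg = MultiscaleConfig(replicates=100, seed=3)
        tree1 = multiscale_bootstrap(df, cfg)
        tree2 = multiscale_bootstrap(df[list(df.columns)[::-1]], cfg)
        for node in tree1.internal_nodes():
            twin = tree2.find(node.members)
            assert twin is not None
            assert twin.au == pytest.approx(node.au, abs=1e-12)
            assert twin.bp == pytest.approx(node.bp, abs=1e-12)

    def test_scales_must_include_one(self):
        with pytest.raises(ValueError, match="1.0"):
            MultiscaleConfig(scales=(0.5, 0.8))


class TestHighlight:
    def test_threshold_selection(self):
        df = two_group_matrix(seed=7)
        tree = multiscale_bootstrap(df, MultiscaleConfig(replicates=100, seed=2))
        strong = highlight_clusters(tree, au_threshold=0.95)
        assert tree.root not in strong
        for node in strong:
            assert node.au > 0.95
        none = highlight_clusters(tree, au_threshold=1.1)
        assert none == []


class TestPipelineTopology:
    def test_ews_joins_outside_fus_taf15_cluster(self):
        """High FUS-TAF15 effect sharing with independent EWS effects puts the
        siEWS array outside the cluster containing siFUS and siTAF15."""
        successes = 0
        for seed in range(10):
            config = SimulationConfig(
                n_probes=3000, n_negative_controls=300,
                frac_shared_fus_taf15=0.8, frac_shared_all=0.0,
                frac_triple_unique=0.5, seed=seed,
            )
            table, _ = simulate_experiment(config)
            normalized = quantile_normalize(table.regular_signal())
            matrix, _ = filter_expressed(table, matrix=normalized)
            selected = sd_select(np.log2(matrix.data + 1.0), top_k=300)
            tree = cluster_samples(selected)
            node = tree.smallest_containing(["siFUS", "siTAF15"])
            successes += "siEWS" not in node.members
        assert successes >= 9
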