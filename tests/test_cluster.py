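"""Performance-vector clustering: Ward oracle, partitions, CWPACs, exports."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from swathbench import (
    PrecisionAssessment,
    ValidationError,
    cut_partitions,
    euclidean_distance,
    heatmap_frame,
    identify_cwpacs,
    method_contribution,
    performance_matrix,
    to_newick,
    ward_cluster,
)


def _assessments(pmads: dict[str, list], datasets=None):
    datasets = datasets or [f"d{i + 1}" for i in range(len(next(iter(pmads.values()))))]
    out = []
    for chain, values in pmads.items():
        for d, v in zip(datasets, values):
            out.append(
                PrecisionAssessment(
                    chain_label=chain, dataset_id=d, pmad=v,
                    failure_stage=None if v is not None else "normalization",
                    failure_class=None if v is not None else "degenerate-scale",
                )
            )
    return out


def ward_oracle(X):
    """Exhaustive agglomeration: at each step merge the pair of clusters
    whose union minimally increases total within-cluster variance (sum of
    squared deviations from the cluster mean); ties by smallest indices.
    Returns the member sets merged at each step and the Ward distances."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    merges, heights = [], []

    def sse(members):
        pts = X[members]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                inc = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
                if best is None or inc < best[0] - 1e-12:
                    best = (inc, a, b)
        inc, a, b = best
        merges.append(frozenset(clusters[a]) | frozenset(clusters[b]))
        heights.append(np.sqrt(2.0 * inc))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges, heights


def linkage_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges


class TestPerformanceMatrix:
    def test_incomplete_chains_filtered_and_listed(self):
        assessments = _assessments(
            {
                "LOG-MED-NON": [0.1, 0.2],
                "LOG-QUA-NON": [0.3, 0.4],
                "NON-MAD-NON": [None, 0.5],
                "NON-ZSC-NON": [0.6, None],
                "LOG-TIC-ZER": [0.2, 0.1],
                "CUB-TIC-ZER": [0.15, 0.25],
                "POW-TIC-ZER": [0.18, 0.28],
                "BOX-TIC-ZER": [0.19, 0.29],
            }
        )
        matrix, excluded = performance_matrix(assessments)
        assert matrix.shape == (6, 2)
        assert sorted(excluded["chain"]) == ["NON-MAD-NON", "NON-ZSC-NON"]
        assert set(excluded["failure_stages"]) == {"normalization"}
        # conservation: included + excluded = enumerated
        assert len(matrix) + len(excluded) == 8

    def test_single_dataset_rejected(self):
        with pytest.raises(ValidationError):
            performance_matrix(_assessments({"A-A-A": [0.1], "B-B-B": [0.2]}))


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == 5.0

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 7))
            expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            euclidean_distance([1.0], [1.0, 2.0])


class TestWardLinkage:
    def test_one_dimensional_forced_merge_order(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z = sch.linkage(X, method="ward")
        merges = linkage_merge_sets(Z, 3)
        assert merges[0] == frozenset({0, 1})

    def test_two_tight_triads_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(100, 0.1, (3, 2))])
        matrix = pd.DataFrame(np.exp(X), index=[f"c{i}" for i in range(6)],
                              columns=["d1", "d2"])
        Z = ward_cluster(matrix, distance_space="log10")
        parts = cut_partitions(Z, matrix, k=2)
        groups = {tuple(sorted(parts.members(p))) for p in parts.partition_names}
        assert groups == {("c0", "c1", "c2"), ("c3", "c4", "c5")}

    @pytest.mark.parametrize("n,dim,seed", [(8, 3, 0), (10, 7, 1), (12, 7, 2)])
    def test_merge_sequence_matches_exhaustive_oracle(self, n, dim, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, dim))
        Z = sch.linkage(X, method="ward")
        got = linkage_merge_sets(Z, n)
        want, heights = ward_oracle(X)
        assert got == want
        np.testing.assert_allclose(Z[:, 2], heights, rtol=1e-9)

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(np.abs(rng.normal(size=(30, 4))) + 0.01)
        matrix.index = [f"c{i}" for i in range(30)]
        Z = ward_cluster(matrix)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_invariant_to_input_order_up_to_relabeling(self):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(size=(12, 3))) + 0.01
        matrix = pd.DataFrame(vals, index=[f"c{i}" for i in range(12)])
        perm = rng.permutation(12)
        permuted = matrix.iloc[perm]
        p1 = cut_partitions(ward_cluster(matrix), matrix, k=3)
        p2 = cut_partitions(ward_cluster(permuted), permuted, k=3)
        sets1 = {frozenset(p1.members(name)) for name in p1.partition_names}
        sets2 = {frozenset(p2.members(name)) for name in p2.partition_names}
        assert sets1 == sets2


class TestPartitions:
    @staticmethod
    def _matrix():
        rng = np.random.default_rng(5)
        blocks = [10.0 ** rng.uniform(lo, hi, size=(4, 3))
                  for lo, hi in [(-6, -5), (-3, -2), (-1, 0), (1, 2), (3, 4), (5, 6)]]
        vals = np.vstack(blocks)
        return pd.DataFrame(vals, index=[f"c{i:02d}" for i in range(24)],
                            columns=["d1", "d2", "d3"])

    def test_k_equals_n_gives_singletons(self):
        matrix = self._matrix()
        Z = ward_cluster(matrix)
        parts = cut_partitions(Z, matrix, k=len(matrix))
        assert sorted(parts.sizes.values()) == [1] * len(matrix)

    def test_default_six_partitions_named_best_to_worst(self):
        matrix = self._matrix()
        parts = cut_partitions(ward_cluster(matrix), matrix, k=6)
        assert parts.partition_names == ["A1", "A2", "A3", "B", "C", "D"]
        means = [parts.mean_log10_pmad[p] for p in parts.partition_names]
        assert means == sorted(means)
        # the block with the lowest PMADs lands in A1
        assert set(parts.members("A1")) == {f"c{i:02d}" for i in range(4)}
        # conservation of membership
        assert sum(parts.sizes.values()) == len(matrix)

    def test_invalid_k_rejected(self):
        matrix = self._matrix()
        Z = ward_cluster(matrix)
        for bad in (1, len(matrix) + 1):
            with pytest.raises(ValidationError):
                cut_partitions(Z, matrix, k=bad)


class TestCWPAC:
    def test_strict_flag_requires_cutoff_everywhere(self):
        matrix = pd.DataFrame(
            {"d1": [0.1, 0.2], "d2": [0.2, 0.9], "d3": [0.05, 0.1]},
            index=["GOOD-CHN-ONE", "MIXD-CHN-TWO"],
        )
        parts = cut_partitions(ward_cluster(matrix), matrix, k=2)
        flags = identify_cwpacs(parts, matrix).set_index("chain")
        assert bool(flags.loc["GOOD-CHN-ONE", "strict_cwpac"])
        assert not bool(flags.loc["MIXD-CHN-TWO", "strict_cwpac"])

    def test_partition_fraction_rule(self):
        # 10 chains x 2 datasets in one tight partition: 19/20 values pass
        # the cutoff -> 0.95 >= 0.9 -> partition-based CWPAC
        vals = np.full((10, 2), 0.2)
        vals[0, 0] = 5.0
        far = np.full((3, 2), 1e4)
        matrix = pd.DataFrame(
            np.vstack([vals, far]),
            index=[f"c{i:02d}" for i in range(13)],
            columns=["d1", "d2"],
        )
        parts = cut_partitions(ward_cluster(matrix), matrix, k=2)
        flags = identify_cwpacs(parts, matrix, partition_fraction=0.9)
        block = flags.set_index("chain").loc[[f"c{i:02d}" for i in range(10)]]
        assert block["partition_cwpac"].all()
        # the chain with one poor PMAD is partition-based but not strict
        assert not bool(block.loc["c00", "strict_cwpac"])


class TestContribution:
    def test_direct_counting(self):
        pct = method_contribution(["LOG-TIC-ZER", "LOG-MED-ZER"], "normalization")
        assert pct == {"MED": 50.0, "TIC": 50.0}
        assert method_contribution(["LOG-TIC-ZER", "LOG-MED-ZER"],
                                   "transformation") == {"LOG": 100.0}

    def test_single_chain_all_hundred(self):
        for cat in ("transformation", "normalization", "imputation"):
            assert list(method_contribution(["POW-TMM-ZER"], cat).values()) == [100.0]

    def test_percentages_sum_to_hundred_uniform_sampling(self):
        rng = np.random.default_rng(6)
        transforms = ["BOX", "CUB", "LOG", "POW", "NON"]
        chains = [f"{rng.choice(transforms)}-TIC-ZER" for _ in range(10_000)]
        pct = method_contribution(chains, "transformation")
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        for share in pct.values():
            assert share == pytest.approx(20.0, abs=2.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            method_contribution([], "imputation")


class TestExports:
    def test_heatmap_clamped_to_plus_minus_five(self):
        matrix = pd.DataFrame(
            {"d1": [1e-9, 1e9], "d2": [1e-2, 1e2]}, index=["low-chn-one", "hig-chn-two"]
        )
        hm = heatmap_frame(matrix)
        assert hm.loc["low-chn-one", "d1"] == -5.0
        assert hm.loc["hig-chn-two", "d1"] == 5.0
        assert hm.loc["low-chn-one", "d2"] == -2.0

    def test_newick_round_trips_all_labels(self):
        from skbio.tree import TreeNode
        import io

        rng = np.random.default_rng(7)
        matrix = pd.DataFrame(np.abs(rng.normal(size=(6, 3))) + 0.01,
                              index=[f"LOG-ME{i}-NON" for i in range(6)])
        Z = ward_cluster(matrix)
        nwk = to_newick(Z, list(matrix.index))
        tree = TreeNode.read(io.StringIO(nwk))
        tips = {t.name for t in tree.tips()}
        assert tips == set(matrix.index)
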