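"""Tests for the DETECT index, partition search and the Detect estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from detectdim.conditional_covariance import ccov_matrix
from detectdim.detect import (
    LABEL_MODERATE,
    LABEL_SIZABLE,
    LABEL_UNIDIMENSIONAL,
    Detect,
    UndefinedRatioError,
    all_partitions,
    canonical_labels,
    classify,
    detect_index,
    maximize_partition,
    ratio_index,
    run_detect,
)
from detectdim.simulate import SimulationCondition, simulate_responses


def four_item_ccov():
    """ccov(1,2)=0.01, ccov(3,4)=0.008, all cross pairs -0.005."""
    c = np.full((4, 4), np.nan)
    c[0, 1] = c[1, 0] = 0.01
    c[2, 3] = c[3, 2] = 0.008
    for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
        c[i, j] = c[j, i] = -0.005
    return c


def random_symmetric_ccov(rng, n, scale=0.01):
    c = rng.normal(0.0, scale, (n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, np.nan)
    return c


class TestDetectIndex:
    def test_hand_evaluation(self):
        # 100 * (2/12) * (0.01 + 0.008 + 4*0.005) = 0.63333
        d = detect_index(four_item_ccov(), [0, 0, 1, 1])
        assert d == pytest.approx(0.63333, abs=1e-4)

    def test_single_cluster_is_mean_pairwise(self, rng):
        c = random_symmetric_ccov(rng, 6)
        vals = c[np.triu_indices(6, k=1)]
        assert detect_index(c, np.zeros(6)) == pytest.approx(100 * vals.mean())

    def test_relabeling_invariance(self):
        c = four_item_ccov()
        assert detect_index(c, [0, 0, 1, 1]) == detect_index(c, [1, 1, 0, 0])

    def test_linear_in_ccov(self, rng):
        c = random_symmetric_ccov(rng, 5)
        labels = [0, 1, 0, 1, 2]
        assert detect_index(2 * c, labels) == pytest.approx(
            2 * detect_index(c, labels)
        )

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            detect_index(four_item_ccov(), [0, 0, 1])


class TestRatioIndex:
    def test_perfect_sign_agreement(self):
        assert ratio_index(four_item_ccov(), [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_hand_evaluation_with_flipped_pair(self):
        c = four_item_ccov()
        c[0, 2] = c[2, 0] = 0.005
        # (0.018 - 0.005 + 0.015) / 0.038 = 0.7368
        assert ratio_index(c, [0, 0, 1, 1]) == pytest.approx(0.7368, abs=1e-4)

    def test_sign_antisymmetry(self):
        """Negating every conditional covariance flips r = 1 to r = -1."""
        c = four_item_ccov()
        assert ratio_index(-c, [0, 0, 1, 1]) == pytest.approx(-1.0)

    def test_all_zero_undefined(self):
        c = np.zeros((3, 3))
        np.fill_diagonal(c, np.nan)
        with pytest.raises(UndefinedRatioError):
            ratio_index(c, [0, 1, 2])


class TestClassify:
    @pytest.mark.parametrize(
        "dstar, expected",
        [
            (0.05, LABEL_UNIDIMENSIONAL),
            (0.1, LABEL_MODERATE),
            (0.294, LABEL_MODERATE),
            (1.0, LABEL_MODERATE),
            (1.503, LABEL_SIZABLE),
        ],
    )
    def test_bands(self, dstar, expected):
        assert classify(dstar) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))


class TestAllPartitions:
    @pytest.mark.parametrize("n, bell", [(1, 1), (2, 2), (3, 5), (5, 52), (6, 203)])
    def test_bell_counts(self, n, bell):
        assert sum(1 for _ in all_partitions(n)) == bell

    def test_distinct_and_canonical(self):
        seen = {tuple(p) for p in all_partitions(4)}
        assert len(seen) == 15
        for p in all_partitions(4):
            assert np.array_equal(p, canonical_labels(p))


class TestMaximizePartition:
    def test_two_items_positive_covariance(self):
        c = np.array([[np.nan, 0.01], [0.01, np.nan]])
        labels = maximize_partition(c, method="exhaustive")
        assert labels[0] == labels[1]

    @pytest.mark.parametrize("method", ["exhaustive", "cluster-heuristic"])
    def test_planted_blocks_recovered(self, method, fixture_dir):
        out, manifest = fixture_dir
        c = np.loadtxt(out / "planted_blocks_ccov.csv", delimiter=",")
        truth = np.asarray(manifest["planted_blocks_ccov"]["true_blocks"])
        labels = maximize_partition(c, method=method)
        assert np.array_equal(canonical_labels(labels), canonical_labels(truth))

    def test_batched_and_streaming_exhaustive_agree(self, rng):
        from detectdim.detect import _exhaustive_batched

        for max_k in (3, 12):
            for _ in range(10):
                c = random_symmetric_ccov(rng, 6)
                batched = _exhaustive_batched(c, max_k)
                best, best_d = None, -np.inf
                for labels in all_partitions(6):
                    if labels.max() + 1 > max_k:
                        continue
                    d = detect_index(c, labels)
                    if d > best_d + 1e-12:
                        best, best_d = labels, d
                assert detect_index(c, batched) == pytest.approx(best_d, abs=1e-12)

    def test_dominance_over_true_partition(self, rng):
        """The maximizing partition's index is never below any fixed partition's."""
        for _ in range(20):
            c = random_symmetric_ccov(rng, 7)
            truth = rng.integers(0, 3, 7)
            best = maximize_partition(c, method="exhaustive")
            assert detect_index(c, best) >= detect_index(c, truth) - 1e-12

    def test_heuristic_never_beats_exhaustive_and_mostly_matches(self, rng):
        matches = 0
        n_trials = 50
        for _ in range(n_trials):
            c = random_symmetric_ccov(rng, 8)
            d_ex = detect_index(c, maximize_partition(c, method="exhaustive"))
            d_he = detect_index(c, maximize_partition(c, method="cluster-heuristic"))
            assert d_he <= d_ex + 1e-9
            if abs(d_he - d_ex) <= 1e-9:
                matches += 1
        assert matches >= 0.95 * n_trials

    def test_max_k_cap_respected(self, rng):
        c = random_symmetric_ccov(rng, 8)
        labels = maximize_partition(c, max_k=2, method="cluster-heuristic")
        assert labels.max() + 1 <= 2


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(4, 8))
def test_ratio_bound_and_relabel_invariance(seed, n):
    """|r| <= 1 for any partition, and both indices ignore label names."""
    rng = np.random.default_rng(seed)
    c = random_symmetric_ccov(rng, n)
    labels = rng.integers(0, 3, n)
    r = ratio_index(c, labels)
    assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
    perm = rng.permutation(3)
    relabeled = perm[labels]
    assert detect_index(c, relabeled) == pytest.approx(detect_index(c, labels))
    assert ratio_index(c, relabeled) == pytest.approx(r)


@pytest.fixture(scope="module")
def two_dim_data():
    cond = SimulationCondition(n_dims=2, rho=0.3, n_examinees=400)
    resp, _, _ = simulate_responses(cond, 404)
    return resp.scores


class TestDetectEstimator:
    def test_sklearn_protocol(self, two_dim_data):
        est = Detect(min_group=10)
        assert est.get_params()["min_group"] == 10
        est2 = clone(est).set_params(max_clusters=5)
        assert est2.get_params()["max_clusters"] == 5
        fitted = est.fit(two_dim_data)
        assert fitted is est
        assert est.labels_.shape == (40,)
        assert est.n_clusters_ == len(est.cluster_sizes_)
        assert est.classification_ == classify(est.detect_value_)
        assert sum(est.cluster_sizes_) + len(est.dropped_items_) == 40

    def test_deterministic_refit(self, two_dim_data):
        a = Detect().fit(two_dim_data)
        b = Detect().fit(two_dim_data)
        assert a.detect_value_ == b.detect_value_
        assert a.ratio_ == b.ratio_
        assert np.array_equal(a.labels_, b.labels_)

    def test_run_detect_matches_estimator(self, two_dim_data):
        res = run_detect(two_dim_data)
        est = Detect().fit(two_dim_data)
        assert res.dstar == est.detect_value_
        assert res.k == est.n_clusters_
        payload = res.to_dict()
        assert set(payload["clusters"]) == {str(c + 1) for c in range(res.k)}

    def test_degenerate_item_dropped_with_warning(self, rng):
        X = (rng.random((120, 8)) < 0.5).astype(int)
        X[:, 3] = 0
        with pytest.warns(UserWarning, match="zero-variance"):
            est = Detect(min_group=5).fit(X)
        assert est.labels_[3] == -1
        assert est.dropped_items_ == (3,)
        assert sum(est.cluster_sizes_) == 7

    def test_strong_two_cluster_structure_recovered(self):
        """Uncorrelated 2-dim data, high discrimination, N=1000: two clusters
        and near-simple structure in nearly every run."""
        from detectdim.simulate import (
            ItemBank,
            _direction_cosines,
            build_angle_design,
            generate_responses,
        )

        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(50_000 + seed)
            angles = build_angle_design(2, 40)
            mdisc = np.full(40, 2.0)
            bank = ItemBank(
                a=mdisc[:, None] * _direction_cosines(angles),
                beta=mdisc * rng.standard_normal(40),
                c=0.0,
                mdisc=mdisc,
                angles=angles,
            )
            X = generate_responses(bank, rng.standard_normal((1000, 2)), rng).scores
            est = Detect().fit(X)
            if est.n_clusters_ == 2 and est.ratio_ > 0.8:
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_unidimensional_below_two_dimensional(self):
        """1-factor data scores lower on D* than matched 2-dim (rho=0.3) data."""
        from detectdim.simulate import ItemBank, generate_responses

        cond = SimulationCondition(n_dims=2, rho=0.3, n_examinees=1000)
        two_dim = [
            Detect().fit(simulate_responses(cond, 60_000 + s)[0].scores).detect_value_
            for s in range(20)
        ]
        mean_two_dim = np.mean(two_dim)
        below = 0
        for s in range(20):
            rng = np.random.default_rng(70_000 + s)
            mdisc = rng.lognormal(0.0, 0.25, 40)
            bank = ItemBank(
                a=mdisc[:, None],
                beta=mdisc * rng.standard_normal(40),
                c=0.0,
                mdisc=mdisc,
                angles=np.zeros((40, 1)),
            )
            X = generate_responses(bank, rng.standard_normal((1000, 1)), rng).scores
            if Detect().fit(X).detect_value_ < mean_two_dim:
                below += 1
        assert below >= 19
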