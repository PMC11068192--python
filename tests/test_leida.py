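import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metastates import leida
from metastates.leida import (
    CentroidSet,
    LeadingEigenvectorStream,
    assign_to_centroids,
    build_eigenvector_stream,
    cluster_eigenvectors,
    fix_eigenvector_sign,
    group_difference_test,
    kuramoto_order,
    leading_eigenvector,
    occupancy,
    phase_coherence_at,
    subject_occupancies,
)
from metastates.signals import PhaseSeries


def _phase_series(arr, tr=2.0):
    return PhaseSeries(phases=np.asarray(arr, dtype=float), tr_seconds=tr)


class TestPhaseCoherence:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 1.0), (np.pi / 2, 0.0), (np.pi, -1.0)],
        ids=["aligned", "orthogonal", "antiphase"],
    )
    def test_worked_pairwise_values(self, delta, expected):
        phases = _phase_series([[0.3, 0.3], [0.3 - delta, 0.3]])
        m = phase_coherence_at(phases, 0)
        assert m[0, 1] == pytest.approx(expected, abs=1e-12)
        assert m[1, 0] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(np.diag(m), 1.0)

    def test_global_phase_shift_invariance(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(5, 1))
        shifted = np.angle(np.exp(1j * (theta + 1.234)))
        m0 = phase_coherence_at(_phase_series(theta), 0)
        m1 = phase_coherence_at(_phase_series(shifted), 0)
        assert np.allclose(m0, m1, atol=1e-12)

    def test_out_of_range_time_rejected(self):
        with pytest.raises(IndexError):
            phase_coherence_at(_phase_series([[0.0], [0.1]]), 1)


class TestLeadingEigenvector:
    def test_rank_one_matrix_recovers_direction(self, rng):
        v = rng.standard_normal(5)
        v /= np.linalg.norm(v)
        top = leading_eigenvector(np.outer(v, v))
        assert np.allclose(np.abs(top @ v), 1.0, atol=1e-10)

    def test_all_ones_matrix_gives_uniform_vector(self):
        top = leading_eigenvector(np.ones((4, 4)))
        assert np.allclose(np.abs(top), 0.5)
        # sign convention: an all-one-sign vector is flipped to negative
        assert np.all(top < 0)

    def test_matches_full_eigendecomposition_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 11))
            a = rng.standard_normal((n, n))
            a = (a + a.T) / 2
            top = leading_eigenvector(a)
            evals, evecs = np.linalg.eigh(a)  # independent full decomposition
            oracle = evecs[:, np.argmax(evals)]
            assert np.allclose(np.abs(top @ oracle), 1.0, atol=1e-8)
            assert np.linalg.norm(top) == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self, rng):
        a = np.eye(4)
        a[0, 1] = 1e-6
        with pytest.raises(ValueError, match="symmetric"):
            leading_eigenvector(a)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=12))
    def test_sign_convention_idempotent(self, vals):
        v = np.asarray(vals)
        once = fix_eigenvector_sign(v)
        twice = fix_eigenvector_sign(once)
        assert np.array_equal(once, twice)
        n_pos = np.sum(once > 0)
        assert 2 * n_pos <= v.size


class TestEigenvectorStream:
    def test_row_count_and_provenance(self, tiny_cohort):
        stream = build_eigenvector_stream(tiny_cohort)
        t = tiny_cohort.series[0].shape[1]
        assert stream.n_samples == tiny_cohort.n_subjects * t
        assert set(stream.group_of) == {"strong", "weak"}
        assert np.allclose(np.linalg.norm(stream.vectors, axis=1), 1.0)

    def test_rows_match_single_matrix_path(self, tiny_cohort):
        from metastates.signals import bandpass_filter, instantaneous_phase

        stream = build_eigenvector_stream(tiny_cohort)
        filt = bandpass_filter(tiny_cohort.series[0], tiny_cohort.tr_seconds)
        phases = instantaneous_phase(filt, tiny_cohort.tr_seconds)
        for t in (0, 7, 50):
            direct = leading_eigenvector(phase_coherence_at(phases, t))
            assert np.allclose(stream.vectors[t], direct, atol=1e-8)

    def test_sign_convention_holds_on_every_row(self, tiny_cohort):
        stream = build_eigenvector_stream(tiny_cohort)
        n = stream.n_nodes
        n_pos = np.sum(stream.vectors > 0, axis=1)
        assert np.all(2 * n_pos <= n)


def _two_direction_stream(rng, n=6, per=40):
    """Stream concentrated around two well-separated directions.

    Both directions are strictly negative so the sign convention leaves
    every noisy sample untouched.
    """
    base = np.vstack([
        -np.array([3.0, 1, 1, 1, 1, 1])[:n] / np.linalg.norm([3.0, 1, 1, 1, 1, 1][:n]),
        -np.array([1.0, 1, 1, 1, 1, 3])[:n] / np.linalg.norm([1.0, 1, 1, 1, 1, 3][:n]),
    ])
    rows, truth = [], []
    for i in range(2):
        for _ in range(per):
            v = base[i] + 0.05 * rng.standard_normal(n)
            v /= np.linalg.norm(v)
            rows.append(leida.fix_eigenvector_sign(v))
            truth.append(i)
    rows = np.asarray(rows)
    s = rows.shape[0]
    return (
        LeadingEigenvectorStream(
            vectors=rows,
            subject_of=np.zeros(s, dtype=int),
            time_of=np.arange(s),
            group_of=np.array(["g"] * s, dtype=object),
        ),
        np.asarray(truth),
    )


class TestClustering:
    def test_separates_two_orthogonal_directions(self, rng):
        stream, truth = _two_direction_stream(rng)
        _, labels = cluster_eigenvectors(stream, k=2, n_restarts=5, seed=0)
        agreement = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agreement == 1.0

    def test_k_equals_s_gives_zero_inertia(self, rng):
        stream, _ = _two_direction_stream(rng, per=5)
        centroids, labels = cluster_eigenvectors(stream, k=stream.n_samples, seed=0)
        assert len(set(labels.tolist())) == stream.n_samples
        d = stream.vectors - centroids.centroids[labels]
        assert np.allclose(d, 0, atol=1e-10)

    def test_deterministic_under_seed(self, rng):
        stream, _ = _two_direction_stream(rng)
        c1, l1 = cluster_eigenvectors(stream, k=3, seed=42)
        c2, l2 = cluster_eigenvectors(stream, k=3, seed=42)
        assert np.array_equal(l1, l2)
        assert np.array_equal(c1.centroids, c2.centroids)

    def test_k_bounds_enforced(self, rng):
        stream, _ = _two_direction_stream(rng, per=3)
        with pytest.raises(ValueError):
            cluster_eigenvectors(stream, k=1, seed=0)
        with pytest.raises(ValueError):
            cluster_eigenvectors(stream, k=stream.n_samples + 1, seed=0)


class TestAssignment:
    def test_centroids_assign_to_themselves(self, rng):
        c = CentroidSet(rng.standard_normal((4, 6)))
        labels = assign_to_centroids(c.centroids, c)
        assert np.array_equal(labels, np.arange(4))

    def test_equidistant_tie_breaks_low(self):
        c = CentroidSet(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        labels = assign_to_centroids(np.array([[0.0, 5.0]]), c)
        assert labels[0] == 0

    def test_self_consistent_with_training_labels(self, rng):
        stream, _ = _two_direction_stream(rng)
        centroids, labels = cluster_eigenvectors(stream, k=2, seed=1)
        reassigned = assign_to_centroids(stream, centroids)
        assert np.array_equal(labels, reassigned)

    def test_dimension_mismatch_rejected(self, rng):
        c = CentroidSet(rng.standard_normal((2, 5)))
        with pytest.raises(ValueError, match="dimension"):
            assign_to_centroids(rng.standard_normal((3, 4)), c)


class TestOccupancy:
    def test_half_half(self):
        pms = occupancy(np.array([0, 0, 1, 1]), np.array(["a"] * 4, dtype=object), 2)
        assert np.allclose(pms.probabilities["a"], [0.5, 0.5])
        assert np.array_equal(pms.counts["a"], [2, 2])

    def test_degenerate_all_in_one_cluster(self):
        pms = occupancy(np.zeros(10, dtype=int), np.array(["a"] * 10, dtype=object), 3)
        assert np.allclose(pms.probabilities["a"], [1, 0, 0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(5, 40), st.integers(0, 1000))
    def test_matches_tally_oracle_and_conserves_mass(self, k, s, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, k, size=s)
        groups = rng.choice(["x", "y"], size=s).astype(object)
        pms = occupancy(labels, groups, k)
        for g in pms.groups:
            expected = [np.sum((labels == i) & (groups == g)) for i in range(k)]
            assert np.array_equal(pms.counts[g], expected)
            assert pms.counts[g].sum() == np.sum(groups == g)
            assert pms.probabilities[g].sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_subject_fractions(self):
        labels = np.array([0, 0, 1, 1, 1, 0])
        subject_of = np.array([0, 0, 0, 1, 1, 1])
        group_of = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        table = subject_occupancies(labels, subject_of, group_of, 2)
        assert table.loc[0, "substate_1"] == pytest.approx(2 / 3)
        assert table.loc[1, "substate_2"] == pytest.approx(2 / 3)


class TestKuramoto:
    def test_identical_phases_fully_synchronized(self):
        phases = _phase_series(np.full((5, 10), 0.7))
        prof = kuramoto_order(phases)
        assert np.allclose(prof.r_t, 1.0)

    def test_evenly_spaced_phases_cancel(self):
        theta = np.array([0, np.pi / 2, np.pi, -np.pi / 2])[:, None] * np.ones((1, 3))
        prof = kuramoto_order(_phase_series(theta))
        assert np.allclose(prof.r_t, 0.0, atol=1e-12)

    def test_matches_phasor_sum_oracle(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(100, 20))
        prof = kuramoto_order(_phase_series(theta))
        oracle = np.abs(np.sum(np.exp(1j * theta), axis=0)) / 100
        assert np.allclose(prof.r_t, oracle, atol=1e-12)
        assert prof.mean_r < 0.3  # ~1/sqrt(100) scale for random phases


class TestGroupDifferenceTest:
    def test_identical_groups_are_null(self, rng):
        occ = rng.dirichlet(np.ones(3), size=6)
        p_raw, _ = group_difference_test(occ, occ.copy(), n_perm=200, seed=0)
        assert np.all(p_raw >= 0.5)

    def test_separated_groups_detected(self, rng):
        occ_a = np.column_stack([np.full(10, 0.9), np.full(10, 0.1)])
        occ_b = np.column_stack([np.full(10, 0.1), np.full(10, 0.9)])
        occ_a += rng.uniform(0, 0.01, occ_a.shape)
        occ_b += rng.uniform(0, 0.01, occ_b.shape)
        p_raw, p_fdr = group_difference_test(occ_a, occ_b, n_perm=1000, seed=1)
        assert np.all(p_raw <= 0.01)
        assert np.all(p_fdr <= 0.05)

    def test_minimum_attainable_p(self, rng):
        occ_a = np.column_stack([np.arange(10) / 100 + 0.9])
        occ_b = np.column_stack([np.arange(10) / 100])
        p_raw, _ = group_difference_test(occ_a, occ_b, n_perm=1000, seed=2)
        assert p_raw.min() >= 1 / 1001

    def test_rejects_bad_inputs(self, rng):
        occ = rng.dirichlet(np.ones(2), size=4)
        with pytest.raises(ValueError):
            group_difference_test(occ, occ, n_perm=0)
        with pytest.raises(ValueError):
            group_difference_test(occ[:1], occ, n_perm=10)
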