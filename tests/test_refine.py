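import numpy as np
import pytest

import chaosrefine as cr
from chaosrefine.refine import Subcluster
from conftest import make_series


def _subcluster(times, center=None, dim=2, cluster_id=0):
    times = np.asarray(times, dtype=int)
    center = np.zeros(dim) if center is None else np.asarray(center, dtype=float)
    return Subcluster(cluster_id, times, center, np.zeros((times.size, dim)))


class TestSelectNearest:
    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        portrait = cr.PhasePortrait(vectors=X, time_index=np.arange(10), order=3,
                                    method="derivative", source_name="t")
        center = rng.normal(size=3)
        model = cr.ClusterModel(centers=center[None, :], membership=np.ones((10, 1)),
                                fuzzifier=2.0, n_iter=1,
                                objective_trace=np.array([0.0]), seed=0)
        subs = cr.select_nearest(portrait, model, np.zeros(10, dtype=int), P=5)
        expected = np.argsort(np.linalg.norm(X - center, axis=1), kind="stable")[:5]
        np.testing.assert_array_equal(subs[0].member_time_indices, expected)
        np.testing.assert_array_equal(subs[0].member_vectors, X[expected])

    def test_small_cluster_returns_all_members(self):
        X = np.arange(6.0).reshape(3, 2)
        portrait = cr.PhasePortrait(vectors=X, time_index=np.arange(3), order=2,
                                    method="derivative", source_name="t")
        model = cr.ClusterModel(centers=np.zeros((2, 2)), membership=np.ones((3, 2)) / 2,
                                fuzzifier=2.0, n_iter=1,
                                objective_trace=np.array([0.0]), seed=0)
        subs = cr.select_nearest(portrait, model, np.zeros(3, dtype=int), P=5)
        assert subs[0].size == 3
        assert subs[1].size == 0  # empty cluster is an empty subcluster, not an error

    def test_distance_tie_broken_by_earlier_time(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        portrait = cr.PhasePortrait(vectors=X, time_index=np.arange(3), order=2,
                                    method="derivative", source_name="t")
        model = cr.ClusterModel(centers=np.zeros((1, 2)), membership=np.ones((3, 1)),
                                fuzzifier=2.0, n_iter=1,
                                objective_trace=np.array([0.0]), seed=0)
        subs = cr.select_nearest(portrait, model, np.zeros(3, dtype=int), P=2)
        np.testing.assert_array_equal(subs[0].member_time_indices, [0, 1])


class TestFilterTimeSeparated:
    def test_hand_traced_greedy_rule(self):
        # members in distance order at times 160, 50, 250, 10 with T=100:
        # 160 kept; 50 kept (gap 110); 250 dropped (gap 90 to 160);
        # 10 dropped (gap 40 to 50)
        out = cr.filter_time_separated(_subcluster([160, 50, 250, 10]), T=100)
        np.testing.assert_array_equal(out.member_time_indices, [160, 50])

    def test_single_member_retained(self):
        out = cr.filter_time_separated(_subcluster([42]), T=100)
        np.testing.assert_array_equal(out.member_time_indices, [42])

    def test_tight_window_keeps_exactly_one(self):
        out = cr.filter_time_separated(_subcluster([30, 10, 50, 70, 90]), T=100)
        assert out.size == 1

    def test_exact_gap_T_is_allowed(self):
        out = cr.filter_time_separated(_subcluster([0, 100, 200]), T=100)
        assert out.size == 3


class TestSelectSubclusters:
    def test_worked_example_sizes_3322(self):
        pool = [_subcluster(np.arange(r) * 300, cluster_id=i)
                for i, r in enumerate([3, 3, 2, 2])]
        chosen, met = cr.select_subclusters(pool, N=1000, T=100, seed=0)
        assert met
        total = sum(s.size for s in chosen) * 100
        assert total >= 1000
        # 3+3+2+2 = 10 members barely cover N, so every subcluster is needed
        assert len(chosen) == 4

    def test_single_small_pool_flags_shortfall(self):
        chosen, met = cr.select_subclusters([_subcluster([0, 500])], N=1000, T=100)
        assert not met and len(chosen) == 1

    def test_seeded_selection_is_reproducible(self):
        pool = [_subcluster([i * 7, i * 7 + 200], cluster_id=i) for i in range(12)]
        a, _ = cr.select_subclusters(pool, N=1000, T=100, seed=9)
        b, _ = cr.select_subclusters(pool, N=1000, T=100, seed=9)
        assert [s.cluster_id for s in a] == [s.cluster_id for s in b]

    def test_prefix_is_shortest_meeting_coverage(self):
        pool = [_subcluster([i * 7, i * 7 + 200], cluster_id=i) for i in range(12)]
        chosen, met = cr.select_subclusters(pool, N=1000, T=100, seed=9)
        assert met
        without_last = sum(s.size for s in chosen[:-1]) * 100
        assert without_last < 1000 <= without_last + chosen[-1].size * 100

    def test_members_past_tail_are_pruned(self):
        # 950 cannot start a 100-sample slice in a 1000-sample signal
        chosen, met = cr.select_subclusters([_subcluster([100, 950, 400])],
                                            N=1000, T=100)
        np.testing.assert_array_equal(chosen[0].member_time_indices, [100, 400])

    def test_empty_pool_raises_refinement_error(self):
        with pytest.raises(cr.RefinementError, match="select_subclusters"):
            cr.select_subclusters([_subcluster([5])], N=1000, T=100)


class TestExtractSubsequences:
    def test_worked_example_counts(self):
        sig = make_series(np.arange(1000.0))
        chosen = [_subcluster(np.arange(r) * 300 + i, cluster_id=i)
                  for i, r in enumerate([3, 3, 2, 2])]
        refined = cr.extract_subsequences(sig, chosen, T=100)
        assert refined.n_subsequences == 10
        assert refined.total_samples == 1000

    def test_substring_identity_and_time_shifts(self):
        rng = np.random.default_rng(2)
        sig = make_series(rng.normal(size=500))
        refined = cr.extract_subsequences(sig, [_subcluster([17, 300])], T=50)
        for sub in refined.subsequences:
            np.testing.assert_array_equal(
                sub.samples, sig.samples[sub.time_shift:sub.time_shift + 50])
        assert sorted(s.time_shift for s in refined.subsequences) == [17, 300]

    def test_out_of_range_slice_rejected(self):
        sig = make_series(np.arange(100.0))
        with pytest.raises(ValueError, match="overruns"):
            cr.extract_subsequences(sig, [_subcluster([80])], T=50)


class TestRefineSignal:
    def test_lorenz_end_to_end_invariants(self, lorenz_signal, lorenz_refined):
        r = lorenz_refined
        config = r.config
        assert r.coverage_met
        assert r.total_samples >= len(lorenz_signal)
        counts = r.counts_per_subcluster()
        assert all(c >= config.min_members for c in counts.values())
        by_sub = {}
        for s in r.subsequences:
            assert s.samples.size == config.time_separation
            np.testing.assert_array_equal(
                s.samples,
                lorenz_signal.samples[s.time_shift:s.time_shift + config.time_separation])
            by_sub.setdefault(s.subcluster_id, []).append(s.time_shift)
        for shifts in by_sub.values():
            shifts = sorted(shifts)
            assert all(b - a >= config.time_separation for a, b in zip(shifts, shifts[1:]))

    def test_subcluster_starts_share_similar_initial_conditions(self, lorenz_signal):
        """Within a subcluster, reconstructed start states are mutually close:
        all lie within the subcluster's nearest-to-center ball, so pairwise
        distances are bounded by twice its radius."""
        config = cr.RefineConfig(seed=1)
        portrait = cr.derivative_embed(lorenz_signal, config.order)
        r = cr.refine_signal(lorenz_signal, config)
        vec_at = {int(t): portrait.vectors[i] for i, t in enumerate(portrait.time_index)}
        by_sub = {}
        for s in r.subsequences:
            by_sub.setdefault(s.subcluster_id, []).append(vec_at[s.time_shift])
        for w, vecs in by_sub.items():
            center = r.subcluster_centers[w]
            radius = max(np.linalg.norm(v - center) for v in vecs)
            for i in range(len(vecs)):
                for j in range(i + 1, len(vecs)):
                    assert np.linalg.norm(vecs[i] - vecs[j]) <= 2 * radius + 1e-9

    def test_constant_signal_fails_cleanly(self):
        sig = make_series(np.ones(1000), dt=0.01)
        with pytest.raises(cr.RefinementError):
            cr.refine_signal(sig, cr.RefineConfig(seed=0))

    def test_bitwise_reproducibility(self, lorenz_signal):
        a = cr.refine_signal(lorenz_signal, cr.RefineConfig(seed=4))
        b = cr.refine_signal(lorenz_signal, cr.RefineConfig(seed=4))
        assert [s.time_shift for s in a.subsequences] == [s.time_shift for s in b.subsequences]
        assert [s.subcluster_id for s in a.subsequences] == [s.subcluster_id for s in b.subsequences]
        for x, y in zip(a.subsequences, b.subsequences):
            np.testing.assert_array_equal(x.samples, y.samples)
        np.testing.assert_array_equal(a.subcluster_centers, b.subcluster_centers)

    def test_step_counts_logged(self, lorenz_refined):
        sc = lorenz_refined.step_counts
        assert sc["n_vectors"] == 998 and sc["n_clusters"] == 20
        assert sc["n_subsequences"] == lorenz_refined.n_subsequences


class TestDivergenceRatio:
    def _refined(self, seqs_by_sub, T=100):
        subs = [cr.RefinedSubsequence(w, 0, np.asarray(s, dtype=float))
                for w, seqs in seqs_by_sub.items() for s in seqs]
        return cr.RefinedSet(source=make_series(np.zeros(T)), subsequences=subs,
                             subcluster_centers=np.zeros((len(seqs_by_sub), 3)),
                             config=cr.RefineConfig())

    def test_identical_subsequences_give_unit_ratio(self):
        s = np.sin(np.arange(100.0))
        per, med = cr.divergence_ratio(self._refined({0: [s, s]}))
        assert per[0] == 1.0 and med == 1.0

    def test_linearly_growing_gap_measured_against_hand_value(self):
        t = np.arange(100.0)
        a, b = np.zeros(100), t / 100.0  # gap grows linearly 0 -> 0.99
        per, _ = cr.divergence_ratio(self._refined({0: [a, b]}))
        assert per[0] == pytest.approx((99 / 100) / (9 / 100))

    def test_singleton_subcluster_skipped_with_warning(self):
        s = np.arange(100.0)
        with pytest.warns(UserWarning, match="skipped"):
            per, _ = cr.divergence_ratio(self._refined({0: [s, s + 1], 1: [s]}))
        assert list(per) == [0]

    def test_oscillator_gaps_stay_bounded(self, oscillator_signal):
        r = cr.refine_signal(oscillator_signal, cr.RefineConfig(order=2, seed=1))
        _, med = cr.divergence_ratio(r)
        assert 0.2 < med < 3.0

    def test_lorenz_diverges_more_than_oscillator(self, lorenz_refined,
                                                  oscillator_signal):
        r_osc = cr.refine_signal(oscillator_signal, cr.RefineConfig(order=2, seed=1))
        _, med_osc = cr.divergence_ratio(r_osc)
        _, med_lor = cr.divergence_ratio(lorenz_refined)
        assert med_lor > med_osc
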