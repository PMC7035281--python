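"""Transition density plots, rate estimation and occupancies."""

import numpy as np
import pytest

from conftest import fret_from_array
from leutkit.pipeline import idealize_traces
from leutkit.simulate import (TraceSimConfig, effective_rate_matrix,
                              simulate_traces, stationary_distribution)
from leutkit.smfret import (estimate_rates, idealize_skm, occupancy,
                            transition_density)


def idealized(values):
    fret = fret_from_array(values)
    return idealize_skm(fret), fret


class TestTransitionDensity:
    def test_single_transition_lands_in_its_bin(self):
        # one dwell at 0.41 (observed), one at 0.62
        vals = np.concatenate([np.full(20, 0.41), np.full(20, 0.62)])
        path, fret = idealized(vals)
        tdp = transition_density([path], [fret])
        assert tdp.total_transitions == 1
        i, j = np.nonzero(tdp.counts)
        assert tdp.edges[i[0]] == pytest.approx(0.40)
        assert tdp.edges[j[0]] == pytest.approx(0.60)

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        paths, frets = [], []
        n_trans = 0
        for _ in range(10):
            states = np.repeat(rng.integers(1, 4, 30),
                               rng.integers(3, 20, 30))
            path, fret = idealized(np.array([0.0, 0.47, 0.63, 0.79])[states])
            keep = [d for d in path.dwells]
            n_trans += sum(1 for a, b in zip(keep[:-1], keep[1:])
                           if a.state != 0 and b.state != 0)
            paths.append(path)
            frets.append(fret)
        tdp = transition_density(paths, frets)
        assert tdp.counts.sum() == tdp.total_transitions == n_trans

    def test_reversible_two_state_chain_gives_symmetric_density(self):
        """Detailed balance: counts of a<->b transitions match within
        Monte-Carlo error, so the TDP is symmetric across the diagonal."""
        q = np.zeros((4, 4))
        q[1, 3] = 1.0
        q[3, 1] = 1.0
        np.fill_diagonal(q, -q.sum(axis=1))
        cfg = TraceSimConfig(n_molecules=20, n_frames=4000, seed=17,
                             noise_sd=0.02, rate_matrix=q)
        traces, _ = simulate_traces(cfg)
        frets, paths = idealize_traces(traces)
        tdp = transition_density(paths, frets)
        asym = tdp.counts - tdp.counts.T
        denom = np.sqrt(tdp.counts + tdp.counts.T + 1.0)
        assert np.max(np.abs(asym) / denom) < 4.0
        assert tdp.total_transitions > 1000

    def test_empty_paths_give_empty_tdp(self):
        path, fret = idealized(np.full(50, 0.79))
        tdp = transition_density([path], [fret])
        assert tdp.total_transitions == 0
        assert tdp.transitions_per_second == 0.0


class TestRates:
    def test_alternating_ten_frame_dwells_give_four_per_second(self):
        vals = np.tile(np.repeat([0.47, 0.79], 10), 50)
        path, _ = idealized(vals)
        est = estimate_rates([path])
        assert est.k[1, 3] == pytest.approx(4.0, rel=0.02)
        assert est.k[3, 1] == pytest.approx(4.0, rel=0.03)

    def test_no_transitions_yields_zero_with_upper_bound_flag(self):
        path, _ = idealized(np.full(100, 0.79))
        est = estimate_rates([path])
        assert est.k[3, 1] == 0.0
        assert est.upper_bound_only[3]

    def test_unvisited_state_rates_are_flagged_undefined(self):
        path, _ = idealized(np.full(100, 0.79))
        est = estimate_rates([path])
        assert not est.defined[1, 2]
        assert np.isnan(est.k[1, 2])

    def test_estimator_error_shrinks_with_growing_data(self):
        """Estimation error of the dwell-time MLE shrinks with observation
        time at rates far below the frame rate (three sizes, fixed seeds,
        averaged over seeds)."""
        q = np.zeros((4, 4))
        q[1, 2] = 0.5
        q[2, 1] = 0.5
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_err = []
        for size_idx, n_frames in enumerate((500, 5000, 50000)):
            errs = []
            for seed in (1, 2, 3):
                cfg = TraceSimConfig(n_molecules=8, n_frames=n_frames,
                                     seed=100 * size_idx + seed,
                                     noise_sd=0.02, rate_matrix=q,
                                     start_state=1)
                traces, _ = simulate_traces(cfg)
                _, paths = idealize_traces(traces)
                est = estimate_rates(paths)
                errs.append(abs(est.k[1, 2] - 0.5))
                assert abs(est.k[1, 2] - 0.5) < 3 * est.se[1, 2] + 0.01
            mean_err.append(np.mean(errs))
        assert mean_err[2] < mean_err[0]

    def test_dead_time_correction_reduces_missed_event_bias(self):
        q = np.zeros((4, 4))
        q[1, 2] = 2.0
        q[2, 1] = 4.0
        np.fill_diagonal(q, -q.sum(axis=1))
        cfg = TraceSimConfig(n_molecules=10, n_frames=20000, seed=6,
                             noise_sd=0.02, rate_matrix=q, start_state=1)
        traces, _ = simulate_traces(cfg)
        _, paths = idealize_traces(traces)
        plain = estimate_rates(paths)
        corrected = estimate_rates(paths, dead_time=cfg.frame_period)
        assert abs(corrected.k[1, 2] - 2.0) < abs(plain.k[1, 2] - 2.0)
        assert abs(corrected.k[2, 1] - 4.0) < abs(plain.k[2, 1] - 4.0)


class TestOccupancy:
    def test_single_state_path(self):
        path, _ = idealized(np.full(100, 0.79))
        occ = occupancy([path])
        np.testing.assert_allclose(occ.mean, [0.0, 0.0, 1.0])

    def test_occupancies_sum_to_one_over_non_dark_frames(self):
        cfg = TraceSimConfig(n_molecules=5, n_frames=500, seed=3,
                             noise_sd=0.05)
        traces, _ = simulate_traces(cfg)
        _, paths = idealize_traces(traces)
        occ = occupancy(paths)
        assert np.allclose(occ.per_molecule.sum(axis=1), 1.0)

    def test_all_dark_input_raises(self):
        path, _ = idealized(np.zeros(50))
        with pytest.raises(ValueError, match="no non-dark"):
            occupancy([path])

    def test_stationary_occupancy_matches_generator_eigenvector(self):
        cfg = TraceSimConfig(n_molecules=40, n_frames=4000, seed=19,
                             noise_sd=0.04)
        traces, _ = simulate_traces(cfg)
        _, paths = idealize_traces(traces)
        occ = occupancy(paths)
        pi = stationary_distribution(effective_rate_matrix(cfg))
        pi_nz = pi[1:] / pi[1:].sum()
        for s in range(3):
            assert abs(occ.mean[s] - pi_nz[s]) < 3 * max(occ.se[s], 2e-3)
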