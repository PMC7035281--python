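"""Trace generator: observation model, photophysics and ligand coupling."""

import numpy as np
import pytest

from leutkit.simulate import (LigandCoupling, TraceSimConfig,
                              effective_rate_matrix, simulate_titration,
                              simulate_traces, stationary_distribution)
from leutkit.smfret import compute_fret, correct_bleed_through


def static_config(**kw) -> TraceSimConfig:
    base = dict(n_molecules=2, n_frames=100, noise_sd=0.0, bleach_rate=0.0,
                blink_rate=0.0, rate_matrix=np.zeros((4, 4)), start_state=3,
                seed=1)
    base.update(kw)
    return TraceSimConfig(**base)


class TestObservationModel:
    def test_static_noiseless_chain_recovers_state_mean(self):
        """A frozen chain in the top state yields E = 0.79 on every frame
        once bleed-through is inverted."""
        traces, _ = simulate_traces(static_config())
        for t in traces:
            fret = compute_fret(correct_bleed_through(t, 0.165))
            np.testing.assert_allclose(fret.efficiency, 0.79, atol=1e-12)

    def test_bleed_through_is_applied_on_top_of_true_acceptor(self):
        traces, _ = simulate_traces(static_config())
        t = traces[0]
        np.testing.assert_allclose(
            t.acceptor, 1000 * 0.79 + 0.165 * 1000 * 0.21, atol=1e-9)

    def test_seed_determinism_is_bitwise(self):
        cfg = TraceSimConfig(n_molecules=3, n_frames=200, seed=9,
                             bleach_rate=0.05, blink_rate=0.1)
        a, _ = simulate_traces(cfg)
        b, _ = simulate_traces(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.donor, y.donor)
            np.testing.assert_array_equal(x.acceptor, y.acceptor)

    def test_bleach_zeroes_signal_and_truth_is_consistent(self):
        cfg = TraceSimConfig(n_molecules=5, n_frames=400, seed=4,
                             bleach_rate=0.5, noise_sd=0.0)
        traces, truths = simulate_traces(cfg)
        bleached = [(t, g) for t, g in zip(traces, truths) if g.bleached]
        assert bleached, "expected at least one bleach at rate 0.5/s"
        for t, g in bleached:
            first_dark = int(np.ceil(g.bleach_time / cfg.frame_period))
            assert np.all(t.total[first_dark:] == 0)

    def test_rejects_invalid_configs(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TraceSimConfig(state_means=(0.0, 0.5, 0.5, 0.8))
        with pytest.raises(ValueError, match="exactly 0"):
            TraceSimConfig(state_means=(0.1, 0.5, 0.6, 0.8))
        with pytest.raises(ValueError, match="sum to zero"):
            TraceSimConfig(rate_matrix=np.ones((4, 4)))
        with pytest.raises(ValueError, match="total_intensity"):
            TraceSimConfig(total_intensity=0.0)


class TestLigandCoupling:
    def coupled(self, **kw) -> TraceSimConfig:
        base = dict(n_molecules=1, n_frames=100, seed=0,
                    ligand_coupling=LigandCoupling(k_on=4e5, k_off=2.04))
        base.update(kw)
        return TraceSimConfig(**base)

    def test_zero_concentration_zeroes_forward_rate(self):
        q = effective_rate_matrix(self.coupled(), 0.0)
        assert q[1, 2] == 0.0 and q[2, 1] == 2.04

    def test_midpoint_concentration_balances_the_coupled_pair(self):
        """At c = k_off/k_on the coupled pair occupies 50/50 at equilibrium."""
        c_mid = 2.04 / 4e5
        q = effective_rate_matrix(self.coupled(), c_mid)
        pi = stationary_distribution(q)
        assert pi[1] / (pi[1] + pi[2]) == pytest.approx(0.5, abs=1e-9)

    def test_saturating_ligand_fills_the_upper_coupled_state(self):
        q = effective_rate_matrix(self.coupled(), 1.0)   # 1 M, saturating
        pi = stationary_distribution(q)
        assert pi[1] < 1e-5
        assert pi[2] + pi[3] > 0.9999

    def test_occupancy_matches_analytic_stationary_distribution(self):
        """Long-run frame-state occupancy agrees with the generator's
        stationary eigenvector within 3 Monte-Carlo SE."""
        cfg = self.coupled(n_molecules=40, n_frames=10000, seed=21,
                           concentration=5.1e-6, noise_sd=0.0)
        _, truths = simulate_traces(cfg)
        per_mol = []
        for g in truths:
            fs = g.frame_states()
            per_mol.append(np.bincount(fs, minlength=4) / fs.size)
        per_mol = np.asarray(per_mol)
        mean = per_mol.mean(axis=0)
        se = per_mol.std(axis=0, ddof=1) / np.sqrt(per_mol.shape[0])
        pi = stationary_distribution(effective_rate_matrix(cfg))
        for s in range(1, 4):
            assert abs(mean[s] - pi[s]) < 3 * max(se[s], 1e-4)

    def test_titration_requires_coupling_and_concentrations(self):
        with pytest.raises(ValueError, match="ligand_coupling"):
            simulate_titration(TraceSimConfig(n_molecules=1), [1e-6])
        with pytest.raises(ValueError, match="empty"):
            simulate_titration(self.coupled(), [])

    def test_titration_per_concentration_seeds_are_deterministic(self):
        cfg = self.coupled(n_molecules=2, n_frames=50)
        a = simulate_titration(cfg, [1e-6, 1e-5])
        b = simulate_titration(cfg, [1e-6, 1e-5])
        for c in a:
            np.testing.assert_array_equal(a[c][0][0].donor, b[c][0][0].donor)
        # different concentrations use different sub-streams
        assert not np.array_equal(a[1e-6][0][0].donor, a[1e-5][0][0].donor)
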