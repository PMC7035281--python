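"""Bleach/blink detection and the five-criterion trace filter."""

import numpy as np
import pytest

from leutkit.simulate import TraceSimConfig, simulate_traces
from leutkit.smfret import (SelectionCriteria, detect_bleach_and_blinks,
                            select_traces)
from leutkit.traces import FluorescenceTrace


def total_trace(total, noise_sd=0.0, rng=None, e=0.6):
    """Build a donor/acceptor pair realizing a given total-intensity path."""
    total = np.asarray(total, float)
    if noise_sd > 0:
        total = total + rng.normal(0, noise_sd, total.size)
    donor = total * (1 - e)
    acceptor = total * e
    t = FluorescenceTrace(donor=donor, acceptor=acceptor)
    t.acceptor_is_corrected = True
    return t


class TestBleachDetection:
    def test_clean_single_step_is_located_exactly(self):
        t = total_trace([1000.0] * 500 + [0.0] * 500)
        rep = detect_bleach_and_blinks(t)
        assert rep.bleach_frame == 500
        assert rep.single_step
        assert rep.n_blinks == 0

    def test_two_step_staircase_fails_single_step(self):
        t = total_trace([1000.0] * 300 + [500.0] * 300 + [0.0] * 400)
        rep = detect_bleach_and_blinks(t)
        assert not rep.single_step

    def test_no_bleach_reports_none(self):
        rep = detect_bleach_and_blinks(total_trace([1000.0] * 100))
        assert rep.bleach_frame is None and not rep.single_step

    def test_blink_intervals_are_counted(self):
        path = [1000.0] * 200 + [0.0] * 10 + [1000.0] * 200 + [0.0] * 5 \
            + [1000.0] * 185 + [0.0] * 400
        rep = detect_bleach_and_blinks(total_trace(path))
        assert rep.bleach_frame == 600
        assert rep.n_blinks == 2

    def test_recovery_on_noisy_simulated_bleaches(self, rng):
        """Detected bleach within +/-2 frames of truth for >= 95% of traces
        at 5% intensity noise."""
        cfg = TraceSimConfig(n_molecules=200, n_frames=600, seed=13,
                             bleach_rate=0.2, noise_sd=0.05)
        traces, truths = simulate_traces(cfg)
        hits = n_bleached = 0
        for t, g in zip(traces, truths):
            # bleaches hugging either trace end are undetectable in principle
            if not g.bleached or not 1.0 < g.bleach_time < cfg.duration - 1.0:
                continue
            n_bleached += 1
            rep = detect_bleach_and_blinks(t)
            if rep.bleach_frame is None:
                continue
            if abs(rep.bleach_frame - g.bleach_time / cfg.frame_period) <= 2:
                hits += 1
        assert n_bleached > 100
        assert hits / n_bleached >= 0.95


class TestSelection:
    def make(self, kind, rng):
        """Hand-built traces with a planted pass/fail label per criterion."""
        n = 1000
        base = np.concatenate([np.full(700, 1000.0), np.zeros(300)])
        if kind == "good":
            total = base
        elif kind == "no_bleach":
            total = np.full(n, 1000.0)
        elif kind == "two_step":
            total = np.concatenate([np.full(350, 1000.0), np.full(350, 500.0),
                                    np.zeros(300)])
        elif kind == "noisy_background":
            total = base + np.where(np.arange(n) >= 700,
                                    rng.normal(0, 200, n), rng.normal(0, 5, n))
        elif kind == "many_blinks":
            total = base.copy()
            for start in (100, 200, 300, 400):   # four blink events
                total[start:start + 8] = 0.0
        elif kind == "low_fret":
            total = base
            return total_trace(total, e=0.05), kind
        return total_trace(total, noise_sd=2.0, rng=rng), kind

    def test_filter_matches_planted_labels(self, rng):
        kinds = ["good", "no_bleach", "two_step", "noisy_background",
                 "many_blinks", "low_fret"] * 5
        traces, labels = zip(*(self.make(k, rng) for k in kinds))
        accepted, report = select_traces(list(traces))
        expect_fail = {
            "no_bleach": "single_step_bleach",
            "two_step": "single_step_bleach",
            "noisy_background": "snr_background_ok",
            "many_blinks": "blinks_ok",
            "low_fret": "fret_frames_ok",
        }
        for (_, row), kind in zip(report.iterrows(), kinds):
            if kind == "good":
                assert row["accepted"], row
            else:
                assert not row["accepted"]
                assert not row[expect_fail[kind]], (kind, dict(row))
        assert len(accepted) == sum(1 for k in kinds if k == "good")

    def test_four_blinks_rejected_three_accepted(self, rng):
        """Criterion (iv) is 'fewer than four' donor blinking events."""
        def blinky(n_blinks):
            total = np.concatenate([np.full(700, 1000.0), np.zeros(300)])
            for i in range(n_blinks):
                total[100 + 60 * i:108 + 60 * i] = 0.0
            return total_trace(total, noise_sd=2.0, rng=rng)

        _, rep = select_traces([blinky(3), blinky(4)])
        assert rep["blinks_ok"].tolist() == [True, False]
        assert rep["accepted"].tolist() == [True, False]

    def test_low_fret_trace_fails_floor_criterion(self):
        t = total_trace(np.concatenate([np.full(700, 1000.0), np.zeros(300)]),
                        e=0.10)
        _, rep = select_traces([t])
        assert not rep["fret_frames_ok"].iloc[0]

    def test_custom_min_frames_threshold(self):
        t = total_trace(np.concatenate([np.full(200, 1000.0), np.zeros(100)]))
        _, strict = select_traces([t], SelectionCriteria(min_frames=300))
        _, loose = select_traces([t], SelectionCriteria(min_frames=100))
        assert not strict["fret_frames_ok"].iloc[0]
        assert loose["fret_frames_ok"].iloc[0]
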