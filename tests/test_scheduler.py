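"""Dynamic query scheduler: SMA and plateau conditions, mode dispatch, and
agreement with a from-scratch brute-force oracle on random traces."""

import math

import numpy as np
import pytest

from dynaquery import (
    LossHistory,
    LossTraceSpec,
    SchedulerConfig,
    condition_plateau,
    condition_sma,
    generate_loss_trace,
    should_query,
)

CFG = SchedulerConfig()


def brute_force_decision(losses, query_epochs, config=CFG):
    """Independent re-evaluation of both conditions with plain Python sums."""
    t = len(losses)
    sma = False
    if t >= config.sma_window:
        window = losses[t - config.sma_window :]
        sma = sum(window) / len(window) < config.sma_threshold
    last_q = query_epochs[-1]
    k = t - last_q
    plateau = False
    if k >= config.min_epochs_between_queries:
        seg = losses[last_q:t]
        r = math.ceil(config.recent_fraction * k)
        recent, preceding = seg[len(seg) - r :], seg[: len(seg) - r]
        if preceding:
            plateau = (sum(recent) / len(recent)) > config.plateau_ratio * (
                sum(preceding) / len(preceding)
            )
    if sma:
        return True, "sma_threshold"
    if plateau:
        return True, "plateau"
    return False, None


class TestConditionSMA:
    def test_below_threshold_fires(self):
        hist = LossHistory(per_epoch_loss=[0.5] * 10 + [5e-5] * 5)
        assert condition_sma(hist, CFG)

    def test_boundary_is_strict(self):
        hist = LossHistory(per_epoch_loss=[1e-4] * 5)
        assert not condition_sma(hist, CFG)

    def test_one_low_loss_does_not_fire(self):
        hist = LossHistory(per_epoch_loss=[0.9, 0.9, 0.9, 0.9, 1e-6])
        assert not condition_sma(hist, CFG)  # mean 0.72

    def test_short_history_is_false(self):
        assert not condition_sma(LossHistory(per_epoch_loss=[1e-6] * 4), CFG)


class TestConditionPlateau:
    def test_minimum_epoch_gate(self):
        hist = LossHistory(per_epoch_loss=[0.5] * 19)
        assert not condition_plateau(hist, CFG)

    def test_flat_trace_fires_at_twenty(self):
        hist = LossHistory(per_epoch_loss=[0.5] * 20)
        # mean(recent 5) = 0.5 > 0.5 * mean(preceding 15) = 0.25
        assert condition_plateau(hist, CFG)

    def test_strong_descent_does_not_fire(self):
        hist = LossHistory(per_epoch_loss=[0.5 * 0.5**t for t in range(20)])
        assert not condition_plateau(hist, CFG)

    def test_segments_scoped_to_epochs_since_query(self):
        # flat tail after a query; old low losses must not enter the window
        losses = [1e-6] * 10 + [0.4] * 20
        hist = LossHistory(per_epoch_loss=losses, query_epochs=[0, 10])
        assert condition_plateau(hist, CFG)


class TestShouldQuery:
    def test_dynamic_tag_priority(self):
        # flat-low trace satisfies both conditions; the SMA tag wins
        hist = LossHistory(per_epoch_loss=[5e-5] * 25)
        fire, tag = should_query(hist, 25, CFG)
        assert fire and tag == "sma_threshold"

    def test_dynamic_neither_condition(self):
        hist = LossHistory(per_epoch_loss=[0.5 * 0.5**t for t in range(10)])
        assert should_query(hist, 10, CFG) == (False, None)

    @pytest.mark.parametrize("q", [15, 25, 30, 50])
    def test_fixed_interval(self, q):
        cfg = SchedulerConfig(mode="fixed", fixed_interval=q)
        hist = LossHistory(per_epoch_loss=[0.5] * q)
        assert should_query(hist, q, cfg) == (True, "fixed")
        hist_short = LossHistory(per_epoch_loss=[0.5] * (q - 1))
        assert should_query(hist_short, q - 1, cfg) == (False, None)

    def test_random_timing_frequency(self):
        cfg = SchedulerConfig(mode="random_timing", fixed_interval=25)
        rng = np.random.default_rng(0)
        hist = LossHistory(per_epoch_loss=[0.5])
        fires = sum(should_query(hist, 1, cfg, rng)[0] for _ in range(5000))
        assert fires == pytest.approx(5000 / 25, rel=0.25)


class TestSchedulerOracleEquivalence:
    def test_brute_force_agreement_on_random_traces(self):
        """1000 randomized synthetic traces with random query placements:
        the implementation and the brute-force oracle agree at every epoch."""
        rng = np.random.default_rng(2024)
        patterns = ["exponential_decay", "plateau_after", "noisy_constant", "piecewise"]
        for trial in range(1000):
            spec = LossTraceSpec(
                pattern=patterns[trial % 4],
                length=int(rng.integers(5, 60)),
                noise_sd=float(rng.uniform(0, 0.1)),
                seed=int(rng.integers(0, 2**31)),
                decay=float(rng.uniform(0.5, 0.99)),
                plateau_epoch=int(rng.integers(1, 20)),
                constant_level=float(rng.uniform(0.0, 1.0)),
            )
            losses = generate_loss_trace(spec)
            # random strictly-increasing query epochs within the trace
            n_queries = int(rng.integers(0, 4))
            qs = sorted(rng.choice(np.arange(1, len(losses) + 1),
                                   size=min(n_queries, len(losses)), replace=False))
            query_epochs = [0] + [int(q) for q in qs]
            for t in range(1, len(losses) + 1):
                past_queries = [q for q in query_epochs if q <= t]
                hist = LossHistory(per_epoch_loss=losses[:t], query_epochs=past_queries)
                assert should_query(hist, t, CFG) == brute_force_decision(
                    losses[:t], past_queries
                ), f"disagreement at trial {trial}, epoch {t}"


class TestTraceGeneratorSchedulerInteraction:
    def test_plateau_fires_on_flat_tail(self):
        """Decay for 10 epochs then flat: with the query event at the plateau
        start, the plateau condition first fires exactly 20 epochs later."""
        losses = generate_loss_trace(LossTraceSpec("plateau_after", length=40, plateau_epoch=10))
        fire_epochs = [
            t
            for t in range(1, 41)
            if condition_plateau(
                LossHistory(per_epoch_loss=losses[:t], query_epochs=[0, 10] if t >= 10 else [0]),
                CFG,
            )
        ]
        assert fire_epochs[0] == 30

    def test_sma_fires_shortly_after_threshold_crossing(self):
        losses = generate_loss_trace(
            LossTraceSpec("exponential_decay", length=60, decay=0.8)
        )
        crossing = next(t for t, l in enumerate(losses, start=1) if l < 2e-5)
        fire = next(
            t
            for t in range(1, 61)
            if condition_sma(LossHistory(per_epoch_loss=losses[:t]), CFG)
        )
        assert fire <= crossing + 5
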