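"""Gating and spill-over compensation: round trips, invariances, crosstalk."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from dropmeth.gating import (
    DropletSet,
    SpilloverMatrix,
    compensate,
    estimate_spillover,
    gate_droplets,
)
from dropmeth.records import CountRecord, DegenerateDataError, ValidationError
from dropmeth.simulate import SimConfig, simulate_counts, simulate_fluorescence


def _two_channel_well(n, pos1, pos2, config, well="w"):
    recs = [
        CountRecord(well, "", "NPY", n, pos1),
        CountRecord(well, "", "WIF1", n, pos2),
    ]
    return recs, simulate_fluorescence(recs, config)


class TestSpilloverMatrix:
    @pytest.mark.parametrize(
        "matrix",
        [np.array([[1.0, 1.0], [0.0, 1.0]]),   # off-diagonal at 1
         np.array([[1.0, -0.1], [0.0, 1.0]]),  # negative bleed
         np.array([[0.9, 0.0], [0.0, 1.0]])],  # diagonal != 1
    )
    def test_invalid_matrices_rejected(self, matrix):
        with pytest.raises(ValidationError):
            SpilloverMatrix(matrix)

    def test_identity_compensation_is_noop(self):
        ds = DropletSet("w", np.array([[1.0, 2.0], [3.0, 4.0]]), ("a", "b"))
        out = compensate(ds, SpilloverMatrix.identity())
        np.testing.assert_allclose(out.amplitudes, ds.amplitudes)

    def test_compensation_is_linear(self):
        rng = np.random.default_rng(0)
        amps = rng.normal(2000, 300, size=(50, 2))
        spill = SpilloverMatrix.from_bleed(0.2, 0.1)
        a = compensate(DropletSet("w", amps, ("a", "b")), spill).amplitudes
        b = compensate(DropletSet("w", 3.0 * amps, ("a", "b")), spill).amplitudes
        np.testing.assert_allclose(3.0 * a, b, rtol=1e-12)

    def test_compensation_not_idempotent(self):
        amps = np.array([[100.0, 50.0], [80.0, 40.0]])
        spill = SpilloverMatrix.from_bleed(0.5, 0.0)
        once = compensate(DropletSet("w", amps, ("a", "b")), spill)
        twice = compensate(once, spill)
        assert not np.allclose(once.amplitudes, twice.amplitudes)


class TestGating:
    def test_manual_threshold_above_all_amplitudes(self):
        ds = DropletSet("w", np.full((10, 2), 100.0), ("a", "b"))
        res = gate_droplets(ds, thresholds=(200.0, 200.0))
        assert [c.n_positive for c in res.counts] == [0, 0]

    def test_droplet_exactly_at_threshold_is_negative(self):
        ds = DropletSet("w", np.array([[5.0, 1.0], [6.0, 1.0]]), ("a", "b"))
        res = gate_droplets(ds, thresholds=(5.0, 0.0))
        assert res.counts[0].n_positive == 1  # only the 6.0 droplet

    def test_roundtrip_recovers_truth_at_high_separation(self):
        cfg = SimConfig(seed=21, cluster_separation=10.0, n_droplets_per_well=10_000)
        recs, ds = _two_channel_well(10_000, 480, 1750, cfg)
        res = gate_droplets(ds, thresholds="auto")
        assert [c.n_positive for c in res.counts] == [480, 1750]

    def test_roundtrip_through_spillover_compensation(self):
        spill = SpilloverMatrix.from_bleed(0.2, 0.1)
        cfg = SimConfig(seed=22, cluster_separation=10.0, n_droplets_per_well=10_000,
                        spillover=spill)
        recs, ds = _two_channel_well(10_000, 480, 1750, cfg)
        res = gate_droplets(compensate(ds, spill), thresholds="auto")
        assert [c.n_positive for c in res.counts] == [480, 1750]

    def test_uncompensated_bleed_overcounts_target_channel(self):
        # 20% of channel-1 signal bleeding into channel 2, 1000 ch1 positives,
        # no true ch2 positives: fixed-threshold gating without compensation
        # must overcount channel 2
        spill = SpilloverMatrix.from_bleed(ch2_into_ch1=0.0, ch1_into_ch2=0.2)
        cfg = SimConfig(seed=23, cluster_separation=8.0, n_droplets_per_well=10_000,
                        spillover=spill)
        recs, ds = _two_channel_well(10_000, 1000, 0, cfg)
        midpoint = 2000 + 8.0 * 250 / 2
        naive = gate_droplets(ds, thresholds=(midpoint, midpoint))
        assert naive.counts[1].n_positive > 50
        fixed = gate_droplets(compensate(ds, spill), thresholds=(midpoint, midpoint))
        assert fixed.counts[1].n_positive <= 2

    def test_misclassification_matches_gaussian_tail_at_low_separation(self):
        # manual threshold midway between clusters 2 SD apart: each droplet
        # crosses with probability Phi(-1); compare the gated count to its
        # closed-form expectation within 3 binomial SE
        n, n_pos = 25_000, 5_000
        cfg = SimConfig(seed=24, cluster_separation=2.0, n_droplets_per_well=n)
        recs, ds = _two_channel_well(n, n_pos, 0, cfg)
        midpoint = 2000 + 2.0 * 250 / 2
        res = gate_droplets(ds, thresholds=(midpoint, midpoint))
        tail = norm.sf(1.0)
        expected = n_pos * (1 - tail) + (n - n_pos) * tail
        var = n_pos * tail * (1 - tail) + (n - n_pos) * tail * (1 - tail)
        assert abs(res.counts[0].n_positive - expected) < 3 * math.sqrt(var)

    def test_counts_invariant_to_droplet_order(self):
        rng = np.random.default_rng(3)
        amps = rng.normal(2000, 250, size=(500, 2))
        amps[:100] += 2000
        ds = DropletSet("w", amps, ("a", "b"))
        res1 = gate_droplets(ds, thresholds="auto")
        perm = rng.permutation(500)
        res2 = gate_droplets(DropletSet("w", amps[perm], ("a", "b")), thresholds="auto")
        assert [c.n_positive for c in res1.counts] == [c.n_positive for c in res2.counts]

    def test_counts_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        amps = rng.normal(2000, 250, size=(400, 2))
        amps[:80, 0] += 2500
        thr = 3250.0
        base = gate_droplets(DropletSet("w", amps, ("a", "b")), thresholds=(thr, 1e9))
        scaled = amps.copy()
        scaled[:, 0] = np.exp(scaled[:, 0] / 1000.0)  # strictly increasing
        res = gate_droplets(
            DropletSet("w", scaled, ("a", "b")), thresholds=(math.exp(thr / 1000.0), 1e9)
        )
        assert res.counts[0].n_positive == base.counts[0].n_positive

    def test_auto_mode_rejects_constant_channel(self):
        ds = DropletSet("w", np.column_stack([np.ones(50), np.arange(50.0)]), ("a", "b"))
        with pytest.raises(DegenerateDataError, match="no cluster structure"):
            gate_droplets(ds, thresholds="auto")

    def test_auto_mode_single_cluster_called_all_negative(self):
        rng = np.random.default_rng(5)
        amps = rng.normal(2000, 250, size=(2000, 2))
        res = gate_droplets(DropletSet("w", amps, ("a", "b")), thresholds="auto")
        assert [c.n_positive for c in res.counts] == [0, 0]


class TestSpilloverEstimation:
    def test_recovers_known_bleed_from_single_positive_well(self):
        spill = SpilloverMatrix.from_bleed(ch2_into_ch1=0.0, ch1_into_ch2=0.15)
        cfg = SimConfig(seed=31, cluster_separation=10.0, n_droplets_per_well=5_000,
                        spillover=spill)
        recs = [CountRecord("w", "", "NPY", 5_000, 800), CountRecord("w", "", "WIF1", 5_000, 0)]
        ds = simulate_fluorescence(recs, cfg)
        est = estimate_spillover([(ds, 0)])
        assert est.matrix[1, 0] == pytest.approx(0.15, abs=0.03)

    def test_no_controls_gives_identity(self):
        np.testing.assert_allclose(estimate_spillover([]).matrix, np.eye(2))
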