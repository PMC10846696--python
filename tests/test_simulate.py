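import math

import numpy as np
import pytest

from hyphamap.simulate import (GrowthParams, PRESET_NAMES, RasterizationParams,
                               condition_preset, count_crossings, rasterize,
                               realized_doubling_time, simulate)
from hyphamap.vectorize import binarize

from oracles import stroke_pixel_count

LN2 = math.log(2.0)


def _small(seed=0, **kw):
    base = dict(tip_speed=60.0, duration=8.0, frame_interval=1.0, seed=seed)
    base.update(kw)
    return GrowthParams(**base)


class TestSimulate:
    def test_tip_bookkeeping(self):
        net = simulate(_small(seed=1))
        n_branches = sum(1 for _, k in net.events if k == "branch")
        assert len(net.tip_birth) == net.params.initial_tips + n_branches
        last = net.per_frame.iloc[-1]
        n_fused = sum(1 for _, k in net.events if k == "anastomosis")
        assert last["A_true"] == len(net.tip_birth) - n_fused
        assert last["N_true"] == n_branches

    def test_determinism(self):
        a = simulate(_small(seed=5))
        b = simulate(_small(seed=5))
        assert np.array_equal(a.segments, b.segments)
        assert a.events == b.events
        assert a.per_frame.equals(b.per_frame)

    def test_seed_changes_network(self):
        a = simulate(_small(seed=5))
        b = simulate(_small(seed=6))
        assert a.segments.shape != b.segments.shape \
            or not np.array_equal(a.segments, b.segments)

    def test_lag_delays_growth(self):
        net = simulate(_small(seed=2, lag_time=3.0))
        assert net.per_frame.loc[net.per_frame["time_h"] <= 2.9,
                                 "L_true"].max() == 0.0
        assert net.per_frame["L_true"].iloc[-1] > 0.0

    def test_L_true_nondecreasing_and_matches_segments(self):
        net = simulate(_small(seed=3))
        L = net.per_frame["L_true"].to_numpy()
        assert (np.diff(L) >= 0).all()
        seg = net.segments_at(net.frame_times[-1])
        total = np.hypot(seg[:, 2] - seg[:, 0], seg[:, 3] - seg[:, 1]).sum()
        assert L[-1] == pytest.approx(total)

    def test_apex_growth_is_exponential(self):
        # pooled over seeds, log2 A vs t should be linear with slope ~1/tau
        tau = 2.0
        slopes = []
        for seed in range(6):
            net = simulate(_small(seed=seed, branch_rate=LN2 / tau,
                                  duration=12.0, lag_time=0.0))
            df = net.per_frame[net.per_frame["A_true"] >= 3]
            t = df["time_h"].to_numpy()
            y = np.log2(df["A_true"].to_numpy())
            slopes.append(np.polyfit(t, y, 1)[0])
        mean_tau = 1.0 / np.mean(slopes)
        assert abs(mean_tau - tau) / tau < 0.35

    def test_anastomosis_kills_tips(self):
        p = _small(seed=4, anastomosis_radius=8.0, duration=10.0,
                   tip_speed=40.0, branch_rate=LN2 / 1.2)
        net = simulate(p)
        fused = sum(1 for _, k in net.events if k == "anastomosis")
        assert fused > 0
        assert np.isfinite(net.tip_death).sum() == fused

    def test_radius_bounded_by_speed(self):
        net = simulate(_small(seed=7))
        t = net.frame_times[-1]
        assert net.radius_at(t) <= net.params.tip_speed \
            * (t - net.params.lag_time) + 1e-6

    def test_param_validation(self):
        with pytest.raises(ValueError):
            GrowthParams(tip_speed=-1.0)
        with pytest.raises(ValueError):
            GrowthParams(duration=0.0)
        with pytest.raises(ValueError):
            GrowthParams(initial_tips=0)


class TestPresets:
    def test_all_names_resolve(self):
        for name in PRESET_NAMES:
            p = condition_preset(name)
            assert p.branch_rate > 0

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown preset"):
            condition_preset("mars")

    def test_overrides_forwarded(self):
        p = condition_preset("standard", seed=9, duration=5.0)
        assert p.seed == 9 and p.duration == 5.0

    def test_branch_rate_orders_match_doubling_targets(self):
        rates = [condition_preset(n).branch_rate for n in
                 ("high_temp", "standard", "low_nutrient", "osmotic",
                  "intense_light", "low_temp")]
        assert rates == sorted(rates, reverse=True)


class TestRasterize:
    def test_pixel_count_oracle_single_segment(self):
        net = simulate(_small(seed=0, duration=0.5, frame_interval=0.5,
                              lag_time=0.0, branch_rate=0.0, initial_tips=1,
                              tip_speed=50.0, heading_sd=0.0))
        rp = RasterizationParams(hypha_width=3.0, image_extent=(128, 128),
                                 pixel_size=1.0)
        fr = rasterize(net, 0.5, rp)
        mask = binarize(fr, threshold=128, min_speckle_px=0)
        seg = net.segments_at(0.5)
        px = [(64 + s[1], 64 + s[0], 64 + s[3], 64 + s[2]) for s in seg]
        assert mask.sum() == stroke_pixel_count(px, (128, 128), width=3.0)

    def test_center_and_metadata(self):
        net = simulate(_small(seed=0, duration=1.0))
        fr = rasterize(net, 1.0, RasterizationParams(image_extent=(512, 512)))
        assert fr.center == (256, 256)
        assert fr.time == 1.0
        assert fr.image.dtype == np.uint8

    def test_extent_too_small_message(self):
        net = simulate(_small(seed=0, tip_speed=300.0, duration=8.0))
        with pytest.raises(ValueError, match="need at least"):
            rasterize(net, 8.0, RasterizationParams(image_extent=(64, 64)))

    def test_noise_seed_determinism(self):
        net = simulate(_small(seed=0, duration=1.0))
        rp = RasterizationParams(noise_sd=0.05, image_extent=(256, 256))
        a = rasterize(net, 1.0, rp, noise_seed=3)
        b = rasterize(net, 1.0, rp, noise_seed=3)
        c = rasterize(net, 1.0, rp, noise_seed=4)
        assert np.array_equal(a.image, b.image)
        assert not np.array_equal(a.image, c.image)

    def test_polarity(self):
        net = simulate(_small(seed=0, duration=1.0))
        rp = RasterizationParams(image_extent=(512, 512),
                                 polarity="light_hyphae")
        fr = rasterize(net, 1.0, rp)
        # strokes brighter than background
        assert fr.image.max() > 200 and fr.image.min() < 60

    def test_frame_beyond_duration(self):
        net = simulate(_small(seed=0, duration=1.0))
        with pytest.raises(ValueError):
            rasterize(net, 2.0, RasterizationParams())


class TestRealizedDoublingTime:
    def test_exact_exponential(self):
        t = np.linspace(0.0, 10.0, 101)
        c = 4.0 * 2.0 ** (t / 2.5)
        assert realized_doubling_time(t, c) == pytest.approx(2.5, rel=1e-9)

    def test_window_restriction(self):
        t = np.linspace(0.0, 12.0, 121)
        c = np.where(t < 4.0, 3.0, 3.0 * 2.0 ** ((t - 4.0) / 2.0))
        tau = realized_doubling_time(t, c, window=(4.0, 12.0))
        assert tau == pytest.approx(2.0, rel=1e-6)

    def test_too_few_doublings(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([4.0, 4.5, 5.0])
        with pytest.raises(ValueError, match="doubling"):
            realized_doubling_time(t, c)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="usable"):
            realized_doubling_time(np.array([1.0]), np.array([3.0]))


class TestCrossings:
    def test_two_crossing_segments(self):
        from hyphamap.simulate import GroundTruthNetwork
        segs = np.array([[-1.0, 0.0, 1.0, 0.0], [0.0, -1.0, 0.0, 1.0]])
        net = GroundTruthNetwork(
            params=_small(), segments=segs,
            seg_birth=np.zeros(2), seg_tip=np.arange(2),
            tip_birth=np.zeros(2), tip_death=np.full(2, np.inf))
        assert count_crossings(net, 0.0) == 1

    def test_crossings_grow_with_density(self):
        net = simulate(_small(seed=1, duration=10.0, branch_rate=LN2 / 1.5))
        assert count_crossings(net, 10.0) > count_crossings(net, 5.0)
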