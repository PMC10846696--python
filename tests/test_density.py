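import math

import numpy as np
import pytest

from hyphamap.density import (density_distribution, jenks_classify,
                              line_density)

from oracles import (jenks_best_cost, partition_cost, segment_circle_length,
                     segment_circle_length_exact)


class TestLineDensity:
    def test_no_segments_all_zero(self):
        dmap = line_density(np.empty((0, 4)), (200, 200))
        assert (dmap.values == 0).all()
        assert dmap.values.shape == (4, 4)

    def test_through_center_chord(self):
        r = 200.0
        segs = np.array([[225.0, 0.0, 225.0, 1000.0]])
        dmap = line_density(segs, (450, 1000), cell_size=50, search_radius=r)
        i = list(dmap.cell_rows).index(225.0)
        j = list(dmap.cell_cols).index(525.0)
        assert dmap.values[i, j] == pytest.approx(2.0 / (math.pi * r),
                                                  rel=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        segs = np.column_stack([rng.uniform(0, 200, size=(20, 4))])
        dmap = line_density(segs, (200, 200), cell_size=50, search_radius=200)
        for i, cr in enumerate(dmap.cell_rows):
            for j, cc in enumerate(dmap.cell_cols):
                total = sum(
                    segment_circle_length_exact(s[:2], s[2:], (cr, cc), 200)
                    for s in segs)
                expect = total / (math.pi * 200 ** 2)
                assert abs(dmap.values[i, j] - expect) < 1e-9

    def test_sampling_oracle_single_cell(self):
        rng = np.random.default_rng(3)
        seg = rng.uniform(0, 100, size=4)
        dmap = line_density(seg.reshape(1, 4), (100, 100), cell_size=100,
                            search_radius=40)
        approx = segment_circle_length(seg[:2], seg[2:], (50.0, 50.0), 40) \
            / (math.pi * 40 ** 2)
        assert dmap.values[0, 0] == pytest.approx(approx, abs=1e-5)

    def test_density_conservation_large_radius(self):
        rng = np.random.default_rng(2)
        segs = rng.uniform(20, 80, size=(10, 4))
        lengths = np.hypot(segs[:, 2] - segs[:, 0], segs[:, 3] - segs[:, 1])
        R = 1e4
        dmap = line_density(segs, (100, 100), cell_size=50, search_radius=R)
        for v in dmap.values.ravel():
            assert v * math.pi * R ** 2 == pytest.approx(lengths.sum(),
                                                         rel=1e-9)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            line_density(np.empty((0, 4)), (10, 10), cell_size=0)
        with pytest.raises(ValueError):
            line_density(np.empty((0, 4)), (10, 10), search_radius=-1)


class TestDensityDistribution:
    def _dmap(self, values):
        from hyphamap.density import DensityMap
        v = np.asarray(values, dtype=float)
        return DensityMap(values=v, cell_rows=np.arange(v.shape[0]),
                          cell_cols=np.arange(v.shape[1]), cell_size=1.0,
                          search_radius=1.0, source_shape=v.shape)

    def test_single_value_single_bin(self):
        df = density_distribution(self._dmap([[0.005, 0.005], [0.0, 0.005]]),
                                  bin_size=0.0024)
        occupied = df[df["count"] > 0]
        assert len(occupied) == 1
        assert (df["frequency"] * 0.0024).sum() == pytest.approx(1.0)
        assert df.attrs["envelope_cells"] == 3
        assert df.attrs["max_density"] == pytest.approx(0.005)

    def test_pdf_normalization_random(self):
        rng = np.random.default_rng(8)
        df = density_distribution(self._dmap(rng.uniform(0, 0.03, (6, 6))))
        assert (df["frequency"] * df.attrs["bin_size"]).sum() \
            == pytest.approx(1.0)

    def test_counts_match_direct_histogram(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 0.02, (5, 5))
        vals[vals < 0.004] = 0.0
        df = density_distribution(self._dmap(vals), bin_size=0.0024)
        sel = vals[vals > 0]
        for _, row in df.iterrows():
            expect = ((sel >= row["bin_left"])
                      & (sel < row["bin_right"])).sum()
            # top edge inclusion handled by np.histogram on the last bin
            if row.name == len(df) - 1:
                expect = ((sel >= row["bin_left"])
                          & (sel <= row["bin_right"])).sum()
            assert row["count"] == expect

    def test_all_zero_map_empty_distribution(self):
        df = density_distribution(self._dmap(np.zeros((3, 3))))
        assert len(df) == 0
        assert df.attrs["envelope_cells"] == 0


class TestJenks:
    def test_two_clear_clusters(self):
        jc = jenks_classify([1, 2, 3, 100, 101, 102], n_classes=2)
        assert jc.breaks[1] == 3          # upper edge of the first class
        assert jc.labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_k_equals_distinct_values(self):
        jc = jenks_classify([5.0, 1.0, 9.0], n_classes=3)
        assert jc.gvf == pytest.approx(1.0)
        assert len(set(jc.labels.tolist())) == 3

    def test_duplicate_reduction_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            jc = jenks_classify([1.0, 1.0, 2.0], n_classes=3)
        assert jc.n_classes == 2

    def test_matches_bruteforce_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            xs = rng.uniform(0, 1, size=int(rng.integers(5, 13)))
            k = int(rng.integers(2, 5))
            jc = jenks_classify(xs, k)
            assert partition_cost(xs, jc.labels) \
                == pytest.approx(jenks_best_cost(xs, k), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        xs = rng.uniform(0, 1, size=10)
        a = jenks_classify(xs, 3)
        perm = rng.permutation(10)
        b = jenks_classify(xs[perm], 3)
        assert np.allclose(a.breaks, b.breaks)
        assert np.array_equal(a.labels[perm], b.labels)

    def test_breaks_cover_data(self):
        rng = np.random.default_rng(2)
        xs = rng.uniform(-5, 5, size=40)
        jc = jenks_classify(xs, 5)
        assert jc.breaks[0] == xs.min() and jc.breaks[-1] == xs.max()
        assert (np.diff(jc.breaks) >= 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jenks_classify([], 2)
        with pytest.raises(ValueError):
            jenks_classify([1.0], 0)
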