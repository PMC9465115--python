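import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diadesign import (
    ScanArea,
    build_scheme,
    cycle_time,
    equal_density_bin_edges,
    equidistant_bin_edges,
    strip_boundary_im,
)

from conftest import lib_from_arrays


def flat_area(bottom, top):
    return ScanArea(bottom, bottom, top, top)


class TestBinEdges:
    def test_equal_density_eight_points_four_bins(self):
        lib = lib_from_arrays(np.arange(400, 408), [1.0] * 8, [2] * 8)
        edges = equal_density_bin_edges(lib, 4, (399, 408))
        counts, _ = np.histogram(lib.mz, bins=edges)
        assert list(counts) == [2, 2, 2, 2]
        assert edges[0] == 399 and edges[-1] == 408

    def test_single_bin_is_just_the_range(self):
        lib = lib_from_arrays([500, 600], [1.0] * 2, [2] * 2)
        assert list(equal_density_bin_edges(lib, 1, (300, 1200))) == [300, 1200]

    def test_uniform_sample_balanced_within_one(self):
        rng = np.random.default_rng(0)
        mz = rng.uniform(300, 1200, 1000)
        lib = lib_from_arrays(mz, [1.0] * 1000, [2] * 1000)
        edges = equal_density_bin_edges(lib, 24, (300, 1200))
        counts, _ = np.histogram(mz, bins=edges)
        assert counts.max() - counts.min() <= 1

    def test_fewer_records_than_bins(self):
        lib = lib_from_arrays([500], [1.0], [2])
        with pytest.raises(ValueError, match="fewer"):
            equal_density_bin_edges(lib, 4, (300, 1200))

    def test_tied_values_reported(self):
        lib = lib_from_arrays([500.0] * 20, [1.0] * 20, [2] * 20)
        with pytest.raises(ValueError, match="non-increasing"):
            equal_density_bin_edges(lib, 4, (300, 1200))

    @pytest.mark.parametrize(
        "mz_range,n_bins,expected",
        [
            ((400, 1000), 3, [400, 600, 800, 1000]),
            ((300, 1200), 1, [300, 1200]),
            ((0, 1), 4, [0, 0.25, 0.5, 0.75, 1]),
        ],
    )
    def test_equidistant(self, mz_range, n_bins, expected):
        assert np.allclose(equidistant_bin_edges(mz_range, n_bins), expected)

    def test_exchange_symmetry_uniform_library(self):
        # equal-density edges of a large uniform sample converge to the
        # equidistant edges
        rng = np.random.default_rng(1)
        n = 100_000
        lib = lib_from_arrays(rng.uniform(300, 1200, n), np.ones(n), np.full(n, 2))
        dens = equal_density_bin_edges(lib, 24, (300, 1200))
        equi = equidistant_bin_edges((300, 1200), 24)
        assert np.max(np.abs(dens - equi)) <= 2.0


class TestStripBoundary:
    def test_midline_of_rectangle(self):
        area = flat_area(0.8, 1.2)
        for mz in (400, 700, 1100):
            assert strip_boundary_im(area, 0.5, mz, (300, 1200)) == pytest.approx(1.0)

    def test_top_edge_midpoint(self):
        area = ScanArea(0.6, 0.8, 1.0, 1.4)
        assert strip_boundary_im(area, 1.0, 800, (400, 1200)) == pytest.approx(1.2)

    def test_quarter_height_at_left(self):
        area = ScanArea(0.6, 0.8, 1.0, 1.4)
        assert strip_boundary_im(area, 0.25, 400, (400, 1200)) == pytest.approx(0.7)

    @settings(deadline=None, derandomize=True)
    @given(
        frac=st.floats(0, 1),
        t=st.floats(0, 1),
    )
    def test_result_lies_between_edges(self, frac, t):
        area = ScanArea(0.65, 0.95, 1.05, 1.45)
        mz = 300 + t * 900
        bottom = strip_boundary_im(area, 0.0, mz, (300, 1200))
        top = strip_boundary_im(area, 1.0, mz, (300, 1200))
        val = strip_boundary_im(area, frac, mz, (300, 1200))
        assert bottom - 1e-12 <= val <= top + 1e-12


class TestBuildScheme:
    def test_twelve_scans_two_windows(self):
        edges = equidistant_bin_edges((300, 1200), 24)
        scheme = build_scheme(edges, flat_area(0.8, 1.2), 12, 2, (0.6, 1.5))
        assert scheme.n_scans == 12 and scheme.n_windows == 24
        for scan in scheme.scans:
            up, low = scan.windows
            assert up.im_low == pytest.approx(low.im_high)

    def test_single_strip_spans_full_im_range(self):
        edges = equidistant_bin_edges((300, 1200), 8)
        scheme = build_scheme(edges, flat_area(0.8, 1.2), 8, 1, (0.6, 1.5))
        for w in scheme.windows:
            assert (w.im_low, w.im_high) == (0.6, 1.5)

    def test_hand_derived_two_by_two(self):
        # diagonal assignment and flat midline, checked by hand
        edges = [400, 600, 800, 1000, 1200]
        scheme = build_scheme(edges, flat_area(0.7, 1.3), 2, 2, (0.6, 1.5))
        s1, s2 = scheme.scans
        assert (s1.windows[0].mz_start, s1.windows[0].mz_end) == (1000, 1200)
        assert (s1.windows[1].mz_start, s1.windows[1].mz_end) == (600, 800)
        assert (s2.windows[0].mz_start, s2.windows[0].mz_end) == (800, 1000)
        assert (s2.windows[1].mz_start, s2.windows[1].mz_end) == (400, 600)
        for scan in (s1, s2):
            assert scan.windows[0].im_low == pytest.approx(1.0)
            assert scan.windows[0].im_high == 1.5
            assert scan.windows[1].im_low == 0.6

    def test_bin_count_mismatch(self):
        with pytest.raises(ValueError, match="incompatible"):
            build_scheme([300, 750, 1200], flat_area(0.8, 1.2), 2, 2, (0.6, 1.5))

    @pytest.mark.parametrize("n_scans,k", [(8, 2), (12, 2), (25, 2), (6, 4), (24, 1)])
    def test_mz_tiling_and_extension(self, n_scans, k):
        rng = np.random.default_rng(n_scans)
        n = 2000
        lib = lib_from_arrays(
            np.sort(rng.uniform(300, 1200, n)), np.ones(n), np.full(n, 2)
        )
        for edges in (
            equidistant_bin_edges((300, 1200), n_scans * k),
            equal_density_bin_edges(lib, n_scans * k, (300, 1200)),
        ):
            scheme = build_scheme(edges, ScanArea(0.7, 1.0, 1.0, 1.4), n_scans, k, (0.6, 1.5))
            # m/z tiling: sorted windows reconstruct the range without gaps
            ws = sorted(scheme.windows, key=lambda w: w.mz_start)
            assert ws[0].mz_start == 300 and ws[-1].mz_end == 1200
            for a, b in zip(ws, ws[1:]):
                assert a.mz_end == pytest.approx(b.mz_start)
            # extension to the instrument IM limits
            assert max(w.im_high for w in scheme.windows) == 1.5
            assert min(w.im_low for w in scheme.windows) == 0.6

    def test_monotone_diagonal(self):
        edges = equidistant_bin_edges((300, 1200), 24)
        scheme = build_scheme(edges, ScanArea(0.7, 1.0, 1.0, 1.4), 12, 2, (0.6, 1.5))
        for strip in range(2):
            starts = [scan.windows[strip].mz_start for scan in scheme.scans]
            assert all(a > b for a, b in zip(starts, starts[1:]))

    def test_transition_clamped_with_warning(self):
        # scan area partially below the instrument IM range
        edges = equidistant_bin_edges((300, 1200), 4)
        with pytest.warns(UserWarning, match="clamped"):
            with pytest.raises(ValueError):  # clamping degenerates the bottom strip
                build_scheme(edges, ScanArea(0.3, 0.3, 0.55, 0.65), 2, 2, (0.6, 1.5))


class TestCycleTime:
    def test_printed_sixty_spd_value(self):
        edges = equidistant_bin_edges((300, 1200), 24)
        scheme = build_scheme(edges, flat_area(0.8, 1.2), 12, 2, (0.6, 1.5))
        assert round(cycle_time(scheme), 2) == 1.38

    def test_ms1_only(self):
        from diadesign import AcquisitionScheme

        scheme = AcquisitionScheme(scans=(), mz_range=(300, 1200), im_range=(0.6, 1.5))
        assert cycle_time(scheme) == pytest.approx(0.10615)

    def test_twentyfive_scans(self):
        edges = equidistant_bin_edges((300, 1200), 50)
        scheme = build_scheme(edges, flat_area(0.8, 1.2), 25, 2, (0.6, 1.5))
        assert cycle_time(scheme) == pytest.approx(2.7599)


class TestScanArea:
    def test_positive_height_required(self):
        with pytest.raises(ValueError):
            ScanArea(1.2, 0.8, 1.0, 1.2)

    def test_vector_round_trip(self):
        area = ScanArea(0.7, 0.9, 1.0, 1.3)
        assert ScanArea.from_vector(area.as_vector()) == area
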