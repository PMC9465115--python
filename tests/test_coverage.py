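import dataclasses

import numpy as np
import pytest

from diadesign import (
    AcquisitionScheme,
    DiaPasefScan,
    IsolationWindow,
    PrecursorRecord,
    ScanArea,
    build_scheme,
    coverage_report,
    covered_mask,
    equal_density_bin_edges,
    equidistant_bin_edges,
    is_covered,
    per_window_balance,
)
from diadesign.synthetic import generate_library, proteome_model

from conftest import lib_from_arrays


def one_window_scheme(mz_start, mz_end, im_low, im_high):
    w = IsolationWindow(mz_start=mz_start, mz_end=mz_end, im_low=im_low, im_high=im_high)
    return AcquisitionScheme(
        scans=(DiaPasefScan(index=1, windows=(w,)),),
        mz_range=(mz_start, mz_end),
        im_range=(im_low, im_high),
    )


def two_by_two_scheme():
    """Hand-checkable scheme: edges 400/600/800/1000/1200, flat midline at 1.0."""
    return build_scheme(
        [400, 600, 800, 1000, 1200], ScanArea(0.7, 0.7, 1.3, 1.3), 2, 2, (0.6, 1.5)
    )


class TestIsCovered:
    def test_full_plane_window(self):
        scheme = one_window_scheme(300, 1200, 0.6, 1.5)
        assert is_covered(PrecursorRecord(mz=700, im=1.0, charge=2), scheme)

    def test_below_mz_range(self):
        scheme = one_window_scheme(300, 1200, 0.6, 1.5)
        assert not is_covered(PrecursorRecord(mz=200, im=1.0, charge=2), scheme)

    @pytest.mark.parametrize(
        "mz,im,expected",
        [
            (1100, 1.2, True),   # high-m/z bin, upper strip
            (1100, 0.8, False),  # below that bin's strip
            (700, 0.8, True),    # low-m/z bin, lower strip
            (500, 1.2, False),   # above that bin's strip
            (1200, 1.5, True),   # method corner: last bin is closed
        ],
    )
    def test_hand_placed_points_against_two_by_two(self, mz, im, expected):
        scheme = two_by_two_scheme()
        assert is_covered(PrecursorRecord(mz=mz, im=im, charge=2), scheme) is expected

    def test_internal_mz_edge_belongs_to_upper_bin(self):
        scheme = two_by_two_scheme()
        # 800 is an internal edge: belongs to bin [800, 1000), upper strip
        assert is_covered(PrecursorRecord(mz=800, im=1.2, charge=2), scheme)
        assert not is_covered(PrecursorRecord(mz=800, im=0.8, charge=2), scheme)


class TestCoverageReport:
    def test_fully_inside_one_window(self):
        lib = lib_from_arrays([500, 600, 700], [1.0, 1.1, 0.9], [2, 2, 3])
        scheme = one_window_scheme(300, 1200, 0.6, 1.5)
        rep = coverage_report(lib, scheme)
        assert rep.covered_fraction == 1.0
        assert rep.per_window_counts == (3,)

    def test_fully_outside(self):
        # in-range coordinates that fall in no window of the 2x2 scheme
        lib = lib_from_arrays([500, 1100], [1.2, 0.8], [2, 2])
        rep = coverage_report(lib, two_by_two_scheme())
        assert rep.covered_fraction == 0.0
        assert sum(rep.uncovered_mz_histogram[0]) == 2
        assert sum(rep.uncovered_im_histogram[0]) == 2

    def test_per_charge_fractions(self):
        lib = lib_from_arrays([500, 500, 200], [1.0, 1.0, 1.0], [2, 3, 3])
        scheme = one_window_scheme(300, 1200, 0.6, 1.5)
        rep = coverage_report(lib, scheme)
        assert rep.per_charge_fraction == {2: 1.0, 3: 0.5}

    def test_empty_library_raises(self):
        from diadesign import SpectralLibrary

        with pytest.raises(ValueError):
            coverage_report(SpectralLibrary(()), one_window_scheme(300, 1200, 0.6, 1.5))

    def test_intensity_weighting(self):
        recs = [
            PrecursorRecord(mz=500, im=1.0, charge=2, intensity=9.0),
            PrecursorRecord(mz=200, im=1.0, charge=2, intensity=1.0),
        ]
        from diadesign import SpectralLibrary

        lib = SpectralLibrary.from_records(recs, deduplicate=False)
        rep = coverage_report(lib, one_window_scheme(300, 1200, 0.6, 1.5), intensity_weighted=True)
        assert rep.covered_fraction == 0.5
        assert rep.intensity_weighted_fraction == pytest.approx(0.9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_vectorized_equals_loop(self, seed):
        lib = generate_library(proteome_model(seed=seed), 1000)
        rng = np.random.default_rng(seed)
        area = ScanArea(
            rng.uniform(0.6, 0.9),
            rng.uniform(0.9, 1.2),
            rng.uniform(1.0, 1.2),
            rng.uniform(1.25, 1.5),
        )
        edges = equal_density_bin_edges(lib, 24, (300, 1200))
        scheme = build_scheme(edges, area, 12, 2, (0.6, 1.5))
        fast = covered_mask(lib, scheme)
        slow = np.array([is_covered(r, scheme) for r in lib])
        assert np.array_equal(fast, slow)
        rep = coverage_report(lib, scheme)
        assert rep.covered_fraction == pytest.approx(slow.mean())

    def test_report_fraction_equals_loop_on_two_by_two(self):
        lib = generate_library(proteome_model(seed=9), 500)
        scheme = two_by_two_scheme()
        inside = [r for r in lib if 400 <= r.mz <= 1200]
        from diadesign import SpectralLibrary

        pop = SpectralLibrary.from_records(inside, deduplicate=False)
        rep = coverage_report(pop, scheme)
        assert rep.covered_fraction == pytest.approx(
            np.mean([is_covered(r, scheme) for r in pop])
        )


class TestMonotonicity:
    def test_enlarging_im_interval_never_decreases_coverage(self):
        lib = generate_library(proteome_model(seed=4), 500)
        base = one_window_scheme(300, 1200, 0.9, 1.1)
        wider = one_window_scheme(300, 1200, 0.7, 1.3)
        assert covered_mask(lib, wider).sum() >= covered_mask(lib, base).sum()
        # element-wise: nothing covered before becomes uncovered
        assert np.all(covered_mask(lib, wider) >= covered_mask(lib, base))


class TestBalance:
    def test_max_over_mean(self):
        rep_equal = dataclasses.replace(
            coverage_report(
                lib_from_arrays([350, 450, 550, 650], [1.0] * 4, [2] * 4),
                one_window_scheme(300, 1200, 0.6, 1.5),
            ),
            per_window_counts=(2, 2, 2, 2),
        )
        assert per_window_balance(rep_equal)["max_over_mean"] == 1.0
        rep_skew = dataclasses.replace(rep_equal, per_window_counts=(0, 4))
        assert per_window_balance(rep_skew)["max_over_mean"] == 2.0

    def test_equal_density_beats_equidistant_spread(self):
        lib = generate_library(proteome_model(seed=8), 10_000)
        area = ScanArea(0.6, 0.6, 1.5, 1.5)
        dens_edges = equal_density_bin_edges(lib, 24, (300, 1200))
        equi_edges = equidistant_bin_edges((300, 1200), 24)
        # single-strip schemes cover every precursor, so per-window counts
        # reflect the binning alone
        dens = coverage_report(lib, build_scheme(dens_edges, area, 24, 1, (0.6, 1.5)))
        equi = coverage_report(lib, build_scheme(equi_edges, area, 24, 1, (0.6, 1.5)))
        dens_counts = np.array(dens.per_window_counts)
        equi_counts = np.array(equi.per_window_counts)
        assert dens_counts.max() - dens_counts.min() <= 1
        assert dens_counts.max() - dens_counts.min() < equi_counts.max() - equi_counts.min()
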