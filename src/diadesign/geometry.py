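"""dia-PASEF acquisition-scheme geometry.

A dia-PASEF method is a cycle of *n* TIMS ramps ("dia-PASEF scans").  During
one ramp, ions elute from high to low reduced mobility (1/K0) while the
quadrupole visits an ordered set of m/z isolation windows, jumping to the
next window at defined IM transition points.  With *k* IM windows per scan,
the cycle carries n*k two-dimensional isolation windows which together tile
the configured m/z range.

The window placement is parameterised by

* m/z bin edges -- either equidistant (fixed window width) or equal-density
  (empirical m/z quantiles of a reference library, so that every isolation
  window holds the same number of library precursors), and
* a trapezoidal *scan area* in the m/z-IM plane, given by four corner IM
  values (the lower and upper edge of the trapezoid, each linear in m/z).

Bins are assigned to scans diagonally: the first scan starts at the
highest-m/z bin and every subsequent scan's starting window is offset one
bin lower, following the natural correlation between m/z and mobility.
The top and bottom IM strips are extended to the instrument IM limits so
no in-range ion is lost above or below the trapezoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .library import SpectralLibrary

__all__ = [
    "ScanArea",
    "IsolationWindow",
    "DiaPasefScan",
    "AcquisitionScheme",
    "equal_density_bin_edges",
    "equidistant_bin_edges",
    "strip_boundary_im",
    "build_scheme",
    "cycle_time",
]

#: per-frame transfer overhead (s) on top of the 100 ms ramp; with one MS1
#: frame and 12 dia-PASEF scans this yields the printed 1.38 s cycle time.
DEFAULT_FRAME_OVERHEAD = 0.00615
DEFAULT_RAMP_TIME = 0.100


@dataclass(frozen=True)
class ScanArea:
    """Trapezoid in the m/z-IM plane: IM of the lower and upper edges
    evaluated at the method's mz_min (left) and mz_max (right)."""

    im_bottom_left: float
    im_bottom_right: float
    im_top_left: float
    im_top_right: float

    def __post_init__(self) -> None:
        if not (
            self.im_top_left > self.im_bottom_left
            and self.im_top_right > self.im_bottom_right
        ):
            raise ValueError("scan area must have positive height at both m/z ends")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.im_bottom_left, self.im_bottom_right, self.im_top_left, self.im_top_right]
        )

    @staticmethod
    def from_vector(v) -> "ScanArea":
        return ScanArea(float(v[0]), float(v[1]), float(v[2]), float(v[3]))


@dataclass(frozen=True)
class IsolationWindow:
    """One rectangular 2-D isolation window: the quadrupole transmits
    [mz_start, mz_end) while the TIMS elution is inside [im_low, im_high]."""

    mz_start: float
    mz_end: float
    im_low: float
    im_high: float

    def __post_init__(self) -> None:
        if not (self.mz_start < self.mz_end and self.im_low < self.im_high):
            raise ValueError(f"degenerate isolation window {self}")


@dataclass(frozen=True)
class DiaPasefScan:
    """One TIMS ramp: windows ordered from high IM to low IM, the quadrupole
    jumping once per internal IM boundary.  Within a scan m/z decreases from
    the first (high-IM) window to the last."""

    index: int
    windows: tuple[IsolationWindow, ...]

    def __post_init__(self) -> None:
        for upper, lower in zip(self.windows, self.windows[1:]):
            if not np.isclose(upper.im_low, lower.im_high):
                raise ValueError(
                    f"scan {self.index}: consecutive windows must share an IM boundary"
                )
            if not upper.mz_start > lower.mz_start:
                raise ValueError(f"scan {self.index}: m/z must decrease with decreasing IM")


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered dia-PASEF scans plus cycle timing parameters."""

    scans: tuple[DiaPasefScan, ...]
    mz_range: tuple[float, float]
    im_range: tuple[float, float]
    ms1_frames_per_cycle: int = 1
    ramp_time: float = DEFAULT_RAMP_TIME
    frame_overhead: float = DEFAULT_FRAME_OVERHEAD

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def windows(self) -> tuple[IsolationWindow, ...]:
        return tuple(w for s in self.scans for w in s.windows)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mz_start, mz_end, im_low, im_high) arrays aligned to `windows`."""
        ws = self.windows
        return (
            np.array([w.mz_start for w in ws]),
            np.array([w.mz_end for w in ws]),
            np.array([w.im_low for w in ws]),
            np.array([w.im_high for w in ws]),
        )


def equidistant_bin_edges(mz_range: tuple[float, float], n_bins: int) -> np.ndarray:
    """Arithmetic-progression m/z edges (fixed isolation width)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return np.linspace(mz_range[0], mz_range[1], n_bins + 1)


def equal_density_bin_edges(
    lib: SpectralLibrary, n_bins: int, mz_range: tuple[float, float]
) -> np.ndarray:
    """Empirical-quantile m/z edges so each bin holds an equal share of the
    library precursors (variable isolation widths).

    Interior edges are the i/n_bins quantiles of the precursor m/z values;
    the outer edges are pinned to ``mz_range``.  Per-bin counts differ by at
    most one in the absence of ties at the edges.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(lib) < n_bins:
        raise ValueError(f"library has {len(lib)} records, fewer than {n_bins} bins")
    mz = np.sort(lib.mz)
    probs = np.arange(1, n_bins) / n_bins
    interior = np.quantile(mz, probs)
    edges = np.concatenate([[mz_range[0]], interior, [mz_range[1]]])
    if not np.all(np.diff(edges) > 0):
        bad = np.where(np.diff(edges) <= 0)[0]
        raise ValueError(
            f"non-increasing equal-density edges at quantile indices {bad.tolist()}: "
            f"{edges[bad].tolist()} -- too many tied m/z values for {n_bins} bins"
        )
    return edges


def strip_boundary_im(
    area: ScanArea,
    strip_fraction: float,
    mz: float,
    mz_range: tuple[float, float],
) -> float:
    """IM of the scan-area line at relative height ``strip_fraction``
    (0 = bottom edge, 1 = top edge), evaluated at ``mz``.

    Both trapezoid edges are linear in m/z between their corner values; the
    requested line interpolates linearly between the two edges.
    """
    lo, hi = mz_range
    t = (mz - lo) / (hi - lo)
    bottom = area.im_bottom_left + t * (area.im_bottom_right - area.im_bottom_left)
    top = area.im_top_left + t * (area.im_top_right - area.im_top_left)
    return bottom + strip_fraction * (top - bottom)


def build_scheme(
    bin_edges,
    area: ScanArea,
    n_scans: int,
    windows_per_scan: int,
    im_range: tuple[float, float],
    *,
    ms1_frames_per_cycle: int = 1,
    ramp_time: float = DEFAULT_RAMP_TIME,
    frame_overhead: float = DEFAULT_FRAME_OVERHEAD,
    mz_overlap: float = 0.0,
) -> AcquisitionScheme:
    """Construct the acquisition scheme from m/z bin edges and a scan area.

    Bin-to-scan assignment is diagonal: with bins indexed 1..W from lowest
    m/z, scan j (1..n_scans) carries, in IM strip s (1 = top strip), the bin
    W - (s-1)*n_scans - (j-1).  Interior strip boundaries sit on the scan-area
    lines at fractions (windows_per_scan - s)/windows_per_scan, each evaluated
    at the mean m/z centre of the two bins adjacent to the boundary (the
    quadrupole jumps once per boundary, so a single IM value is required).
    The top strip is extended up to the instrument IM maximum and the bottom
    strip down to the IM minimum.
    """
    edges = np.asarray(bin_edges, dtype=float)
    W = len(edges) - 1
    k = windows_per_scan
    if W != n_scans * k:
        raise ValueError(f"{W} bins incompatible with {n_scans} scans x {k} windows")
    mz_range = (float(edges[0]), float(edges[-1]))
    im_lo, im_hi = im_range
    centers = 0.5 * (edges[:-1] + edges[1:])

    scans = []
    for j in range(1, n_scans + 1):
        # bin index per strip, 1-based; strip 1 = top (highest IM)
        bins = [W - (s - 1) * n_scans - (j - 1) for s in range(1, k + 1)]
        # IM boundaries of this scan's strips, from top (im_hi) downwards
        boundaries = [im_hi]
        for s in range(1, k):
            frac = (k - s) / k
            eval_mz = 0.5 * (centers[bins[s - 1] - 1] + centers[bins[s] - 1])
            b = strip_boundary_im(area, frac, eval_mz, mz_range)
            if b < im_lo or b > im_hi:
                warnings.warn(
                    f"scan {j}: transition IM {b:.4f} outside instrument range, clamped",
                    stacklevel=2,
                )
                b = float(np.clip(b, im_lo, im_hi))
            boundaries.append(float(b))
        boundaries.append(im_lo)
        windows = []
        for s, b in enumerate(bins, start=1):
            mz_start = float(edges[b - 1]) - (mz_overlap / 2 if b > 1 else 0.0)
            mz_end = float(edges[b]) + (mz_overlap / 2 if b < W else 0.0)
            windows.append(
                IsolationWindow(
                    mz_start=mz_start,
                    mz_end=mz_end,
                    im_low=boundaries[s],
                    im_high=boundaries[s - 1],
                )
            )
        scans.append(DiaPasefScan(index=j, windows=tuple(windows)))

    return AcquisitionScheme(
        scans=tuple(scans),
        mz_range=mz_range,
        im_range=(float(im_lo), float(im_hi)),
        ms1_frames_per_cycle=ms1_frames_per_cycle,
        ramp_time=ramp_time,
        frame_overhead=frame_overhead,
    )


def cycle_time(scheme: AcquisitionScheme) -> float:
    """Duration of one acquisition cycle in seconds:
    (n_scans + ms1_frames) * (ramp_time + frame_overhead)."""
    return (scheme.n_scans + scheme.ms1_frames_per_cycle) * (
        scheme.ramp_time + scheme.frame_overhead
    )
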