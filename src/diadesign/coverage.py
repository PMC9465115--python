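"""Coverage evaluation: which library precursors does a scheme acquire?

A precursor is *covered* when its (m/z, 1/K0) coordinate falls inside at
least one isolation window.  m/z intervals are half-open [start, end) except
the window reaching the method's upper m/z limit, which is closed, so every
precursor belongs to at most one window of a default (non-overlapping)
scheme; IM intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionScheme
from .library import PrecursorRecord, SpectralLibrary

__all__ = [
    "CoverageReport",
    "is_covered",
    "covered_mask",
    "coverage_report",
    "per_window_balance",
    "DEFAULT_CHARGES",
]

#: default coverage population: multiply charged precursors, 2+ to 4+
DEFAULT_CHARGES = (2, 3, 4)


def _window_mask(
    mz: np.ndarray,
    im: np.ndarray,
    scheme: AcquisitionScheme,
) -> np.ndarray:
    """Boolean matrix (n_precursors, n_windows) of containment."""
    mz_start, mz_end, im_low, im_high = scheme.window_arrays()
    mz_max = scheme.mz_range[1]
    mz = mz[:, None]
    im = im[:, None]
    in_mz = (mz >= mz_start) & ((mz < mz_end) | ((mz_end == mz_max) & (mz <= mz_end)))
    in_im = (im >= im_low) & (im <= im_high)
    return in_mz & in_im


def covered_mask(lib: SpectralLibrary, scheme: AcquisitionScheme) -> np.ndarray:
    """Vectorized per-precursor coverage (any window contains the point)."""
    if len(lib) == 0:
        return np.zeros(0, dtype=bool)
    return _window_mask(lib.mz, lib.im, scheme).any(axis=1)


def is_covered(p: PrecursorRecord, scheme: AcquisitionScheme) -> bool:
    """Scalar reference test: true iff some window satisfies
    mz_start <= mz < mz_end (closed at the method's upper m/z limit) and
    im_low <= im <= im_high."""
    mz_max = scheme.mz_range[1]
    for w in scheme.windows:
        in_mz = w.mz_start <= p.mz and (p.mz < w.mz_end or (w.mz_end == mz_max and p.mz <= w.mz_end))
        if in_mz and w.im_low <= p.im <= w.im_high:
            return True
    return False


@dataclass(frozen=True)
class CoverageReport:
    """Coverage diagnostics of one (library, scheme) pair."""

    n_precursors: int
    covered_fraction: float
    per_charge_fraction: dict
    per_window_counts: tuple
    uncovered_mz_histogram: tuple  # (counts, bin_edges)
    uncovered_im_histogram: tuple
    intensity_weighted_fraction: float | None = None

    def to_rows(self) -> list[dict]:
        """Flat rows for TSV export."""
        rows = [{"metric": "covered_fraction", "value": self.covered_fraction}]
        for c, f in sorted(self.per_charge_fraction.items()):
            rows.append({"metric": f"covered_fraction_charge_{c}", "value": f})
        for i, n in enumerate(self.per_window_counts):
            rows.append({"metric": f"window_{i + 1}_count", "value": n})
        return rows


def coverage_report(
    lib: SpectralLibrary,
    scheme: AcquisitionScheme,
    histogram_bins: int = 20,
    intensity_weighted: bool = False,
) -> CoverageReport:
    """Overall and per-charge covered fractions, per-window precursor counts
    and marginal histograms of the uncovered population."""
    if len(lib) == 0:
        raise ValueError("cannot evaluate coverage of an empty library")
    mz, im, charge = lib.mz, lib.im, lib.charge
    mask_matrix = _window_mask(mz, im, scheme)
    covered = mask_matrix.any(axis=1)

    per_charge = {
        int(c): float(covered[charge == c].mean()) for c in np.unique(charge)
    }
    # each covered precursor counted in the first window containing it
    # (unique by construction for non-overlapping schemes)
    first = np.argmax(mask_matrix, axis=1)
    counts = np.zeros(scheme.n_windows, dtype=int)
    np.add.at(counts, first[covered], 1)

    unc_mz, unc_im = mz[~covered], im[~covered]
    mz_hist = np.histogram(unc_mz, bins=histogram_bins, range=scheme.mz_range)
    im_hist = np.histogram(unc_im, bins=histogram_bins, range=scheme.im_range)

    weighted = None
    if intensity_weighted:
        w = lib.intensity
        weighted = float(w[covered].sum() / w.sum())

    return CoverageReport(
        n_precursors=len(lib),
        covered_fraction=float(covered.mean()),
        per_charge_fraction=per_charge,
        per_window_counts=tuple(int(c) for c in counts),
        uncovered_mz_histogram=(tuple(mz_hist[0].tolist()), tuple(mz_hist[1].tolist())),
        uncovered_im_histogram=(tuple(im_hist[0].tolist()), tuple(im_hist[1].tolist())),
        intensity_weighted_fraction=weighted,
    )


def per_window_balance(report: CoverageReport) -> dict:
    """Min, max, mean and max/mean ratio of the per-window precursor counts."""
    counts = np.asarray(report.per_window_counts, dtype=float)
    mean = counts.mean()
    return {
        "min": float(counts.min()),
        "max": float(counts.max()),
        "mean": float(mean),
        "max_over_mean": float(counts.max() / mean) if mean > 0 else float("inf"),
    }
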