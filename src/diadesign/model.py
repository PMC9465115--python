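"""High-level Model/Results interface for dia-PASEF window design.

:class:`DiaWindowDesigner` is constructed from a spectral library plus the
method frame (number of scans, windows per scan, m/z and IM ranges, timing);
``fit()`` searches the scan-area corners and returns a
:class:`DesignResults` carrying the acquisition scheme, the coverage
diagnostics and the optimization history, with ``summary()``,
``save_method()`` and ``plot()`` for downstream use.

Throughput presets follow Evosep gradients: 100 samples/day -> 8 dia-PASEF
scans, 60 SPD -> 12 scans, 30 SPD -> 25 scans, all with two IM windows per
scan (with one MS1 frame and a 100 ms ramp the 60 SPD preset has a 1.38 s
cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .coverage import DEFAULT_CHARGES, CoverageReport, coverage_report, per_window_balance
from .geometry import (
    AcquisitionScheme,
    DEFAULT_FRAME_OVERHEAD,
    DEFAULT_RAMP_TIME,
    ScanArea,
    build_scheme,
    cycle_time,
    equal_density_bin_edges,
    equidistant_bin_edges,
)
from .library import SpectralLibrary, filter_precursors, read_library
from .optimize import (
    OptimizationConfig,
    OptimizationResult,
    grid_search_oracle,
    optimize_scan_area,
)

__all__ = ["DiaWindowDesigner", "DesignResults", "PRESETS"]

#: samples-per-day presets: (n_scans, mz_range)
PRESETS = {
    "spd100": (8, (300.0, 1200.0)),
    "spd60": (12, (300.0, 1200.0)),
    "spd30": (25, (300.0, 1200.0)),
}


class DiaWindowDesigner:
    """Design a dia-PASEF acquisition scheme against a spectral library.

    Parameters
    ----------
    library : SpectralLibrary
        Reference precursors; filtered on construction to the method ranges
        and charge set (the objective/coverage population).
    n_scans, windows_per_scan : int
        Cycle layout; the total window count is their product.
    mz_range, im_range : (float, float)
        Method coordinate ranges.
    charges : sequence of int
        Charge states included in the design population (default 2-4).
    """

    def __init__(
        self,
        library: SpectralLibrary,
        *,
        n_scans: int = 12,
        windows_per_scan: int = 2,
        mz_range: tuple[float, float] = (300.0, 1200.0),
        im_range: tuple[float, float] = (0.6, 1.5),
        charges: Sequence[int] = DEFAULT_CHARGES,
        ms1_frames_per_cycle: int = 1,
        ramp_time: float = DEFAULT_RAMP_TIME,
        frame_overhead: float = DEFAULT_FRAME_OVERHEAD,
    ):
        self.library = library
        self.population = filter_precursors(library, mz_range, im_range, charges)
        if len(self.population) == 0:
            raise ValueError("no precursors in the design population after filtering")
        self.n_scans = n_scans
        self.windows_per_scan = windows_per_scan
        self.mz_range = (float(mz_range[0]), float(mz_range[1]))
        self.im_range = (float(im_range[0]), float(im_range[1]))
        self.charges = tuple(int(c) for c in charges)
        self.ms1_frames_per_cycle = ms1_frames_per_cycle
        self.ramp_time = ramp_time
        self.frame_overhead = frame_overhead

    @classmethod
    def from_library_file(cls, path, format: str = "auto", **kwargs) -> "DiaWindowDesigner":
        lib, _ = read_library(path, format=format)
        return cls(lib, **kwargs)

    @classmethod
    def from_preset(cls, library: SpectralLibrary, preset: str, **kwargs) -> "DiaWindowDesigner":
        """Construct with a throughput preset (spd100 / spd60 / spd30)."""
        n_scans, mz_range = PRESETS[preset]
        kwargs.setdefault("n_scans", n_scans)
        kwargs.setdefault("mz_range", mz_range)
        return cls(library, **kwargs)

    # ------------------------------------------------------------------

    def _timing(self) -> dict:
        return dict(
            ms1_frames_per_cycle=self.ms1_frames_per_cycle,
            ramp_time=self.ramp_time,
            frame_overhead=self.frame_overhead,
        )

    def build(self, area: ScanArea, equidistant: bool = False) -> AcquisitionScheme:
        """Build the scheme for a given scan area without optimizing."""
        n_bins = self.n_scans * self.windows_per_scan
        edges = (
            equidistant_bin_edges(self.mz_range, n_bins)
            if equidistant
            else equal_density_bin_edges(self.population, n_bins, self.mz_range)
        )
        return build_scheme(
            edges, area, self.n_scans, self.windows_per_scan, self.im_range, **self._timing()
        )

    def full_im_area(self) -> ScanArea:
        """Rectangle spanning the whole instrument IM range."""
        lo, hi = self.im_range
        return ScanArea(lo, lo, hi, hi)

    def fit(
        self,
        method: str = "bayesian",
        *,
        n_trials: int = 200,
        n_initial_random: int = 20,
        seed: int = 42,
        initial_points: Sequence = (),
        grid_resolution: int = 7,
        histogram_bins: int = 20,
    ) -> "DesignResults":
        """Search the scan area and evaluate the resulting scheme.

        ``method`` is one of ``"bayesian"`` (GP surrogate, the default),
        ``"random"`` (pure random search), ``"grid"`` (exhaustive oracle) or
        ``"equidistant"`` (no search: fixed-width windows over the full IM
        range, the classic scheme used as baseline).
        """
        opt: OptimizationResult | None = None
        if method == "equidistant":
            area = self.full_im_area()
            scheme = self.build(area, equidistant=True)
        elif method == "grid":
            opt = grid_search_oracle(
                self.population,
                grid_resolution,
                n_scans=self.n_scans,
                windows_per_scan=self.windows_per_scan,
                mz_range=self.mz_range,
                im_range=self.im_range,
                charges=self.charges,
            )
            area = opt.best_area
            scheme = self.build(area)
        elif method in ("bayesian", "random"):
            cfg = OptimizationConfig(
                n_trials=n_trials,
                n_initial_random=n_initial_random,
                seed=seed,
                initial_points=tuple(tuple(p) for p in initial_points),
            )
            opt = optimize_scan_area(
                self.population,
                cfg,
                n_scans=self.n_scans,
                windows_per_scan=self.windows_per_scan,
                mz_range=self.mz_range,
                im_range=self.im_range,
                charges=self.charges,
                proposer="gp" if method == "bayesian" else "random",
            )
            area = opt.best_area
            scheme = self.build(area)
        else:
            raise ValueError(f"unknown fit method {method!r}")

        report = coverage_report(self.population, scheme, histogram_bins=histogram_bins)
        return DesignResults(
            model=self,
            scan_area=area,
            scheme=scheme,
            coverage=report,
            optimization=opt,
            method=method,
        )


@dataclass
class DesignResults:
    """Fitted window design: scheme, coverage diagnostics, search history."""

    model: DiaWindowDesigner
    scan_area: ScanArea
    scheme: AcquisitionScheme
    coverage: CoverageReport
    optimization: OptimizationResult | None
    method: str

    @property
    def cycle_time(self) -> float:
        return cycle_time(self.scheme)

    def summary(self) -> str:
        """Human-readable design summary table."""
        m = self.model
        bal = per_window_balance(self.coverage)
        lines = [
            "dia-PASEF window design",
            "=" * 55,
            f"design method            {self.method}",
            f"dia-PASEF scans          {m.n_scans}",
            f"IM windows per scan      {m.windows_per_scan}",
            f"m/z range                {m.mz_range[0]:.1f} - {m.mz_range[1]:.1f} Th",
            f"IM range                 {m.im_range[0]:.2f} - {m.im_range[1]:.2f} 1/K0",
            f"cycle time               {self.cycle_time:.2f} s",
            f"design population        {self.coverage.n_precursors} precursors "
            f"(charges {'/'.join(map(str, m.charges))})",
            "-" * 55,
            f"scan area corners        bottom {self.scan_area.im_bottom_left:.3f}/"
            f"{self.scan_area.im_bottom_right:.3f}, top {self.scan_area.im_top_left:.3f}/"
            f"{self.scan_area.im_top_right:.3f}",
            f"covered fraction         {self.coverage.covered_fraction:.1%}",
        ]
        for c, f in sorted(self.coverage.per_charge_fraction.items()):
            lines.append(f"  charge {c}+               {f:.1%}")
        lines.append(
            f"precursors per window    min {bal['min']:.0f} / mean {bal['mean']:.1f} / "
            f"max {bal['max']:.0f} (max/mean {bal['max_over_mean']:.2f})"
        )
        if self.optimization is not None:
            lines.append(
                f"optimizer                {len(self.optimization.history)} trials, "
                f"seed {self.optimization.seed}, best {self.optimization.best_value:.4f}"
            )
        return "\n".join(lines)

    def save_method(self, path) -> Path:
        from .methodfile import write_method_file

        return write_method_file(self.scheme, path)

    def save_history(self, path) -> Path:
        """Trial history as TSV (trial, four corners, coverage)."""
        if self.optimization is None:
            raise ValueError("no optimization history for this design method")
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("trial\tim_bottom_left\tim_bottom_right\tim_top_left\tim_top_right\tcoverage\n")
            for i, p, v in self.optimization.history:
                fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in p) + f"\t{v:.6f}\n")
        return path

    def plot(self, path):
        from .plotting import plot_scheme_density

        return plot_scheme_density(self.model.population, self.scheme, path)
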