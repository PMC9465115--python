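"""Scan-area optimization: maximise precursor coverage over trapezoid corners.

The search space is the box of four corner IM values (bottom-left,
bottom-right, top-left, top-right), each bounded by the instrument IM range.
Invalid orderings (top <= bottom at either m/z end) score zero instead of
being excluded, which keeps the space a simple box.

The default search is Bayesian optimization: after an initial batch of
random evaluations, a Gaussian-process surrogate (Matern-5/2 kernel) is fit
to the trial history and the next candidate is chosen by maximising expected
improvement over a random candidate pool.  The proposer is swappable: any
callable consuming (bounds, history, rng) and returning the next parameter
vector can be passed, and a pure random-search proposer is provided as a
fallback.  A coarse exhaustive grid search serves as a deterministic oracle
for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .coverage import DEFAULT_CHARGES
from .geometry import ScanArea, build_scheme, equal_density_bin_edges
from .library import SpectralLibrary, filter_precursors

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "CoverageObjective",
    "optimize_scan_area",
    "grid_search_oracle",
    "gp_proposer",
    "random_proposer",
]


@dataclass(frozen=True)
class OptimizationConfig:
    """Settings of one optimization run.

    ``n_trials`` total objective evaluations (the field standard is about
    200); the first ``n_initial_random`` are uniform random draws seeding the
    surrogate.  ``initial_points`` are evaluated first and count toward the
    trial budget.  ``bounds`` default to the instrument IM range per corner.
    """

    n_trials: int = 200
    n_initial_random: int = 20
    seed: int = 42
    bounds: tuple | None = None
    initial_points: tuple = ()

    def __post_init__(self) -> None:
        if self.n_initial_random > self.n_trials:
            raise ValueError("n_initial_random must be <= n_trials")


@dataclass(frozen=True)
class OptimizationResult:
    """Best scan area found, its coverage, and the full trial history."""

    best_area: ScanArea
    best_value: float
    history: tuple  # of (trial_index, parameter tuple, value)
    seed: int

    def history_array(self) -> np.ndarray:
        """(n_trials, 5) array: four corner IMs then the objective value."""
        return np.array([list(p) + [v] for _, p, v in self.history])

    def running_best(self) -> np.ndarray:
        return np.maximum.accumulate([v for _, _, v in self.history])


class CoverageObjective:
    """Pure, cached objective: corner IM vector -> covered fraction.

    Equal-density m/z bin edges are computed once from the library (they do
    not depend on the scan area); each call builds the scheme for the
    candidate corners and scores the default population (charges 2-4 inside
    the configured ranges).  Geometrically invalid candidates return 0.
    """

    def __init__(
        self,
        lib: SpectralLibrary,
        n_scans: int,
        windows_per_scan: int,
        mz_range: tuple[float, float],
        im_range: tuple[float, float],
        charges: Sequence[int] = DEFAULT_CHARGES,
    ):
        if len(lib) == 0:
            raise ValueError("empty library")
        pop = filter_precursors(lib, mz_range, im_range, charges)
        if len(pop) == 0:
            raise ValueError("no precursors in the objective population")
        self.population = pop
        self.n_scans = n_scans
        self.windows_per_scan = windows_per_scan
        self.mz_range = mz_range
        self.im_range = im_range
        n_bins = n_scans * windows_per_scan
        self.bin_edges = equal_density_bin_edges(pop, n_bins, mz_range)
        # precursor -> m/z bin (half-open bins, last closed at mz_max)
        idx = np.searchsorted(self.bin_edges, pop.mz, side="right") - 1
        self._bin_idx = np.clip(idx, 0, n_bins - 1)
        self._im = pop.im
        # window order in build_scheme output -> bin index (0-based)
        W, n, k = n_bins, n_scans, windows_per_scan
        self._window_bin = np.array(
            [W - s * n - (j - 1) - 1 for j in range(1, n + 1) for s in range(k)]
        )

    def build(self, params):
        area = ScanArea.from_vector(params)
        return build_scheme(
            self.bin_edges,
            area,
            self.n_scans,
            self.windows_per_scan,
            self.im_range,
        )

    def __call__(self, params) -> float:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scheme = self.build(params)
        except ValueError:
            return 0.0
        im_low = np.array([w.im_low for w in scheme.windows])
        im_high = np.array([w.im_high for w in scheme.windows])
        # invert: bin index -> that bin's window IM interval
        lo = np.empty_like(im_low)
        hi = np.empty_like(im_high)
        lo[self._window_bin] = im_low
        hi[self._window_bin] = im_high
        w_lo = lo[self._bin_idx]
        w_hi = hi[self._bin_idx]
        covered = (self._im >= w_lo) & (self._im <= w_hi)
        return float(covered.mean())


def random_proposer(bounds: np.ndarray, history, rng: np.random.Generator) -> np.ndarray:
    """Pure random search fallback."""
    return rng.uniform(bounds[:, 0], bounds[:, 1])


def gp_proposer(
    bounds: np.ndarray,
    history,
    rng: np.random.Generator,
    n_candidates: int = 512,
) -> np.ndarray:
    """Expected-improvement proposal from a GP surrogate of the history."""
    X = np.array([list(p) for _, p, _ in history])
    y = np.array([v for _, _, v in history])
    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.full(bounds.shape[0], 0.2 * np.ptp(bounds, axis=1).mean()),
        nu=2.5,
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-2))
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, random_state=0, n_restarts_optimizer=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gp.fit(X, y)
    cand = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_candidates, bounds.shape[0]))
    # densify around the incumbent with local perturbations
    best = X[np.argmax(y)]
    local = best + rng.normal(0.0, 0.05 * np.ptp(bounds, axis=1), size=(n_candidates // 4, bounds.shape[0]))
    local = np.clip(local, bounds[:, 0], bounds[:, 1])
    cand = np.vstack([cand, local])
    mu, sigma = gp.predict(cand, return_std=True)
    y_best = y.max()
    xi = 1e-3
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - y_best - xi) / sigma
    ei = (mu - y_best - xi) * norm.cdf(z) + sigma * norm.pdf(z)
    return cand[int(np.argmax(ei))]


def optimize_scan_area(
    lib: SpectralLibrary,
    cfg: OptimizationConfig,
    *,
    n_scans: int = 12,
    windows_per_scan: int = 2,
    mz_range: tuple[float, float] = (300.0, 1200.0),
    im_range: tuple[float, float] = (0.6, 1.5),
    charges: Sequence[int] = DEFAULT_CHARGES,
    proposer: Callable | str = "gp",
) -> OptimizationResult:
    """Search the scan-area corners maximising library coverage.

    Runs ``cfg.initial_points`` first, then ``n_initial_random`` uniform
    draws, then surrogate-guided proposals up to ``n_trials`` evaluations.
    Fully reproducible from the config seed.
    """
    objective = CoverageObjective(
        lib, n_scans, windows_per_scan, mz_range, im_range, charges
    )
    if isinstance(proposer, str):
        proposer = {"gp": gp_proposer, "random": random_proposer}[proposer]
    bounds = np.array(
        cfg.bounds if cfg.bounds is not None else [(im_range[0], im_range[1])] * 4,
        dtype=float,
    )
    rng = np.random.default_rng(cfg.seed)
    history: list[tuple[int, tuple, float]] = []

    def evaluate(params) -> None:
        params = tuple(float(x) for x in params)
        history.append((len(history) + 1, params, objective(params)))

    for p in cfg.initial_points:
        if len(history) >= cfg.n_trials:
            break
        evaluate(p)
    while len(history) < min(cfg.n_initial_random + len(cfg.initial_points), cfg.n_trials):
        evaluate(rng.uniform(bounds[:, 0], bounds[:, 1]))
    while len(history) < cfg.n_trials:
        evaluate(proposer(bounds, history, rng))

    values = [v for _, _, v in history]
    if max(values) <= 0.0:
        raise RuntimeError(
            "all trials geometrically invalid or zero coverage; "
            "check bounds against the instrument IM range"
        )
    best_i = int(np.argmax(values))
    return OptimizationResult(
        best_area=ScanArea.from_vector(history[best_i][1]),
        best_value=float(values[best_i]),
        history=tuple(history),
        seed=cfg.seed,
    )


def grid_search_oracle(
    lib: SpectralLibrary,
    resolution: int = 7,
    *,
    n_scans: int = 12,
    windows_per_scan: int = 2,
    mz_range: tuple[float, float] = (300.0, 1200.0),
    im_range: tuple[float, float] = (0.6, 1.5),
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> OptimizationResult:
    """Exhaustive Cartesian grid over corner values (deterministic oracle).

    Invalid corner combinations score 0; the best grid point is returned.
    """
    if resolution < 2:
        raise ValueError("grid resolution must be >= 2 per dimension")
    objective = CoverageObjective(
        lib, n_scans, windows_per_scan, mz_range, im_range, charges
    )
    axis = np.linspace(im_range[0], im_range[1], resolution)
    grids = np.meshgrid(axis, axis, axis, axis, indexing="ij")
    candidates = np.stack([g.ravel() for g in grids], axis=1)
    history = []
    for i, params in enumerate(candidates, start=1):
        p = tuple(float(x) for x in params)
        history.append((i, p, objective(p)))
    values = [v for _, _, v in history]
    best_i = int(np.argmax(values))
    best_params = history[best_i][1]
    if values[best_i] <= 0.0:
        raise RuntimeError("no grid candidate achieved nonzero coverage")
    return OptimizationResult(
        best_area=ScanArea.from_vector(best_params),
        best_value=float(values[best_i]),
        history=tuple(history),
        seed=0,
    )
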