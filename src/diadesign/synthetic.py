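"""Synthetic precursor clouds in the m/z-1/K0 plane.

Tryptic-digest precursors form charge-dependent bands in the m/z-mobility
plane: within a charge state, reduced mobility rises roughly linearly with
m/z, and higher charge states sit on lower, flatter bands.  The generator
emulates this structure as a charge-stratified mixture: per charge, m/z is
drawn from a truncated lognormal and 1/K0 from a linear trend in m/z plus
Gaussian residual, with rejection sampling enforcing the configured
coordinate ranges.

Phosphopeptide-enriched samples are emulated by translating the whole cloud
to higher m/z (the phosphate adds ~80 Da to the mass) and higher mobility,
and re-weighting toward higher charge states.

A second generator draws points strictly inside a prescribed trapezoidal
scan area, giving fixtures with a known optimal window placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanArea, strip_boundary_im
from .library import PrecursorRecord, SpectralLibrary

__all__ = [
    "ChargeBand",
    "CloudModel",
    "proteome_model",
    "phospho_model",
    "generate_library",
    "generate_within_trapezoid",
]

#: abort rejection sampling below this acceptance rate
_MIN_ACCEPTANCE = 0.01


@dataclass(frozen=True)
class ChargeBand:
    """One charge state's band: im ~ intercept + slope*mz + N(0, im_sd)."""

    weight: float
    im_intercept: float
    im_slope: float
    im_sd: float


@dataclass(frozen=True)
class CloudModel:
    """Charge-stratified precursor cloud.

    m/z is lognormal with the given log-median/log-sd, shifted by
    ``mz_shift`` and truncated to ``mz_range``; mobility follows the
    charge band's linear trend (computed at the unshifted m/z) plus
    ``im_shift``, truncated to ``im_range``.  The shifts implement the
    phospho cloud as a translation of the proteome cloud.
    """

    bands: dict  # charge -> ChargeBand
    mz_log_median: float = np.log(700.0)
    mz_log_sd: float = 0.25
    mz_range: tuple[float, float] = (300.0, 1200.0)
    im_range: tuple[float, float] = (0.6, 1.5)
    mz_shift: float = 0.0
    im_shift: float = 0.0
    is_phospho: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(b.weight for b in self.bands.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, expected 1")


def proteome_model(seed: int = 0, **overrides) -> CloudModel:
    """Default whole-proteome digest cloud (m/z 300-1200, IM 0.6-1.5)."""
    bands = {
        2: ChargeBand(weight=0.66, im_intercept=0.40, im_slope=0.0009, im_sd=0.045),
        3: ChargeBand(weight=0.27, im_intercept=0.30, im_slope=0.0008, im_sd=0.045),
        4: ChargeBand(weight=0.07, im_intercept=0.28, im_slope=0.00075, im_sd=0.045),
    }
    return CloudModel(bands=bands, seed=seed, **overrides)


def phospho_model(seed: int = 0, **overrides) -> CloudModel:
    """Phospho-enriched cloud: proteome cloud translated by (+80 Th, +0.03
    1/K0), truncated to m/z 400-1400, with more 3+/4+ precursors."""
    bands = {
        2: ChargeBand(weight=0.50, im_intercept=0.40, im_slope=0.0009, im_sd=0.045),
        3: ChargeBand(weight=0.38, im_intercept=0.30, im_slope=0.0008, im_sd=0.045),
        4: ChargeBand(weight=0.12, im_intercept=0.28, im_slope=0.00075, im_sd=0.045),
    }
    defaults = dict(
        mz_range=(400.0, 1400.0),
        mz_shift=80.0,
        im_shift=0.03,
        is_phospho=True,
    )
    defaults.update(overrides)
    return CloudModel(bands=bands, seed=seed, **defaults)


def _sample_batch(model: CloudModel, rng: np.random.Generator, size: int):
    charges = np.array(sorted(model.bands))
    weights = np.array([model.bands[c].weight for c in charges])
    z = rng.choice(charges, size=size, p=weights)
    mz0 = np.exp(rng.normal(model.mz_log_median, model.mz_log_sd, size=size))
    intercept = np.array([model.bands[c].im_intercept for c in z])
    slope = np.array([model.bands[c].im_slope for c in z])
    sd = np.array([model.bands[c].im_sd for c in z])
    im0 = intercept + slope * mz0 + rng.normal(0.0, 1.0, size=size) * sd
    mz = mz0 + model.mz_shift
    im = im0 + model.im_shift
    ok = (
        (mz >= model.mz_range[0])
        & (mz <= model.mz_range[1])
        & (im >= model.im_range[0])
        & (im <= model.im_range[1])
    )
    return mz[ok], im[ok], z[ok]


def generate_library(model: CloudModel, n: int) -> SpectralLibrary:
    """Draw exactly ``n`` precursors from the cloud model.

    Reproducible: the model's seed fully determines the output.  Aborts if
    the truncation region is so improbable that rejection sampling stalls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed)
    mzs, ims, zs = [], [], []
    got, drawn = 0, 0
    while got < n:
        batch = max(n - got, 1000)
        mz, im, z = _sample_batch(model, rng, batch)
        drawn += batch
        got += len(mz)
        mzs.append(mz)
        ims.append(im)
        zs.append(z)
        if drawn >= 10_000 and got / drawn < _MIN_ACCEPTANCE:
            raise RuntimeError(
                f"cloud model acceptance rate {got / drawn:.3%} below "
                f"{_MIN_ACCEPTANCE:.0%}: truncation ranges exclude nearly all "
                "of the configured distribution"
            )
    mz = np.concatenate(mzs)[:n]
    im = np.concatenate(ims)[:n]
    z = np.concatenate(zs)[:n]
    records = [
        PrecursorRecord(
            mz=float(mz[i]),
            im=float(im[i]),
            charge=int(z[i]),
            is_phospho=model.is_phospho,
        )
        for i in range(n)
    ]
    return SpectralLibrary.from_records(records, deduplicate=False)


def generate_within_trapezoid(
    area: ScanArea,
    mz_range: tuple[float, float],
    n: int,
    seed: int,
) -> SpectralLibrary:
    """Draw ``n`` precursors strictly inside a trapezoidal scan area.

    m/z is uniform over ``mz_range``; at each m/z the mobility is uniform
    strictly between the trapezoid's bottom and top edges.  Charges are 2 or
    3 with equal probability.  Used as an optimizer-recovery fixture: a
    scheme whose windows tile this trapezoid covers the sample completely.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    heights = [
        area.im_top_left - area.im_bottom_left,
        area.im_top_right - area.im_bottom_right,
    ]
    if min(heights) <= 0:
        raise ValueError("degenerate (zero-area) trapezoid")
    rng = np.random.default_rng(seed)
    mz = rng.uniform(mz_range[0], mz_range[1], size=n)
    bottom = np.array([strip_boundary_im(area, 0.0, x, mz_range) for x in mz])
    top = np.array([strip_boundary_im(area, 1.0, x, mz_range) for x in mz])
    # margin keeps points strictly interior even at printed precision
    u = rng.uniform(0.01, 0.99, size=n)
    im = bottom + u * (top - bottom)
    charge = rng.choice([2, 3], size=n)
    records = [
        PrecursorRecord(mz=float(mz[i]), im=float(im[i]), charge=int(charge[i]))
        for i in range(n)
    ]
    return SpectralLibrary.from_records(records, deduplicate=False)
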