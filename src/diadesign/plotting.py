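"""Diagnostic figures: precursor density with the acquisition scheme overlay."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle
import numpy as np
from scipy.stats import gaussian_kde

from .geometry import AcquisitionScheme
from .library import SpectralLibrary

__all__ = ["plot_scheme_density"]


def plot_scheme_density(
    lib: SpectralLibrary,
    scheme: AcquisitionScheme | None,
    path: str | Path,
    grid_size: int = 120,
) -> Path | None:
    """Render a 2-D kernel-density estimate of the precursor cloud in the
    m/z-1/K0 plane with the scheme's isolation windows overlaid.

    Purely diagnostic; failures warn instead of raising.
    """
    path = Path(path)
    try:
        if len(lib) == 0:
            raise ValueError("empty library")
        mz, im = lib.mz, lib.im
        fig, ax = plt.subplots(figsize=(7, 5))
        if len(lib) >= 10 and np.std(mz) > 0 and np.std(im) > 0:
            kde = gaussian_kde(np.vstack([mz, im]))
            xg = np.linspace(mz.min(), mz.max(), grid_size)
            yg = np.linspace(im.min(), im.max(), grid_size)
            X, Y = np.meshgrid(xg, yg)
            Z = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(X.shape)
            ax.contourf(X, Y, Z, levels=12, cmap="viridis")
        else:
            ax.scatter(mz, im, s=4, c="k")
        if scheme is not None:
            for w in scheme.windows:
                ax.add_patch(
                    Rectangle(
                        (w.mz_start, w.im_low),
                        w.mz_end - w.mz_start,
                        w.im_high - w.im_low,
                        fill=False,
                        edgecolor="white",
                        linewidth=0.8,
                    )
                )
        ax.set_xlabel("m/z (Th)")
        ax.set_ylabel("ion mobility 1/K$_0$ (V·s/cm²)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    except Exception as exc:  # diagnostics must never break a run
        warnings.warn(f"scheme/density plot failed: {exc}", stacklevel=2)
        return None
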