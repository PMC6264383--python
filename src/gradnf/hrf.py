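"""Double-gamma hemodynamic response function and block regressors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DesignError
from .protocol import RunDesign


@dataclass(frozen=True)
class HemodynamicModel:
    """Canonical double-gamma HRF shape (delays/dispersions in seconds).

    The kernel is the difference of two gamma densities: a positive lobe
    peaking near ``peak_delay`` and an undershoot lobe scaled by
    ``undershoot_ratio``.  Defaults are the widely used canonical values
    (peak 6 s, undershoot 16 s, ratio 1/6).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0  # kernel support in seconds

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise DesignError("HRF dispersions must be positive")
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise DesignError("HRF delays must be positive")
        if self.undershoot_ratio < 0:
            raise DesignError("undershoot_ratio must be >= 0")
        if self.duration < 20:
            raise DesignError("kernel support must cover at least 20 s")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Continuous kernel values at times ``t`` (unnormalized)."""
        peak = stats.gamma.pdf(
            t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion
        )
        under = stats.gamma.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        return peak - self.undershoot_ratio * under


def make_hrf(model: HemodynamicModel | None = None, tr: float = 1.55) -> np.ndarray:
    """Sample the double-gamma kernel on the TR grid, normalized to unit peak.

    The peak is taken over a fine (10 ms) grid so that the normalization is
    independent of the TR.
    """
    model = model or HemodynamicModel()
    if tr <= 0:
        raise DesignError(f"tr must be > 0, got {tr}")
    fine = np.arange(0, model.duration, 0.01)
    peak = float(np.max(model.evaluate(fine)))
    t = np.arange(0, model.duration, tr)
    return model.evaluate(t) / peak


def convolve_blocks(boxcar: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve a per-volume boxcar with an HRF kernel, unit-plateau scaled.

    The result is rescaled by the kernel sum so a sustained block reaches a
    plateau of exactly 1: a block amplitude then reads directly in the
    boxcar's units (e.g. percent signal change).
    """
    ksum = float(np.sum(kernel))
    if ksum <= 0:
        raise DesignError("kernel must integrate to a positive value")
    return np.convolve(boxcar, kernel)[: len(boxcar)] / ksum


def task_regressor(design: RunDesign, kernel: np.ndarray) -> np.ndarray:
    """Unit-plateau task regressor over all task blocks of a run."""
    return convolve_blocks(design.boxcar(["task", "low", "high"]), kernel)


def level_regressor(design: RunDesign, kernel: np.ndarray) -> np.ndarray:
    """Parametric level regressor: +1/2 on high blocks, -1/2 on low blocks.

    With this coding the associated GLM coefficient equals the high-minus-low
    amplitude difference.
    """
    box = 0.5 * design.boxcar(["high"]) - 0.5 * design.boxcar(["low"])
    return convolve_blocks(box, kernel)
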