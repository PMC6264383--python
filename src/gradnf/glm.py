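"""Offline GLM re-analysis of ROI time series.

Replicates the offline re-analysis of the neurofeedback experiment on
ROI-mean series: for NF runs a GLM with a task predictor spanning both
levels, a parametric level-difference predictor (+1/2 high, -1/2 low on
the convolved support) and one pre-onset baseline indicator per task
block (the 10 volumes preceding stimulus onset, matching the online
baseline window), with no drift term; for localizer runs a task predictor
plus a linear drift.  Fits use two-pass AR(1) prewhitening
(Cochrane-Orcutt estimate of the lag-1 residual autocorrelation followed
by a Prais-Winsten transform and re-fit).  Percent signal change (PSC) is
extracted per level as the ratio of the level amplitude to the estimated
baseline signal, mirroring the online definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DesignError
from .feedback import BASELINE_WINDOW
from .protocol import LEVELS, RunDesign
from .simulate import RoiTimeSeries
from .hrf import level_regressor, task_regressor


@dataclass
class DesignMatrix:
    """Named regressors per volume for one run's GLM."""

    names: list[str]
    matrix: np.ndarray
    design: RunDesign

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.design.total_volumes, len(self.names)):
            raise DesignError("design matrix shape does not match names/volumes")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < len(self.names):
            # flag columns whose removal restores full rank
            collinear = []
            for j, name in enumerate(self.names):
                reduced = np.delete(self.matrix, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    collinear.append(name)
            raise DesignError(f"design matrix is rank deficient; collinear columns: {collinear}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @property
    def n_pre_onset(self) -> int:
        return sum(1 for n in self.names if n.startswith("pre_onset"))

    def r1_bias_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected residual lag-1 autocorrelation as a function of true rho.

        OLS residuals are the projection Q = I - H of the noise, which biases
        their lag-1 autocorrelation toward zero.  This computes
        E[r1 | rho] = tr(L Q S(rho) Q) / tr(Q S(rho) Q) on a rho grid (L the
        symmetrized lag-1 operator, S the AR(1) autocovariance), so the raw
        estimate can be de-biased by inverting the map.  Cached per matrix.
        """
        if not hasattr(self, "_r1_map"):
            n = self.matrix.shape[0]
            Q = np.eye(n) - self.matrix @ np.linalg.pinv(self.matrix)
            L = np.zeros((n, n))
            idx = np.arange(n - 1)
            L[idx + 1, idx] = 0.5
            L[idx, idx + 1] = 0.5
            rho_grid = np.linspace(-0.5, 0.95, 30)
            lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
            expected = np.empty_like(rho_grid)
            for i, rho in enumerate(rho_grid):
                M = Q @ (rho**lags) @ Q
                expected[i] = np.trace(L @ M) / np.trace(M)
            self._r1_map = (expected, rho_grid)
        return self._r1_map


@dataclass
class GlmFit:
    """Prewhitened GLM fit: coefficients and noise diagnostics."""

    betas: dict[str, float]
    residual_variance: float
    ar1_rho_hat: float
    dof: int


@dataclass(frozen=True)
class PscEstimate:
    """One percent-signal-change value for a region/condition/level cell."""

    region: str
    condition: str  # 'active' or 'passive'
    level: str
    psc: float
    run_id: str = ""
    subject: str = ""


def _pre_onset_indicators(design: RunDesign) -> list[np.ndarray]:
    """One 0/1 column per task block covering its 10 pre-onset volumes."""
    n = design.total_volumes
    cols = []
    for blk in design.blocks:
        if blk.block_type == "rest":
            continue
        col = np.zeros(n)
        col[blk.onset_volume - BASELINE_WINDOW : blk.onset_volume] = 1.0
        cols.append(col)
    return cols


def build_nf_design_matrix(design: RunDesign, hrf: np.ndarray) -> DesignMatrix:
    """NF-run model: intercept + task + parametric level + pre-onset baselines."""
    if design.run_kind != "neurofeedback":
        raise DesignError("build_nf_design_matrix requires a neurofeedback design")
    n = design.total_volumes
    cols = [np.ones(n), task_regressor(design, hrf), level_regressor(design, hrf)]
    names = ["intercept", "task", "level"]
    for i, col in enumerate(_pre_onset_indicators(design)):
        cols.append(col)
        names.append(f"pre_onset_{i + 1}")
    return DesignMatrix(names, np.column_stack(cols), design)


def build_localizer_design_matrix(design: RunDesign, hrf: np.ndarray) -> DesignMatrix:
    """Localizer model: intercept + task + mean-centred linear drift."""
    if design.run_kind != "localizer":
        raise DesignError("build_localizer_design_matrix requires a localizer design")
    n = design.total_volumes
    drift = np.arange(n, dtype=float)
    drift -= drift.mean()
    cols = [np.ones(n), task_regressor(design, hrf), drift]
    return DesignMatrix(["intercept", "task", "drift"], np.column_stack(cols), design)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def fit_glm_prewhitened(
    series: RoiTimeSeries | np.ndarray, X: DesignMatrix
) -> GlmFit:
    """Two-pass AR(1)-prewhitened GLM fit.

    First pass: OLS, estimate the lag-1 autocorrelation rho of the
    residuals, de-biased for the residual projection (see
    :meth:`DesignMatrix.r1_bias_map`).  Second pass: Prais-Winsten
    transform of both data and design (first row scaled by
    sqrt(1 - rho^2)), re-fit by OLS.
    """
    y = series.values if isinstance(series, RoiTimeSeries) else np.asarray(series, float)
    if len(y) != X.matrix.shape[0]:
        raise DataError(f"series length {len(y)} != design rows {X.matrix.shape[0]}")
    beta0, resid = _ols(y, X.matrix)
    denom = float(resid @ resid)
    r1 = float(resid[1:] @ resid[:-1] / denom) if denom > 0 else 0.0
    if not abs(r1) < 1:
        raise DataError(f"estimated AR(1) coefficient {r1} outside (-1, 1)")
    expected, rho_grid = X.r1_bias_map()
    rho = float(np.clip(np.interp(r1, expected, rho_grid), -0.99, 0.99))

    def whiten(a: np.ndarray) -> np.ndarray:
        out = np.empty_like(a, dtype=float)
        out[0] = np.sqrt(1.0 - rho**2) * a[0]
        out[1:] = a[1:] - rho * a[:-1]
        return out

    beta, wresid = _ols(whiten(y), whiten(X.matrix))
    n, p = X.matrix.shape
    dof = n - p
    sigma2 = float(wresid @ wresid) / dof if dof > 0 else np.nan
    return GlmFit(dict(zip(X.names, beta)), sigma2, rho, dof)


def extract_psc(
    fit: GlmFit,
    X: DesignMatrix,
    level: str,
    *,
    region: str = "",
    condition: str = "",
    run_id: str = "",
    subject: str = "",
) -> PscEstimate:
    """Level-wise PSC from an NF fit.

    The level amplitude is ``task beta + 1/2 level beta`` (high) or
    ``task beta - 1/2 level beta`` (low); the baseline signal is the
    intercept plus the mean of the pre-onset baseline coefficients.
    """
    if level not in LEVELS:
        raise DesignError(f"unknown level {level!r}")
    if "level" not in fit.betas or X.n_pre_onset == 0:
        raise DesignError("extract_psc requires a fit from an NF design matrix")
    sign = 0.5 if level == "high" else -0.5
    amplitude = fit.betas["task"] + sign * fit.betas["level"]
    pre = [v for k, v in fit.betas.items() if k.startswith("pre_onset")]
    baseline = fit.betas["intercept"] + float(np.mean(pre))
    if baseline <= 0:
        raise DataError(f"estimated baseline signal {baseline} is not positive")
    return PscEstimate(
        region=region,
        condition=condition,
        level=level,
        psc=100.0 * amplitude / baseline,
        run_id=run_id,
        subject=subject,
    )


def localizer_psc(fit: GlmFit) -> float:
    """Localizer PSC: task amplitude as a percentage of the intercept."""
    if "drift" not in fit.betas:
        raise DesignError("localizer_psc requires a fit from a localizer design matrix")
    intercept = fit.betas["intercept"]
    if intercept <= 0:
        raise DataError(f"intercept {intercept} is not positive")
    return 100.0 * fit.betas["task"] / intercept


def event_related_average(
    series: RoiTimeSeries | np.ndarray,
    design: RunDesign,
    window: tuple[int, int] = (5, 30),
) -> pd.DataFrame:
    """Peri-onset average response across a run's task blocks.

    ``window = (pre, post)`` selects ``pre`` volumes before each task-block
    onset through ``post`` volumes after it.  Each epoch is expressed as
    percent change from its own pre-onset baseline (mean of the 10 volumes
    before onset), then averaged across blocks.  Returns a frame with
    columns ``peri_volume``, ``time_seconds`` and ``mean_pct``.
    """
    y = series.values if isinstance(series, RoiTimeSeries) else np.asarray(series, float)
    pre, post = window
    epochs = []
    for blk in design.task_blocks:
        start, stop = blk.onset_volume - pre, blk.onset_volume + post
        if start < 0 or stop > design.total_volumes:
            raise DesignError(
                f"window ({pre}, {post}) around onset {blk.onset_volume} exceeds run bounds"
            )
        base = float(np.mean(y[blk.onset_volume - BASELINE_WINDOW : blk.onset_volume]))
        epochs.append(100.0 * (y[start:stop] - base) / base)
    arr = np.mean(np.stack(epochs), axis=0)
    peri = np.arange(-pre, post)
    return pd.DataFrame(
        {"peri_volume": peri, "time_seconds": peri * design.tr_seconds, "mean_pct": arr}
    )


def cousineau_morey_sem(values: np.ndarray) -> np.ndarray:
    """Within-subject SEM per column (Cousineau centering, Morey correction).

    ``values`` is a subjects x timepoints array.  Each subject's rows are
    re-centred on the grand mean, the per-column SD is corrected by
    sqrt(m / (m - 1)) for m timepoints, and divided by sqrt(n subjects).
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    centred = values - values.mean(axis=1, keepdims=True) + values.mean()
    sd = centred.std(axis=0, ddof=1) * np.sqrt(m / (m - 1)) if m > 1 else centred.std(axis=0, ddof=1)
    return sd / np.sqrt(n)
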