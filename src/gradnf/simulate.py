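"""Synthetic ROI-level BOLD and physiological data.

Generates per-subject mean time series for the two regions of interest
(SMA and M1) under the study's block designs, with the statistical
structure the downstream analysis assumes: a hemodynamically convolved
block response scaled in percent signal change, a linear drift, and AR(1)
Gaussian noise.  Optional end-tidal CO2 and heart-rate traces carry a
slow autocorrelated fluctuation plus a task-locked component.

The default effect structure emulates the study population: a positive
SMA response, larger for the high than the low target level, a negative
(deactivation) M1 response at both levels, and localizer responses of
1.48% (M1) and 1.10% (SMA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import DataError, DesignError
from .hrf import HemodynamicModel, convolve_blocks, make_hrf
from .protocol import (
    LEVELS,
    REGIONS,
    RunDesign,
    ScanProtocol,
    SessionPlan,
    assign_counterbalancing,
)

PHYSIO_KINDS = ("petco2", "heart_rate")

#: subject-typical mean and fluctuation parameters per physiological trace
_PHYSIO_DEFAULTS = {
    "petco2": {"mean": 40.0, "fluct_sd": 1.5, "fluct_rho": 0.9},  # mmHg
    "heart_rate": {"mean": 65.0, "fluct_sd": 3.0, "fluct_rho": 0.9},  # bpm
}


@dataclass(frozen=True)
class SubjectSimParams:
    """Generative parameters for one subject's session.

    ``psc_true`` maps (region, level) to the true neurofeedback-run percent
    signal change (signed; M1 entries are negative by default).
    ``loc_psc_true`` maps region to the localizer task PSC.  Noise is AR(1)
    Gaussian with marginal standard deviation ``noise_sd`` in raw units.
    """

    baseline_signal: float = 1000.0
    psc_true: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("SMA", "low"): 0.300,
            ("SMA", "high"): 0.387,
            ("M1", "low"): -0.150,
            ("M1", "high"): -0.150,
        }
    )
    loc_psc_true: Mapping[str, float] = field(
        default_factory=lambda: {"M1": 1.48, "SMA": 1.10}
    )
    ar1_rho: float = 0.3
    noise_sd: float = 6.0
    drift_slope: float = 0.05  # raw units per volume
    physio_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"petco2": -0.1, "heart_rate": -0.3}
    )

    def __post_init__(self) -> None:
        if self.baseline_signal <= 0:
            raise DesignError("baseline_signal must be > 0")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise DesignError("|ar1_rho| must be < 1")


@dataclass
class RoiTimeSeries:
    """Raw ROI-mean signal for one region over one run."""

    values: np.ndarray
    region: str
    design: RunDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.design.total_volumes:
            raise DataError(
                f"series length {len(self.values)} != design volumes "
                f"{self.design.total_volumes}"
            )


@dataclass
class PhysioTrace:
    """Per-TR physiological samples for one run (mmHg or bpm)."""

    kind: str
    values: np.ndarray
    coupling: float

    def __post_init__(self) -> None:
        if self.kind not in PHYSIO_KINDS:
            raise DesignError(f"unknown physio kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("physio trace contains non-finite values")


def ar1_noise(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    innov[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -rho], innov)


def _level_boxcars(design: RunDesign) -> dict[str, np.ndarray]:
    if design.run_kind == "localizer":
        return {"task": design.boxcar(["task"])}
    return {lev: design.boxcar([lev]) for lev in LEVELS}


def simulate_roi_run(
    design: RunDesign,
    params: SubjectSimParams,
    region: str,
    hrf: np.ndarray,
    seed: int | np.random.Generator,
) -> RoiTimeSeries:
    """Simulate one region's raw ROI-mean series for one run.

    signal = baseline * (1 + sum_levels psc_true/100 * convolved boxcar)
             + drift_slope * volume_index + AR(1) noise
    """
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n = design.total_volumes
    response = np.zeros(n)
    for label, box in _level_boxcars(design).items():
        psc = (
            params.loc_psc_true[region]
            if label == "task"
            else params.psc_true[(region, label)]
        )
        response += psc / 100.0 * convolve_blocks(box, hrf)
    signal = (
        params.baseline_signal * (1.0 + response)
        + params.drift_slope * np.arange(n)
        + ar1_noise(n, params.ar1_rho, params.noise_sd, rng)
    )
    return RoiTimeSeries(signal, region, design)


def simulate_physio(
    design: RunDesign,
    kind: str,
    coupling: float,
    seed: int | np.random.Generator,
) -> PhysioTrace:
    """Simulate a per-TR physiological trace for one run.

    trace = subject-typical mean + slow AR(1) fluctuation
            + coupling * task boxcar
    """
    if kind not in PHYSIO_KINDS:
        raise DesignError(f"unknown physio kind {kind!r}")
    if not np.isfinite(coupling):
        raise DesignError("coupling must be finite")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    cfg = _PHYSIO_DEFAULTS[kind]
    n = design.total_volumes
    box = design.boxcar(["task", "low", "high"])
    values = (
        cfg["mean"]
        + ar1_noise(n, cfg["fluct_rho"], cfg["fluct_sd"], rng)
        + coupling * box
    )
    return PhysioTrace(kind, values, coupling)


@dataclass
class SimulatedRun:
    """All simultaneously acquired series for one run."""

    run_id: str
    target_region: str | None  # None for the localizer
    design: RunDesign
    roi: dict[str, RoiTimeSeries]
    physio: dict[str, PhysioTrace]

    def to_frame(self) -> pd.DataFrame:
        data = {"volume": np.arange(self.design.total_volumes)}
        for region in REGIONS:
            data[f"signal_{region}"] = self.roi[region].values
        for kind in PHYSIO_KINDS:
            data[kind] = self.physio[kind].values
        return pd.DataFrame(data)


@dataclass
class SubjectData:
    """One subject's session plan, generative parameters and simulated runs."""

    plan: SessionPlan
    params: SubjectSimParams
    localizer: SimulatedRun
    nf_runs: list[SimulatedRun]


@dataclass
class Cohort:
    """A simulated cohort: the dataset every downstream stage consumes."""

    subjects: list[SubjectData]
    protocol: ScanProtocol
    hrf: np.ndarray
    seed: int


def _perturbed_params(
    template: SubjectSimParams,
    region_sd: float,
    level_sd: float,
    rng: np.random.Generator,
) -> SubjectSimParams:
    """Draw one subject's parameters around the template.

    A shared per-region offset (SD ``region_sd``) moves both levels
    together; an independent per-cell offset (SD ``level_sd``) perturbs the
    level difference.  Localizer PSCs share the region offset.  Physiological
    task coupling varies across subjects with SD equal to the magnitude of
    the template coupling, so the group correlation test sees realistic
    between-subject scatter.
    """
    offsets = {r: rng.normal(0.0, region_sd) for r in REGIONS}
    psc = {
        (r, lev): v + offsets[r] + rng.normal(0.0, level_sd)
        for (r, lev), v in template.psc_true.items()
    }
    loc = {r: max(v + offsets[r], 0.05) for r, v in template.loc_psc_true.items()}
    coupling = {
        k: v + rng.normal(0.0, abs(v)) for k, v in template.physio_coupling.items()
    }
    return replace(template, psc_true=psc, loc_psc_true=loc, physio_coupling=coupling)


def simulate_cohort(
    n_subjects: int = 17,
    template: SubjectSimParams | None = None,
    between_subject_sd: float = 0.25,
    seed: int = 0,
    level_sd: float = 0.08,
    n_runs_per_region: int = 5,
    protocol: ScanProtocol | None = None,
    hrf_model: HemodynamicModel | None = None,
) -> Cohort:
    """Simulate a full cohort: localizer plus NF runs for every subject.

    ``between_subject_sd`` is the SD of the shared per-region PSC offset
    across subjects; ``level_sd`` the SD of the independent per-cell offset
    (so the high-minus-low difference has between-subject SD
    ``level_sd * sqrt(2)``).  Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise DesignError("n_subjects must be >= 2")
    template = template or SubjectSimParams()
    protocol = protocol or ScanProtocol()
    kernel = make_hrf(hrf_model, protocol.tr_seconds)
    plans = assign_counterbalancing(
        n_subjects, seed, protocol, n_runs_per_region=n_runs_per_region
    )
    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)
    subjects = []
    for plan, seq in zip(plans, subj_seqs):
        rng = np.random.default_rng(seq)
        params = _perturbed_params(template, between_subject_sd, level_sd, rng)
        loc = _simulate_run("loc", None, plan.localizer, params, kernel, rng)
        nf = [
            _simulate_run(f"nf-{i + 1:02d}", run.target_region, run.design, params, kernel, rng)
            for i, run in enumerate(plan.nf_runs)
        ]
        subjects.append(SubjectData(plan, params, loc, nf))
    return Cohort(subjects, protocol, kernel, seed)


def _simulate_run(run_id, target_region, design, params, kernel, rng) -> SimulatedRun:
    roi = {r: simulate_roi_run(design, params, r, kernel, rng) for r in REGIONS}
    physio = {
        k: simulate_physio(design, k, params.physio_coupling.get(k, 0.0), rng)
        for k in PHYSIO_KINDS
    }
    return SimulatedRun(run_id, target_region, design, roi, physio)
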