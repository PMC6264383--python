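"""Online neurofeedback computation and thermometer mapping.

Faithful re-implementation of the feedback loop as run during scanning:
at every TR of a task block the percent signal change

    PSC_NF = (val - baseline) * 100 / baseline

is computed, where ``val`` is the mean of the last three consecutive
ROI-mean raw values and ``baseline`` the median over the last 10 volumes
of the preceding rest block.  PSC_NF is normalized by the localizer PSC
(PSC_LOC) of the feedback target region and mapped onto the 15 segments
of the thermometer display (one segment per 10% of PSC_LOC, clamped to
[0, 15]).  Target levels are 50% (low) and 100% (high) of PSC_LOC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, DesignError, ProtocolError
from .protocol import LEVELS, RunDesign, ScanProtocol
from .simulate import RoiTimeSeries

#: volumes of a rest block that define the online baseline
BASELINE_WINDOW = 10
#: length of the moving average over raw values
VAL_WINDOW = 3


@dataclass(frozen=True)
class Calibration:
    """Localizer percent signal change per region, and the feedback target."""

    psc_loc: Mapping[str, float]
    region: str

    def __post_init__(self) -> None:
        for r, v in self.psc_loc.items():
            if not np.isfinite(v):
                raise CalibrationError(f"psc_loc for {r!r} is not finite")
        if self.region not in self.psc_loc:
            raise CalibrationError(f"no psc_loc entry for target region {self.region!r}")
        if self.psc_loc[self.region] <= 0:
            raise CalibrationError(
                f"target region {self.region!r} has non-positive psc_loc"
            )


@dataclass(frozen=True)
class FeedbackSample:
    """Feedback state at one volume."""

    volume_index: int
    block_type: str
    val: float | None
    baseline: float | None
    psc_nf: float | None
    segments: int | None  # None during rest ("the thermometer remained empty")
    target_segments: int | None


@dataclass
class FeedbackTrace:
    """Per-TR feedback states for one run."""

    samples: list[FeedbackSample]
    calibration: Calibration
    region: str

    def task_samples(self, level: str | None = None) -> list[FeedbackSample]:
        out = [s for s in self.samples if s.block_type in LEVELS]
        if level is not None:
            out = [s for s in out if s.block_type == level]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "volume": s.volume_index,
                    "block_type": s.block_type,
                    "val": s.val,
                    "baseline": s.baseline,
                    "psc_nf": s.psc_nf,
                    "segments": s.segments,
                    "target_segments": s.target_segments,
                }
                for s in self.samples
            ]
        )


def compute_baseline(rest_values: Sequence[float]) -> float:
    """Median raw signal over the last 10 volumes of a rest period."""
    rest_values = np.asarray(rest_values, dtype=float)
    if len(rest_values) < BASELINE_WINDOW:
        raise ProtocolError(
            f"rest period has {len(rest_values)} volumes; "
            f"at least {BASELINE_WINDOW} are required for the online baseline"
        )
    return float(np.median(rest_values[-BASELINE_WINDOW:]))


def compute_psc_nf(last_three: Sequence[float], baseline: float) -> float:
    """Online percent signal change of the 3-volume moving average."""
    last_three = np.asarray(last_three, dtype=float)
    if len(last_three) != VAL_WINDOW:
        raise DataError(f"expected {VAL_WINDOW} values, got {len(last_three)}")
    if not np.all(np.isfinite(last_three)):
        raise DataError("raw values must be finite")
    if baseline <= 0:
        raise CalibrationError(f"baseline must be > 0, got {baseline}")
    val = float(np.mean(last_three))
    return (val - baseline) * 100.0 / baseline


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def map_to_segments(
    psc_nf: float,
    psc_loc: float,
    protocol: ScanProtocol | None = None,
    rounding: str = "nearest",
) -> int:
    """Map an online PSC onto thermometer segments.

    The continuous segment value is ``psc_nf / (segment_fraction * psc_loc)``
    (each segment is 10% of PSC_LOC by default), rounded to the nearest
    integer (half away from zero; ``rounding='floor'`` selects a floor
    convention instead) and clamped to [0, n_segments].
    """
    protocol = protocol or ScanProtocol()
    if psc_loc <= 0:
        raise CalibrationError(f"psc_loc must be > 0, got {psc_loc}")
    cont = psc_nf / (protocol.segment_fraction * psc_loc)
    if rounding == "nearest":
        seg = _round_half_away(cont)
    elif rounding == "floor":
        seg = int(np.floor(cont))
    else:
        raise DesignError(f"unknown rounding convention {rounding!r}")
    return max(0, min(protocol.n_segments, seg))


def target_segments(level: str, protocol: ScanProtocol | None = None) -> int:
    """Thermometer segment count of a target level (low -> 5, high -> 10)."""
    protocol = protocol or ScanProtocol()
    if level == "low":
        frac = protocol.low_target_fraction
    elif level == "high":
        frac = protocol.high_target_fraction
    else:
        raise DesignError(f"unknown level {level!r}")
    return _round_half_away(frac / protocol.segment_fraction)


def run_feedback_engine(
    series: RoiTimeSeries | np.ndarray,
    design: RunDesign,
    calibration: Calibration,
    protocol: ScanProtocol | None = None,
    rounding: str = "nearest",
    window: str = "causal",
) -> FeedbackTrace:
    """Causal pass over a run, emitting the online feedback state per TR.

    At each rest-to-task transition the baseline is set from the last 10
    volumes of the completed rest block.  During task blocks ``val`` is the
    mean of the last three acquired volumes, which at the first two task
    volumes straddles the block boundary (``window='causal'``, the
    behaviour of the online system); ``window='block'`` instead restarts
    the moving average at block onset, using however many block volumes
    have been acquired.  Rest volumes carry no segments.
    """
    protocol = protocol or ScanProtocol()
    values = series.values if isinstance(series, RoiTimeSeries) else np.asarray(series, float)
    if len(values) != design.total_volumes:
        raise DataError(
            f"series length {len(values)} != design volumes {design.total_volumes}"
        )
    if design.blocks[0].block_type != "rest":
        raise DataError("feedback runs must begin with a rest block")
    if window not in ("causal", "block"):
        raise DesignError(f"unknown window convention {window!r}")

    psc_loc = calibration.psc_loc[calibration.region]
    samples: list[FeedbackSample] = []
    baseline: float | None = None
    for block in design.blocks:
        if block.block_type == "rest":
            for k in range(block.onset_volume, block.onset_volume + block.n_volumes):
                samples.append(FeedbackSample(k, "rest", None, None, None, None, None))
            baseline = compute_baseline(
                values[block.onset_volume : block.onset_volume + block.n_volumes]
            )
        else:
            if baseline is None:
                raise DataError("task block encountered before any rest block")
            tgt = target_segments(block.block_type, protocol)
            for k in range(block.onset_volume, block.onset_volume + block.n_volumes):
                if window == "causal":
                    last = values[k - VAL_WINDOW + 1 : k + 1]
                else:
                    start = max(block.onset_volume, k - VAL_WINDOW + 1)
                    last = values[start : k + 1]
                val = float(np.mean(last))
                psc = (val - baseline) * 100.0 / baseline
                seg = map_to_segments(psc, psc_loc, protocol, rounding)
                samples.append(
                    FeedbackSample(k, block.block_type, val, baseline, psc, seg, tgt)
                )
    return FeedbackTrace(samples, calibration, calibration.region)


def online_mean_psc(
    trace: FeedbackTrace, level: str, plateau_volumes: int | None = None
) -> float:
    """Mean online PSC over all task volumes of a level.

    ``plateau_volumes`` restricts the average to the last N volumes of each
    block (where the hemodynamic response has plateaued).
    """
    if level not in LEVELS:
        raise DesignError(f"unknown level {level!r}")
    samples = trace.task_samples(level)
    if not samples:
        raise DesignError(f"trace contains no {level!r} blocks")
    if plateau_volumes is not None:
        # keep the last N samples of each contiguous block
        blocks: list[list[FeedbackSample]] = []
        for s in samples:
            if blocks and s.volume_index == blocks[-1][-1].volume_index + 1:
                blocks[-1].append(s)
            else:
                blocks.append([s])
        samples = [s for b in blocks for s in b[-plateau_volumes:]]
    return float(np.mean([s.psc_nf for s in samples]))
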