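"""Run/block designs for the graded neurofeedback experiment.

The experiment's temporal skeleton: a motor-execution localizer run and
neurofeedback (NF) runs, both block designs sampled at a fixed TR.  An NF
run is five 20-volume rest blocks interleaved with four 20-volume task
blocks, two at the *low* target level and two at the *high* level; the
localizer alternates five rest and four task blocks of 16 volumes each.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError

REGIONS = ("SMA", "M1")
LEVELS = ("low", "high")

#: block volume counts used by the study
NF_BLOCK_VOLUMES = 20
LOC_BLOCK_VOLUMES = 16
N_NF_TASK_BLOCKS = 4
N_LOC_TASK_BLOCKS = 4


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition and feedback-display constants.

    Parameters
    ----------
    tr_seconds
        Repetition time (sampling interval) of the BOLD series, seconds.
    n_segments
        Number of segments in the thermometer display.
    segment_fraction
        Fraction of the localizer percent signal change (PSC_LOC)
        represented by one thermometer segment.
    low_target_fraction, high_target_fraction
        Target levels as fractions of PSC_LOC.
    """

    tr_seconds: float = 1.55
    n_segments: int = 15
    segment_fraction: float = 0.10
    low_target_fraction: float = 0.50
    high_target_fraction: float = 1.00

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise DesignError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if self.n_segments < 1:
            raise DesignError(f"n_segments must be >= 1, got {self.n_segments}")
        if not 0 < self.segment_fraction <= 1:
            raise DesignError(
                f"segment_fraction must be in (0, 1], got {self.segment_fraction}"
            )
        if not 0 < self.low_target_fraction < self.high_target_fraction:
            raise DesignError(
                "target fractions must satisfy 0 < low < high, got "
                f"low={self.low_target_fraction}, high={self.high_target_fraction}"
            )


@dataclass(frozen=True)
class Block:
    """One contiguous block of volumes of a single type."""

    block_type: str  # 'rest', 'task', 'low' or 'high'
    n_volumes: int
    onset_volume: int  # 0-based index of the first volume

    def __post_init__(self) -> None:
        if self.block_type not in ("rest", "task") + LEVELS:
            raise DesignError(f"unknown block type {self.block_type!r}")
        if self.n_volumes < 1:
            raise DesignError(f"n_volumes must be >= 1, got {self.n_volumes}")


@dataclass(frozen=True)
class RunDesign:
    """An ordered tiling of blocks covering one run."""

    run_kind: str  # 'localizer' or 'neurofeedback'
    blocks: tuple[Block, ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        expected_onset = 0
        for blk in self.blocks:
            if blk.onset_volume != expected_onset:
                raise DesignError(
                    f"blocks must tile the run; block at volume {blk.onset_volume} "
                    f"expected at {expected_onset}"
                )
            expected_onset += blk.n_volumes

    @property
    def total_volumes(self) -> int:
        return sum(b.n_volumes for b in self.blocks)

    @property
    def duration_seconds(self) -> float:
        return self.total_volumes * self.tr_seconds

    @property
    def task_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.block_type != "rest")

    @property
    def level_order(self) -> tuple[str, ...]:
        return tuple(b.block_type for b in self.task_blocks)

    def labels(self) -> np.ndarray:
        """Per-volume block-type label array of length ``total_volumes``."""
        out = np.empty(self.total_volumes, dtype=object)
        for b in self.blocks:
            out[b.onset_volume : b.onset_volume + b.n_volumes] = b.block_type
        return out

    def boxcar(self, block_types: Sequence[str]) -> np.ndarray:
        """Per-volume 0/1 indicator for the given block types."""
        lab = self.labels()
        return np.isin(lab, list(block_types)).astype(float)


@dataclass(frozen=True)
class NfRun:
    """One neurofeedback run within a session: its target region and design."""

    target_region: str
    design: RunDesign


@dataclass(frozen=True)
class SessionPlan:
    """Per-subject session: one localizer followed by 5 NF runs per region."""

    subject_id: str
    region_order: tuple[str, str]
    localizer: RunDesign
    nf_runs: tuple[NfRun, ...]

    def __post_init__(self) -> None:
        if sorted(self.region_order) != sorted(REGIONS):
            raise DesignError(f"region_order must be a permutation of {REGIONS}")

    def runs_for_region(self, region: str) -> tuple[NfRun, ...]:
        return tuple(r for r in self.nf_runs if r.target_region == region)


def _alternating_blocks(
    n_task: int, block_volumes: int, task_labels: Sequence[str]
) -> tuple[Block, ...]:
    blocks: list[Block] = []
    onset = 0
    labels = iter(task_labels)
    for i in range(2 * n_task + 1):
        btype = "rest" if i % 2 == 0 else next(labels)
        blocks.append(Block(btype, block_volumes, onset))
        onset += block_volumes
    return tuple(blocks)


def build_nf_run(
    protocol: ScanProtocol,
    level_order: Sequence[str] = ("low", "high", "low", "high"),
    block_volumes: int = NF_BLOCK_VOLUMES,
) -> RunDesign:
    """Build a neurofeedback run: 5 rest + 4 task blocks of 20 volumes.

    ``level_order`` gives the levels of the four task blocks in temporal
    order and must contain 'low' twice and 'high' twice.
    """
    if sorted(level_order) != ["high", "high", "low", "low"]:
        bad = [x for x in level_order if x not in LEVELS]
        if bad:
            raise DesignError(f"unknown level label {bad[0]!r} in level_order")
        raise DesignError(
            f"level_order must contain 'low' twice and 'high' twice, got {tuple(level_order)}"
        )
    blocks = _alternating_blocks(N_NF_TASK_BLOCKS, block_volumes, level_order)
    return RunDesign("neurofeedback", blocks, protocol.tr_seconds)


def build_localizer_run(
    protocol: ScanProtocol,
    n_task_blocks: int = N_LOC_TASK_BLOCKS,
    block_volumes: int = LOC_BLOCK_VOLUMES,
    padding_volumes: int = 0,
) -> RunDesign:
    """Build a motor-execution localizer run: alternating rest/task blocks.

    ``padding_volumes`` appends extra rest volumes at the end of the run;
    the default of 0 yields the bare 4-task/5-rest tiling (144 volumes).
    """
    if n_task_blocks < 1:
        raise DesignError(f"n_task_blocks must be >= 1, got {n_task_blocks}")
    if block_volumes < 1:
        raise DesignError(f"block_volumes must be >= 1, got {block_volumes}")
    if padding_volumes < 0:
        raise DesignError(f"padding_volumes must be >= 0, got {padding_volumes}")
    blocks = list(_alternating_blocks(n_task_blocks, block_volumes, ["task"] * n_task_blocks))
    if padding_volumes:
        onset = blocks[-1].onset_volume + blocks[-1].n_volumes
        blocks.append(Block("rest", padding_volumes, onset))
    return RunDesign("localizer", tuple(blocks), protocol.tr_seconds)


# the six orderings of two 'low' and two 'high' task blocks, split by which
# level comes first -- the unit of level-order counterbalancing
_LOW_FIRST = (
    ("low", "low", "high", "high"),
    ("low", "high", "low", "high"),
    ("low", "high", "high", "low"),
)
_HIGH_FIRST = tuple(
    tuple("high" if x == "low" else "low" for x in o) for o in _LOW_FIRST
)


def assign_counterbalancing(
    n_subjects: int,
    seed: int,
    protocol: ScanProtocol | None = None,
    n_runs_per_region: int = 5,
) -> list[SessionPlan]:
    """Build counterbalanced session plans for a cohort.

    Region order alternates across consecutive subjects (subject 1 trains
    SMA first).  Within each subject, each region's runs draw level orders
    so that 'low'-first and 'high'-first runs differ in count by at most
    one; the draw is deterministic for a given ``seed``.
    """
    if n_subjects < 1:
        raise DesignError(f"n_subjects must be >= 1, got {n_subjects}")
    protocol = protocol or ScanProtocol()
    rng = np.random.default_rng(seed)
    localizer = build_localizer_run(protocol)
    plans = []
    for i in range(n_subjects):
        region_order = REGIONS if i % 2 == 0 else tuple(reversed(REGIONS))
        nf_runs: list[NfRun] = []
        for region in region_order:
            # near-equal split between low-first and high-first runs
            n_low_first = n_runs_per_region // 2 + (
                int(rng.integers(2)) if n_runs_per_region % 2 else 0
            )
            starts = ["low"] * n_low_first + ["high"] * (n_runs_per_region - n_low_first)
            rng.shuffle(starts)
            for start in starts:
                pool = _LOW_FIRST if start == "low" else _HIGH_FIRST
                order = pool[int(rng.integers(len(pool)))]
                nf_runs.append(NfRun(region, build_nf_run(protocol, order)))
        plans.append(
            SessionPlan(f"sub-{i + 1:02d}", tuple(region_order), localizer, tuple(nf_runs))
        )
    return plans


def write_events_tsv(design: RunDesign, path: str | Path) -> Path:
    """Serialize a run design as a BIDS-style events table.

    Columns: onset (s), duration (s), trial_type; onsets are
    ``onset_volume * TR`` (0-based volume indexing, no slice-timing offset).
    """
    path = Path(path)
    rows = [
        {
            "onset": b.onset_volume * design.tr_seconds,
            "duration": b.n_volumes * design.tr_seconds,
            "trial_type": b.block_type,
        }
        for b in design.blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path, tr_seconds: float) -> RunDesign:
    """Parse an events table written by :func:`write_events_tsv`."""
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for _, row in df.iterrows():
        onset_vol = int(round(row["onset"] / tr_seconds))
        n_vol = int(round(row["duration"] / tr_seconds))
        blocks.append(Block(str(row["trial_type"]), n_vol, onset_vol))
    run_kind = "localizer" if any(b.block_type == "task" for b in blocks) else "neurofeedback"
    return RunDesign(run_kind, tuple(blocks), tr_seconds)
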