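"""Behavioural metrics from detection samples.

A standard assay is 180 s sampled at 0.1 s (1800 samples).  The first 5 s is
discarded while the background model acclimatises; the remaining 175 s is
aggregated into 35 five-second epochs of activity, stratified into the upper
(UHC) and lower (LHC) halves of the cone.  Activity is counted in
mosquito-samples: each detected moving mosquito in each 0.1-s sample
contributes one count, so a test of five continuously active mosquitoes tops
out at 5 x 1750 = 8750.  The strict resting statistic counts samples in
which *no* mosquito moved relative to the previous sample, over the full
1800-sample record (the per-sample complement 5 - n only infers inactivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geometry import UPPER, RegionGeometry
from .segmentation import DetectionSample

#: analysis sampling interval (s)
SAMPLE_INTERVAL = 0.1
#: acclimatisation window discarded from epoch aggregation (s)
ACCLIMATISATION = 5.0
#: epoch length (s)
EPOCH_LENGTH = 5.0
#: number of epochs in a standard assay
N_EPOCHS = 35
#: expected samples in a standard 180-s assay
EXPECTED_SAMPLES = 1800
#: mosquitoes per cone test
CONE_OCCUPANCY = 5


class AssayTooShortError(ValueError):
    """The sample record does not span the full epoch schedule."""


@dataclass(frozen=True)
class EpochSummary:
    """Activity totals for one 5-s aggregation window."""

    index: int  # 1..35
    t_start: float
    t_end: float
    activity_total: int
    activity_upper: int
    activity_lower: int
    inactive_samples: int
    valid_samples: int


@dataclass(frozen=True)
class AssayMetrics:
    """Whole-test behavioural summary.

    ``total_activity`` (and its regional split) is the epoch-based total over
    the 35 aggregation windows; ``total_activity_full`` additionally counts
    the acclimatisation window and is emitted as an auxiliary column.
    ``prop_lower`` is NaN (never 0) when there was no activity.
    ``resting_frames`` is counted over the full sample record including the
    acclimatisation overlap.
    """

    assay_id: str
    total_activity: int
    upper_activity: int
    lower_activity: int
    prop_lower: float
    inactive_frames: int
    resting_frames: int
    resting_seconds: float
    valid_frames_proportion: float
    total_activity_full: int


def sample_slot(t: float, interval: float = SAMPLE_INTERVAL) -> int:
    """Integer sample index of a timestamp (robust to float representation)."""
    return int(round(t / interval))


def assign_region(blob, geometry: RegionGeometry) -> str:
    """Region of a blob centroid: ``upper`` iff y < split_line_y, else lower.

    A centroid exactly on the split line counts as lower.  Raises if the
    centroid is outside the cone ROI (``extract_movers`` guarantees
    containment for pipeline-produced blobs).
    """
    x, y = blob.centroid
    if not geometry.contains(x, y):
        raise ValueError(f"blob centroid ({x:.1f}, {y:.1f}) outside the cone ROI")
    return geometry.region_of(y)


def aggregate_epochs(
    samples: Sequence[DetectionSample],
    geometry: RegionGeometry,
    *,
    interval: float = SAMPLE_INTERVAL,
    start: float = ACCLIMATISATION,
    epoch_length: float = EPOCH_LENGTH,
    n_epochs: int = N_EPOCHS,
) -> list[EpochSummary]:
    """Aggregate samples into the epoch schedule (default: 35 x 5 s from t=5).

    Windows are half-open [start + k*L, start + (k+1)*L).  Invalid samples
    are excluded from both activity and inactivity counts but the schedule
    itself must be fully covered, otherwise :class:`AssayTooShortError`.
    """
    if not samples:
        raise AssayTooShortError("no samples")
    span = samples[-1].t + interval
    needed = start + n_epochs * epoch_length
    if span + 1e-9 < needed:
        raise AssayTooShortError(
            f"samples span {span:.1f} s but the epoch schedule needs {needed:.0f} s"
        )
    per_epoch = int(round(epoch_length / interval))
    start_slot = sample_slot(start, interval)
    totals = [[0, 0, 0, 0, 0] for _ in range(n_epochs)]  # up, low, total, inactive, valid
    for s in samples:
        slot = sample_slot(s.t, interval)
        e = (slot - start_slot) // per_epoch
        if slot < start_slot or e >= n_epochs:
            continue
        if not s.valid:
            continue
        row = totals[e]
        row[4] += 1
        if s.n_moving == 0:
            row[3] += 1
        for b in s.blobs:
            if assign_region(b, geometry) == UPPER:
                row[0] += 1
            else:
                row[1] += 1
        row[2] = row[0] + row[1]
    out = []
    for k, (up, low, tot, inact, valid) in enumerate(totals):
        out.append(
            EpochSummary(
                index=k + 1,
                t_start=start + k * epoch_length,
                t_end=start + (k + 1) * epoch_length,
                activity_total=tot,
                activity_upper=up,
                activity_lower=low,
                inactive_samples=inact,
                valid_samples=valid,
            )
        )
    return out


def resting_frames(samples: Sequence[DetectionSample]) -> int:
    """Strict resting count: valid samples in which no mosquito moved.

    The first sample has no predecessor to move relative to and is excluded;
    the count otherwise runs over the full record (all 1800 samples of a
    standard test, acclimatisation overlap included).
    """
    if len(samples) < 2:
        raise ValueError("resting needs at least two samples")
    return sum(1 for s in samples[1:] if s.valid and s.n_moving == 0)


def inferred_inactivity(sample: DetectionSample | int,
                        occupancy: int = CONE_OCCUPANCY) -> int:
    """Inactive mosquitoes inferred per sample as occupancy minus movers (5 - n)."""
    n = sample if isinstance(sample, int) else sample.n_moving
    if n > occupancy:
        raise ValueError(f"n_moving={n} exceeds cone occupancy {occupancy}")
    return occupancy - n


def summarize_assay(
    epochs: Sequence[EpochSummary],
    samples: Sequence[DetectionSample],
    *,
    assay_id: str = "assay",
    expected_samples: int | None = None,
) -> AssayMetrics:
    """Reduce epochs + samples to whole-test metrics."""
    if len(epochs) != N_EPOCHS:
        raise ValueError(f"expected {N_EPOCHS} epochs, got {len(epochs)}")
    upper = sum(e.activity_upper for e in epochs)
    lower = sum(e.activity_lower for e in epochs)
    total = sum(e.activity_total for e in epochs)
    inactive = sum(e.inactive_samples for e in epochs)
    rest = resting_frames(samples)
    n_expected = expected_samples if expected_samples is not None else max(
        EXPECTED_SAMPLES, len(samples)
    )
    n_valid = sum(1 for s in samples if s.valid)
    full_total = sum(s.n_moving for s in samples if s.valid)
    return AssayMetrics(
        assay_id=assay_id,
        total_activity=total,
        upper_activity=upper,
        lower_activity=lower,
        prop_lower=lower / total if total > 0 else math.nan,
        inactive_frames=inactive,
        resting_frames=rest,
        resting_seconds=rest * SAMPLE_INTERVAL,
        valid_frames_proportion=n_valid / n_expected,
        total_activity_full=full_total,
    )


# ---------------------------------------------------------------------------
# tabular output

EPOCH_COLUMNS = [
    "assay_id", "epoch", "t_start", "t_end", "activity_total",
    "activity_upper", "activity_lower", "inactive_samples", "valid_samples",
]

METRICS_COLUMNS = [
    "assay_id", "total_activity", "upper_activity", "lower_activity",
    "prop_lower", "inactive_frames", "resting_frames", "resting_seconds",
    "valid_frames_proportion", "total_activity_full",
]


def epochs_to_table(epochs: Sequence[EpochSummary], assay_id: str = "assay") -> pd.DataFrame:
    return pd.DataFrame(
        [
            (assay_id, e.index, e.t_start, e.t_end, e.activity_total,
             e.activity_upper, e.activity_lower, e.inactive_samples, e.valid_samples)
            for e in epochs
        ],
        columns=EPOCH_COLUMNS,
    )


def metrics_to_table(metrics: Sequence[AssayMetrics] | AssayMetrics) -> pd.DataFrame:
    if isinstance(metrics, AssayMetrics):
        metrics = [metrics]
    return pd.DataFrame(
        [
            (m.assay_id, m.total_activity, m.upper_activity, m.lower_activity,
             m.prop_lower, m.inactive_frames, m.resting_frames, m.resting_seconds,
             m.valid_frames_proportion, m.total_activity_full)
            for m in metrics
        ],
        columns=METRICS_COLUMNS,
    )
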