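"""Standard-frame construction: peak-delimited segments to fixed-length vectors.

Every fiducial-delimited segment — R to T, T to the next R, and their
concatenations — is resampled uniformly onto 50 points by linear
interpolation, so a cycle becomes 100 samples (R-R or T-T anchored) and n
consecutive cycles become 100*n, regardless of the instantaneous heart
rate.  Segments follow a half-open convention [start, end): each segment
owns its starting fiducial and stops one query short of the shared ending
fiducial, so concatenated segments never duplicate boundary samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError, InsufficientFiducialsError
from .peaks import FiducialSet
from .synthetic import RawRecording

__all__ = [
    "SegmentType",
    "StandardFrame",
    "SAMPLES_PER_SEGMENT",
    "resample_segment",
    "build_frame",
    "extract_frames",
]

#: Every fiducial-delimited sub-segment is mapped onto this many points.
SAMPLES_PER_SEGMENT = 50


class SegmentType(str, Enum):
    """Which fiducial-delimited portion of each cycle enters the frame."""

    RR = "RR"  # R_j -> T_j -> R_{j+1}: two sub-segments, 100 samples/cycle
    TT = "TT"  # T_j -> R_{j+1} -> T_{j+1}: two sub-segments, 100 samples/cycle
    RT = "RT"  # R_j -> T_j only: 50 samples/cycle
    TR = "TR"  # T_j -> R_{j+1} only: 50 samples/cycle

    @property
    def segments_per_cycle(self) -> int:
        return 2 if self in (SegmentType.RR, SegmentType.TT) else 1

    @property
    def samples_per_cycle(self) -> int:
        return self.segments_per_cycle * SAMPLES_PER_SEGMENT


@dataclass
class StandardFrame:
    """A fixed-length pattern vector spanning n_cycles consecutive cycles."""

    values: np.ndarray
    n_cycles: int
    segment_type: SegmentType
    subject_id: str
    record_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.segment_type.samples_per_cycle * self.n_cycles
        if self.n_cycles < 1 or len(self.values) != expected:
            raise ConfigurationError(
                f"{self.segment_type.value} frame of {self.n_cycles} cycles must have "
                f"{expected} samples, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("frame values must be finite")


def resample_segment(
    signal: np.ndarray,
    start_idx: int,
    end_idx: int,
    n_out: int = SAMPLES_PER_SEGMENT,
) -> np.ndarray:
    """Uniformly resample signal[start_idx:end_idx) onto n_out points.

    Query positions span the half-open segment: the first query falls on
    start_idx, the last strictly before end_idx.  A segment already n_out
    samples long is returned unchanged.
    """
    if n_out < 2:
        raise ConfigurationError("n_out must be >= 2")
    if end_idx - start_idx < 2:
        raise ConfigurationError(
            f"degenerate segment [{start_idx}, {end_idx}): need at least 2 samples"
        )
    signal = np.asarray(signal, dtype=float)
    if not (0 <= start_idx and end_idx <= len(signal)):
        raise ConfigurationError("segment exceeds signal bounds")
    pos = start_idx + (end_idx - start_idx) * np.arange(n_out) / n_out
    base = np.arange(start_idx, end_idx)
    return np.interp(pos, base, signal[start_idx:end_idx])


def _cycle_segments(
    fid: FiducialSet, j: int, seg: SegmentType
) -> list[tuple[int, int]]:
    """(start, end) sample index pairs contributed by cycle j."""
    r, t = fid.r_indices, fid.t_indices
    if seg is SegmentType.RR:
        return [(r[j], t[j]), (t[j], r[j + 1])]
    if seg is SegmentType.TT:
        return [(t[j], r[j + 1]), (r[j + 1], t[j + 1])]
    if seg is SegmentType.RT:
        return [(r[j], t[j])]
    return [(t[j], r[j + 1])]


def _cycles_required(n_cycles: int, seg: SegmentType) -> int:
    # a TT window additionally needs the T peak of the following cycle
    return n_cycles + 1 if seg is SegmentType.TT else n_cycles


def build_frame(
    rec: RawRecording,
    fid: FiducialSet,
    cycle_start: int,
    n_cycles: int,
    seg: SegmentType,
) -> StandardFrame:
    """Concatenate the resampled segments of n_cycles consecutive cycles."""
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    need = _cycles_required(n_cycles, seg)
    if cycle_start < 0 or cycle_start + need > fid.n_cycles:
        raise InsufficientFiducialsError(
            f"record {rec.subject_id}/{rec.record_id}: cycles "
            f"[{cycle_start}, {cycle_start + need}) not available"
        )
    if not fid.cycle_valid[cycle_start : cycle_start + need].all():
        raise InsufficientFiducialsError(
            f"record {rec.subject_id}/{rec.record_id}: window starting at cycle "
            f"{cycle_start} spans an invalid cycle"
        )
    parts = []
    for j in range(cycle_start, cycle_start + n_cycles):
        for a, b in _cycle_segments(fid, j, seg):
            parts.append(resample_segment(rec.samples, a, b))
    return StandardFrame(
        np.concatenate(parts), n_cycles, seg, rec.subject_id, rec.record_id
    )


def extract_frames(
    rec: RawRecording,
    fid: FiducialSet,
    n_cycles: int,
    seg: SegmentType = SegmentType.RR,
) -> list[StandardFrame]:
    """All stride-1 windows of n_cycles cycles within maximal valid runs."""
    need = _cycles_required(n_cycles, seg)
    frames: list[StandardFrame] = []
    for run_start, run_stop in fid.valid_runs():
        for c in range(run_start, run_stop - need + 1):
            frames.append(build_frame(rec, fid, c, n_cycles, seg))
    if not frames:
        warnings.warn(
            f"record {rec.subject_id}/{rec.record_id}: no complete "
            f"{n_cycles}-cycle {seg.value} window",
            stacklevel=2,
        )
    return frames
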