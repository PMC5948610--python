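"""R and T fiducial detection.

R peaks: the cleaned signal is differentiated, squared, and smoothed with a
short moving average — an emphasis signal whose bursts mark the steep QRS
slopes.  Candidate regions above a fixed fraction of the record's emphasis
maximum are refined to the argmax of the *original* signal (the emphasis
operator distorts timing), and a refractory period suppresses double fires
on the two slopes of a single QRS.

T peaks: within each R-R cycle, the T wave is the largest positive peak
once guard bands around both R peaks are excluded.  Cycles whose window
maximum is not an interior local maximum are flagged invalid rather than
imputed; downstream frame windows never span them.

All indices are 0-based sample positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientCyclesError
from .synthetic import RawRecording

__all__ = [
    "DetectorConfig",
    "FiducialSet",
    "emphasize",
    "detect_r_peaks",
    "detect_t_peaks",
    "extract_fiducials",
]


@dataclass(frozen=True)
class DetectorConfig:
    ma_order: int = 5
    threshold_frac: float = 0.35
    refractory: float = 0.25
    r_blank: float = 0.10

    def __post_init__(self) -> None:
        if self.ma_order < 1:
            raise ConfigurationError("ma_order must be >= 1")
        if not (0 < self.threshold_frac < 1):
            raise ConfigurationError("threshold_frac must be in (0, 1)")
        if self.refractory <= 0:
            raise ConfigurationError("refractory must be positive")
        if self.r_blank < 0:
            raise ConfigurationError("r_blank must be >= 0")


@dataclass
class FiducialSet:
    """Detected fiducials of one recording.

    ``t_indices`` holds exactly one entry per adjacent R pair; cycles where
    no valid interior T exists are marked False in ``cycle_valid`` and carry
    a sentinel -1.  For every valid cycle j:
    r_indices[j] < t_indices[j] < r_indices[j+1].
    """

    r_indices: np.ndarray
    t_indices: np.ndarray
    cycle_valid: np.ndarray

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        self.t_indices = np.asarray(self.t_indices, dtype=int)
        self.cycle_valid = np.asarray(self.cycle_valid, dtype=bool)
        r, t, v = self.r_indices, self.t_indices, self.cycle_valid
        if len(t) != max(len(r) - 1, 0) or len(v) != len(t):
            raise ConfigurationError("need exactly one T slot per adjacent R pair")
        if np.any(np.diff(r) <= 0):
            raise ConfigurationError("r_indices must be strictly increasing")
        for j in np.nonzero(v)[0]:
            if not (r[j] < t[j] < r[j + 1]):
                raise ConfigurationError(
                    f"cycle {j}: T index {t[j]} not inside ({r[j]}, {r[j + 1]})"
                )

    @property
    def n_cycles(self) -> int:
        return len(self.t_indices)

    def valid_runs(self) -> list[tuple[int, int]]:
        """Maximal runs [start, stop) of consecutive valid cycles."""
        runs: list[tuple[int, int]] = []
        start = None
        for j, ok in enumerate(self.cycle_valid):
            if ok and start is None:
                start = j
            elif not ok and start is not None:
                runs.append((start, j))
                start = None
        if start is not None:
            runs.append((start, self.n_cycles))
        return runs


def emphasize(signal: np.ndarray, ma_order: int = 5) -> np.ndarray:
    """Squared first difference, smoothed by a centered moving average.

    Output has length len(signal) - 1; element i sits on the slope between
    samples i and i+1.  Edge windows are averaged over the available
    samples only.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < ma_order + 2:
        raise ConfigurationError("signal too short for the emphasis operator")
    sq = np.diff(signal) ** 2
    m = len(sq)
    half = (ma_order - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    lo = np.clip(np.arange(m) - half, 0, m)
    hi = np.clip(np.arange(m) - half + ma_order, 0, m)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_r_peaks(rec: RawRecording, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Locate R peaks; returns a sorted array of sample indices."""
    sig = rec.samples
    emph = emphasize(sig, cfg.ma_order)
    peak = emph.max()
    if peak <= 0:
        warnings.warn("flat signal: no R peaks detected", stacklevel=2)
        return np.empty(0, dtype=int)
    above = emph > cfg.threshold_frac * peak
    if not above.any():
        warnings.warn("no emphasis region above threshold", stacklevel=2)
        return np.empty(0, dtype=int)

    # contiguous True runs in the emphasis signal
    bounds = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    region_starts, region_stops = bounds[0::2], bounds[1::2]

    # a QRS complex fires the emphasis on both its slopes with a dip at the
    # R peak itself; runs closer than the refractory period belong to one
    # peak and are merged before localization
    refr = int(round(cfg.refractory * rec.fs))
    merged: list[list[int]] = []
    for a, b in zip(region_starts, region_stops):
        if merged and a - merged[-1][1] < refr:
            merged[-1][1] = b
        else:
            merged.append([int(a), int(b)])

    accepted: list[int] = []
    n = len(sig)
    for a, b in merged:
        # emphasis run [a, b) covers slopes between samples a .. b, so the
        # source peak lies within signal[a : b + 1] — except when only one
        # QRS slope cleared the threshold, leaving the peak just outside;
        # hill-climb to the adjacent local maximum of the original signal
        cand = a + int(np.argmax(sig[a : b + 1]))
        while cand > 0 and sig[cand - 1] > sig[cand]:
            cand -= 1
        while cand < n - 1 and sig[cand + 1] > sig[cand]:
            cand += 1
        if accepted and cand - accepted[-1] < refr:
            if sig[cand] > sig[accepted[-1]]:
                accepted[-1] = cand
        else:
            accepted.append(cand)
    return np.asarray(accepted, dtype=int)


def detect_t_peaks(
    rec: RawRecording, r_indices: np.ndarray, cfg: DetectorConfig = DetectorConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Locate one T per adjacent R pair; returns (t_indices, cycle_valid).

    The search window excludes r_blank guard bands after/before the
    delimiting R peaks so QRS flanks cannot masquerade as T.  Ties at the
    maximum resolve to the earliest index.  A cycle is invalid when the
    window is empty or its maximum is not an interior local maximum.
    """
    if len(r_indices) < 2:
        raise InsufficientCyclesError("need at least two R peaks to search for T")
    sig = rec.samples
    nb = int(round(cfg.r_blank * rec.fs))
    t_out = np.full(len(r_indices) - 1, -1, dtype=int)
    valid = np.zeros(len(r_indices) - 1, dtype=bool)
    for j in range(len(r_indices) - 1):
        lo, hi = r_indices[j] + nb, r_indices[j + 1] - nb  # window [lo, hi)
        if hi - lo < 3:
            continue
        t = lo + int(np.argmax(sig[lo:hi]))
        if lo < t < hi - 1:  # interior => rises before, falls after
            t_out[j] = t
            valid[j] = True
    return t_out, valid


def extract_fiducials(
    rec: RawRecording, cfg: DetectorConfig = DetectorConfig()
) -> FiducialSet:
    """Full fiducial extraction: R detection then per-cycle T search."""
    r = detect_r_peaks(rec, cfg)
    if len(r) < 2:
        raise InsufficientCyclesError(
            f"record {rec.subject_id}/{rec.record_id}: fewer than 2 R peaks detected"
        )
    t, valid = detect_t_peaks(rec, r, cfg)
    if not valid.any():
        raise InsufficientCyclesError(
            f"record {rec.subject_id}/{rec.record_id}: no valid cycles"
        )
    return FiducialSet(r, t, valid)
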