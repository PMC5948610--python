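"""Synthetic multi-subject ECG corpora with exact fiducial ground truth.

Each subject is a morphology: five Gaussian bumps (P, Q, R, S, T) placed
relative to the R peak, plus first-order RR statistics.  A beat drawn at
RR interval ``rr`` is the morphology time-warped by ``rr / rr_mean`` —
wave centers and widths scale proportionally with the cycle length, so a
fast heart merely compresses the waveform.  Under that model, peak-to-peak
resampling to a fixed-length frame is (up to interpolation error) invariant
to heart rate, which makes the downstream standard-frame stage testable
against a known-invariant generator.

Wave centers are quantized to the sample grid at render time and those
integers are reported as ground truth, so fiducial localization error of
the detector can be measured exactly.

Recordings are rendered as a global superposition of all beats' Gaussians
(tails spill smoothly into neighboring beats; no splice discontinuities),
then corrupted with white, powerline, and baseline-wander noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConfigurationError, DegenerateBeatError

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .peaks import FiducialSet

__all__ = [
    "WaveComponent",
    "SubjectMorphology",
    "NoiseConfig",
    "RawRecording",
    "CohortConfig",
    "NOISE_PRESETS",
    "DEFAULT_COHORT_CONFIG",
    "sample_subject_morphology",
    "render_beat",
    "simulate_recording",
    "simulate_cohort",
    "warp_reference_morphology",
]

WAVE_LABELS = ("P", "Q", "R", "S", "T")

# RR intervals outside this band are not physiologically plausible for the
# resting cohorts being emulated; draws are truncated to it.
RR_TRUNCATION = (0.4, 2.0)


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump of the P-QRS-T complex.

    amplitude is in millivolts (signed), center_offset in seconds relative
    to the R peak, width is the Gaussian standard deviation in seconds.
    """

    label: str
    amplitude: float
    center_offset: float
    width: float

    def __post_init__(self) -> None:
        if self.label not in WAVE_LABELS:
            raise ConfigurationError(f"unknown wave label {self.label!r}")
        if not self.width > 0:
            raise ConfigurationError(f"{self.label} wave width must be > 0")


@dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject generative parameters: five waves plus RR statistics."""

    subject_id: str
    waves: tuple[WaveComponent, ...]
    rr_mean: float
    rr_sd: float
    beat_jitter: float

    def __post_init__(self) -> None:
        if len(self.waves) != 5 or tuple(w.label for w in self.waves) != WAVE_LABELS:
            raise ConfigurationError("waves must be (P, Q, R, S, T) in order")
        p, q, r, s, t = self.waves
        if not (0.4 <= self.rr_mean <= 1.5):
            raise ConfigurationError(f"rr_mean {self.rr_mean} outside [0.4, 1.5]")
        if self.rr_sd < 0 or self.beat_jitter < 0:
            raise ConfigurationError("rr_sd and beat_jitter must be >= 0")
        centers = [w.center_offset for w in self.waves]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ConfigurationError("wave centers must be ordered P < Q < R < S < T")
        half = self.rr_mean / 2
        if not all(-half < c < half for c in centers):
            raise ConfigurationError("wave centers must lie within (-rr_mean/2, rr_mean/2)")
        if r.amplitude <= 0 or t.amplitude <= 0:
            raise ConfigurationError("R and T amplitudes must be positive")
        if q.amplitude > 0 or s.amplitude > 0:
            raise ConfigurationError("Q and S amplitudes must be <= 0")
        # R strictly dominant, T strictly the runner-up positive peak: the
        # premise of peak-delimited segmentation.
        positives = {w.label: w.amplitude for w in self.waves if w.amplitude > 0}
        if not (r.amplitude > t.amplitude and all(
            t.amplitude > a for lbl, a in positives.items() if lbl not in ("R", "T")
        )):
            raise ConfigurationError("amplitudes must satisfy R > T > other positive waves")

    @property
    def r_wave(self) -> WaveComponent:
        return self.waves[2]

    @property
    def t_wave(self) -> WaveComponent:
        return self.waves[4]


@dataclass(frozen=True)
class NoiseConfig:
    """Additive corruption model: broadband, mains hum, respiration-band drift."""

    white_sd: float = 0.0
    powerline_amp: float = 0.0
    powerline_hz: float = 60.0
    baseline_amp: float = 0.0
    baseline_hz: float = 0.15

    def __post_init__(self) -> None:
        for name in ("white_sd", "powerline_amp", "powerline_hz", "baseline_amp", "baseline_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


#: Electrode-site presets.  Finger contacts gave visibly cleaner traces than
#: wrist straps in the emulated acquisition setup, so the finger preset is the
#: wrist preset at reduced noise amplitudes; "clean" is noise-free.
NOISE_PRESETS: dict[str, NoiseConfig] = {
    "clean": NoiseConfig(),
    "wrist": NoiseConfig(white_sd=0.05, powerline_amp=0.05, baseline_amp=0.30),
    "finger": NoiseConfig(white_sd=0.02, powerline_amp=0.03, baseline_amp=0.20),
}


@dataclass
class RawRecording:
    """A single-channel voltage trace with its sampling rate and identity."""

    samples: np.ndarray
    fs: float
    subject_id: str
    record_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("samples must be finite")
        if len(self.samples) < 2 * self.fs:
            raise ConfigurationError("recording must be at least ~2 s long")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "RawRecording":
        return RawRecording(samples, self.fs, self.subject_id, self.record_id)


Range = tuple[float, float]


@dataclass(frozen=True)
class CohortConfig:
    """Uniform sampling ranges for per-subject morphology parameters.

    P and T timing/width are drawn as fractions of rr_mean (repolarization
    timing tracks cycle length); Q and S are drawn in absolute seconds (QRS
    geometry is comparatively rate-stable at rest).  Amplitudes in mV.
    """

    rr_mean: Range = (0.7, 1.1)
    rr_sd: Range = (0.01, 0.04)
    beat_jitter: Range = (0.005, 0.02)
    p_amp: Range = (0.08, 0.20)
    p_center_frac: Range = (-0.32, -0.26)
    p_width: Range = (0.025, 0.040)
    q_amp: Range = (-0.16, -0.06)
    q_center: Range = (-0.048, -0.032)
    q_width: Range = (0.010, 0.016)
    r_amp: Range = (0.9, 1.6)
    r_width: Range = (0.012, 0.020)
    s_amp: Range = (-0.30, -0.10)
    s_center: Range = (0.034, 0.048)
    s_width: Range = (0.012, 0.018)
    t_amp: Range = (0.25, 0.50)
    t_center_frac: Range = (0.28, 0.36)
    t_width_frac: Range = (0.055, 0.080)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            lo, hi = getattr(self, f.name)
            if lo > hi:
                raise ConfigurationError(f"invalid range for {f.name}: low {lo} > high {hi}")


DEFAULT_COHORT_CONFIG = CohortConfig()


def _draw(rng: np.random.Generator, r: Range) -> float:
    return float(rng.uniform(r[0], r[1]))


def sample_subject_morphology(
    seed: int,
    cohort_config: CohortConfig = DEFAULT_COHORT_CONFIG,
    subject_id: str | None = None,
) -> SubjectMorphology:
    """Draw one subject's generative parameters; deterministic per seed."""
    cfg = cohort_config
    rng = np.random.default_rng(seed)
    rr_mean = _draw(rng, cfg.rr_mean)
    waves = (
        WaveComponent("P", _draw(rng, cfg.p_amp), _draw(rng, cfg.p_center_frac) * rr_mean,
                      _draw(rng, cfg.p_width)),
        WaveComponent("Q", _draw(rng, cfg.q_amp), _draw(rng, cfg.q_center), _draw(rng, cfg.q_width)),
        WaveComponent("R", _draw(rng, cfg.r_amp), 0.0, _draw(rng, cfg.r_width)),
        WaveComponent("S", _draw(rng, cfg.s_amp), _draw(rng, cfg.s_center), _draw(rng, cfg.s_width)),
        WaveComponent("T", _draw(rng, cfg.t_amp), _draw(rng, cfg.t_center_frac) * rr_mean,
                      _draw(rng, cfg.t_width_frac) * rr_mean),
    )
    return SubjectMorphology(
        subject_id=subject_id if subject_id is not None else f"S{seed:04d}",
        waves=waves,
        rr_mean=rr_mean,
        rr_sd=_draw(rng, cfg.rr_sd),
        beat_jitter=_draw(rng, cfg.beat_jitter),
    )


def _jittered_waves(
    m: SubjectMorphology, rng: np.random.Generator | None
) -> list[tuple[float, float, float]]:
    """Per-beat (amplitude, center, width) with multiplicative jitter applied."""
    out = []
    for w in m.waves:
        amp, width = w.amplitude, w.width
        if m.beat_jitter > 0 and rng is not None:
            amp = amp * (1.0 + m.beat_jitter * rng.standard_normal())
            width = max(width * (1.0 + m.beat_jitter * rng.standard_normal()), 1e-4)
        out.append((amp, w.center_offset, width))
    return out


def _add_gaussian(buf: np.ndarray, center: float, sd: float, amp: float) -> None:
    """Accumulate amp * N(center, sd) into buf, windowed to +-6 sd for speed."""
    lo = max(int(np.floor(center - 6 * sd)), 0)
    hi = min(int(np.ceil(center + 6 * sd)) + 1, len(buf))
    if hi <= lo:
        return
    idx = np.arange(lo, hi, dtype=float)
    buf[lo:hi] += amp * np.exp(-0.5 * ((idx - center) / sd) ** 2)


def render_beat(
    m: SubjectMorphology, rr: float, fs: float, beat_seed: int = 0
) -> np.ndarray:
    """Render one isolated beat of length round(rr*fs), R wave at mid-beat.

    The morphology is time-warped by rr / rr_mean.  The global maximum is
    the R wave and the largest remaining positive local maximum the T wave.
    """
    if rr <= 0 or fs <= 0:
        raise ConfigurationError("rr and fs must be positive")
    n = int(round(rr * fs))
    if n < 10:
        raise DegenerateBeatError(f"beat of {n} samples is too short to render")
    scale = rr / m.rr_mean
    rng = np.random.default_rng(beat_seed) if m.beat_jitter > 0 else None
    r_idx = int(round(rr * fs / 2))
    out = np.zeros(n)
    for amp, center, width in _jittered_waves(m, rng):
        c = r_idx + round(center * scale * fs)  # integer sample grid
        _add_gaussian(out, c, width * scale * fs, amp)
    return out


def warp_reference_morphology(m: SubjectMorphology, grid: float = 0.01) -> SubjectMorphology:
    """Re-reference a morphology for heart-rate-sweep experiments.

    Returns a copy with rr_mean = 1 s, zero RR variance and jitter, and wave
    centers (as fractions of the cycle) snapped to a ``grid``-second lattice.
    With fs*grid and fs*rr integral, beats rendered at different
    ``rr_override`` values land on a common exact warp grid, so any residual
    difference between their standard frames is pure interpolation error —
    the quantity the resampling-invariance property is about — rather than
    sample-grid rounding of the render itself.
    """
    waves = tuple(
        dataclasses.replace(w, center_offset=round(w.center_offset / m.rr_mean / grid) * grid)
        for w in m.waves
    )
    return dataclasses.replace(m, waves=waves, rr_mean=1.0, rr_sd=0.0, beat_jitter=0.0)


def _draw_rr(rng: np.random.Generator, rr_mean: float, rr_sd: float) -> float:
    """Normal(rr_mean, rr_sd) truncated to the physiologic band by rejection."""
    if rr_sd == 0:
        return rr_mean
    lo, hi = RR_TRUNCATION
    for _ in range(1000):
        rr = rng.normal(rr_mean, rr_sd)
        if lo <= rr <= hi:
            return rr
    return float(np.clip(rr_mean, lo, hi))  # pragma: no cover


def simulate_recording(
    m: SubjectMorphology,
    duration: float = 10.0,
    fs: float = 500.0,
    noise: NoiseConfig = NOISE_PRESETS["clean"],
    seed: int = 0,
    record_id: str = "R00",
    rr_override: float | None = None,
) -> tuple[RawRecording, "FiducialSet"]:
    """Simulate one recording plus its exact fiducial ground truth.

    Beats are laid down back to back with RR drawn per beat (or pinned to
    ``rr_override``, useful for heart-rate sweeps of a fixed morphology) and
    rendered as a single Gaussian superposition.  Ground truth contains only
    beats fully inside the record window; T indices are reported per adjacent
    R pair.
    """
    from .peaks import FiducialSet  # local import to avoid a cycle

    if duration < 2 * m.rr_mean:
        raise ConfigurationError("duration must cover at least two mean cycles")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    signal = np.zeros(n_total)

    r_truth: list[int] = []
    t_truth: list[int] = []
    start = 0
    while start < n_total:
        rr = rr_override if rr_override is not None else _draw_rr(rng, m.rr_mean, m.rr_sd)
        n_beat = int(round(rr * fs))
        scale = rr / m.rr_mean
        r_idx = start + int(round(rr * fs / 2))
        beat_rng = np.random.default_rng(rng.integers(0, 2**31 - 1)) if m.beat_jitter > 0 else None
        complete = start + n_beat <= n_total
        for amp, center, width in _jittered_waves(m, beat_rng):
            c = r_idx + round(center * scale * fs)
            _add_gaussian(signal, c, width * scale * fs, amp)
        if complete:
            r_truth.append(int(r_idx))
            t_truth.append(int(r_idx + round(m.t_wave.center_offset * scale * fs)))
        start += n_beat

    t = np.arange(n_total) / fs
    if noise.white_sd > 0:
        signal = signal + rng.normal(0.0, noise.white_sd, n_total)
    if noise.powerline_amp > 0:
        signal = signal + noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.baseline_amp > 0:
        signal = signal + noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_hz * t + rng.uniform(0, 2 * np.pi)
        )

    rec = RawRecording(signal, fs, m.subject_id, record_id)
    r_arr = np.asarray(r_truth, dtype=int)
    # one T per adjacent R pair: the T of the earlier beat
    t_arr = np.asarray(t_truth[: max(len(r_truth) - 1, 0)], dtype=int)
    truth = FiducialSet(r_arr, t_arr, np.ones(len(t_arr), dtype=bool))
    return rec, truth


def simulate_cohort(
    n_subjects: int,
    n_records: int,
    cohort_config: CohortConfig = DEFAULT_COHORT_CONFIG,
    noise: NoiseConfig | str = "wrist",
    duration: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple["pd.DataFrame", dict[tuple[str, str], RawRecording], dict[tuple[str, str], "FiducialSet"]]:
    """Simulate n_subjects x n_records recordings; optionally write them out.

    Returns (manifest, recordings, ground_truths), keyed by
    (subject_id, record_id).  The whole corpus is a pure function of
    (config, seed); per-subject and per-record seeds are derived from the
    master seed.
    """
    import pandas as pd

    from . import io as ecg_io

    if n_subjects < 2 or n_records < 2:
        raise ConfigurationError("need at least 2 subjects and 2 records each")
    if isinstance(noise, str):
        try:
            noise = NOISE_PRESETS[noise]
        except KeyError:
            raise ConfigurationError(f"unknown noise preset {noise!r}") from None

    master = np.random.default_rng(seed)
    subj_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    rec_seeds = master.integers(0, 2**31 - 1, size=(n_subjects, n_records))

    rows = []
    recordings: dict[tuple[str, str], RawRecording] = {}
    truths: dict[tuple[str, str], object] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        m = sample_subject_morphology(int(subj_seeds[i]), cohort_config, subject_id=sid)
        for j in range(n_records):
            rid = f"R{j:02d}"
            rec, truth = simulate_recording(
                m, duration=duration, fs=fs, noise=noise, seed=int(rec_seeds[i, j]),
                record_id=rid,
            )
            recordings[(sid, rid)] = rec
            truths[(sid, rid)] = truth
            path = ""
            if out_path is not None:
                path = str(out_path / f"{sid}_{rid}.txt")
                ecg_io.write_recording(rec, path)
                ecg_io.write_fiducials(truth, out_path / f"{sid}_{rid}_truth.json")
            rows.append({"subject_id": sid, "record_id": rid, "path": path})
    manifest = pd.DataFrame(rows, columns=["subject_id", "record_id", "path"])
    if out_path is not None:
        ecg_io.write_manifest(manifest, out_path / "manifest.csv")
    return manifest, recordings, truths
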