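"""The four matching measures and nearest-template identification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import distance as sp_dist

from ecgid.errors import ConfigurationError
from ecgid.matching import (
    Metric,
    Template,
    build_template,
    city_block_distance,
    cosine_similarity,
    cross_correlation_score,
    euclidean_distance,
    identify,
    score,
)

vec = arrays(
    float,
    st.integers(5, 40),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


def _pairs(n=500, length=30, seed=0):
    rng = np.random.default_rng(seed)
    return [(rng.standard_normal(length), rng.standard_normal(length)) for _ in range(n)]


# --- cosine -----------------------------------------------------------------

def test_cosine_self_similarity_is_one():
    v = np.random.default_rng(0).standard_normal(200)
    assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)


def test_cosine_orthogonal_is_zero():
    a = np.array([1.0, 0.0, 2.0, 0.0])
    b = np.array([0.0, 3.0, 0.0, -4.0])
    assert cosine_similarity(a, b) == 0.0


def test_cosine_scale_free():
    v = np.random.default_rng(1).standard_normal(50)
    assert cosine_similarity(v, 3 * v) == pytest.approx(1.0, abs=1e-12)


def test_cosine_zero_vector_rejected():
    with pytest.raises(ConfigurationError):
        cosine_similarity(np.zeros(5), np.ones(5))


# --- cross correlation ------------------------------------------------------

def _cross_oracle(a, b, max_lag):
    """Brute-force biased cross covariance over all lags, per definition."""
    n = len(a)
    am, bm = np.mean(a), np.mean(b)
    best, best_lag = -math.inf, 0
    denom = math.sqrt(
        sum((x - am) ** 2 for x in a) / n * sum((x - bm) ** 2 for x in b) / n
    )
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            f = sum((a[i] - am) * (b[i + k] - bm) for i in range(n - k)) / n
        else:
            f = sum((b[i] - bm) * (a[i - k] - am) for i in range(n + k)) / n
        d = f / denom
        if d > best:
            best, best_lag = d, k
    return best, best_lag


def test_cross_identical_signals_score_one_at_zero_lag():
    v = np.random.default_rng(2).standard_normal(100)
    s = cross_correlation_score(v, v, max_lag=0)
    assert s.raw == pytest.approx(1.0, abs=1e-12) and s.lag == 0


def test_cross_anticorrelation():
    v = np.random.default_rng(3).standard_normal(100)
    v -= v.mean()
    s = cross_correlation_score(v, -v, max_lag=0)
    assert s.raw == pytest.approx(-1.0, abs=1e-12)


def test_cross_recovers_shift():
    rng = np.random.default_rng(4)
    a = rng.standard_normal(120)
    b = np.concatenate([np.zeros(3), a[:-3]])  # right shift by 3, zero padded
    s = cross_correlation_score(a, b, max_lag=5)
    assert s.lag == 3


def test_cross_matches_bruteforce_oracle():
    for a, b in _pairs(100, 40, seed=5):
        got = cross_correlation_score(a, b, max_lag=7)
        want, want_lag = _cross_oracle(a, b, 7)
        assert got.raw == pytest.approx(want, abs=1e-9)
        assert got.lag == want_lag


def test_cross_constant_input_rejected():
    with pytest.raises(ConfigurationError):
        cross_correlation_score(np.full(10, 2.0), np.arange(10.0))


def test_cross_at_zero_lag_equals_cosine_of_centered():
    """Algebraic identity linking the two similarity measures."""
    for a, b in _pairs(20, 50, seed=6):
        a0, b0 = a - a.mean(), b - b.mean()
        s = cross_correlation_score(a, b, max_lag=0)
        assert s.raw == pytest.approx(cosine_similarity(a0, b0), abs=1e-10)


# --- distances --------------------------------------------------------------

def test_city_block_examples():
    assert city_block_distance(np.array([0.0, 0.0]), np.array([1.0, 2.0])) == 3.0
    v = np.random.default_rng(7).standard_normal(30)
    assert city_block_distance(v, v) == 0.0


def test_euclidean_examples():
    assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0
    v = np.random.default_rng(8).standard_normal(30)
    assert euclidean_distance(v, v) == 0.0


def test_distances_match_scipy():
    for a, b in _pairs(200, 30, seed=9):
        assert city_block_distance(a, b) == pytest.approx(sp_dist.cityblock(a, b), abs=1e-9)
        assert euclidean_distance(a, b) == pytest.approx(sp_dist.euclidean(a, b), abs=1e-9)


def test_length_mismatch_rejected():
    with pytest.raises(ConfigurationError):
        city_block_distance(np.zeros(3), np.zeros(4))
    with pytest.raises(ConfigurationError):
        euclidean_distance(np.zeros(3), np.zeros(4))


# --- properties over all metrics --------------------------------------------

@given(vec.flatmap(lambda a: st.tuples(st.just(a), arrays(float, len(a), elements=st.floats(-100, 100, allow_nan=False, width=32)))))
def test_symmetry_and_bounds(pair):
    a, b = pair
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        return
    assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a), abs=1e-10)
    assert abs(cosine_similarity(a, b)) <= 1 + 1e-12
    assert city_block_distance(a, b) == city_block_distance(b, a) >= 0
    assert euclidean_distance(a, b) == euclidean_distance(b, a) >= 0
    if np.ptp(a) > 0 and np.ptp(b) > 0:
        sab = cross_correlation_score(a, b, 3)
        sba = cross_correlation_score(b, a, 3)
        assert sab.raw == pytest.approx(sba.raw, abs=1e-10)
        assert abs(sab.raw) <= 1 + 1e-12


def test_triangle_inequality_fuzzed():
    rng = np.random.default_rng(10)
    for _ in range(200):
        a, b, c = rng.standard_normal((3, 20))
        assert city_block_distance(a, c) <= city_block_distance(a, b) + city_block_distance(b, c) + 1e-9
        assert euclidean_distance(a, c) <= euclidean_distance(a, b) + euclidean_distance(b, c) + 1e-9


# --- templates and identification -------------------------------------------

def test_template_of_single_frame_is_that_frame():
    v = np.random.default_rng(11).standard_normal(100)
    np.testing.assert_array_equal(build_template([v]).mean_frame, v)


def test_template_cancellation_and_oracle():
    v = np.random.default_rng(12).standard_normal(100)
    np.testing.assert_allclose(build_template([v, -v]).mean_frame, 0.0, atol=1e-12)
    frames = [np.random.default_rng(s).standard_normal(40) for s in range(3)]
    want = np.array([sum(f[i] for f in frames) / 3 for i in range(40)])
    np.testing.assert_allclose(build_template(frames).mean_frame, want, atol=1e-12)


def test_template_empty_rejected():
    with pytest.raises(ConfigurationError):
        build_template([])


@pytest.mark.parametrize("metric", list(Metric))
def test_identify_exact_match_wins(metric):
    rng = np.random.default_rng(13)
    gallery = [Template(rng.standard_normal(60), 1, f"S{i}") for i in range(5)]
    res = identify(gallery[3].mean_frame.copy(), gallery, metric)
    assert res.subject_id == "S3"
    assert len(res.scores) == 5


def test_identify_single_template_trivial():
    t = Template(np.arange(10.0), 1, "only")
    assert identify(np.random.default_rng(0).standard_normal(10), [t], "euclidean").subject_id == "only"


@pytest.mark.parametrize("metric", list(Metric))
def test_identify_agrees_with_bruteforce_argmax(metric):
    rng = np.random.default_rng(14)
    for _ in range(20):
        gallery = [Template(rng.standard_normal(30), 1, f"S{i}") for i in range(8)]
        q = rng.standard_normal(30)
        res = identify(q, gallery, metric)
        oriented = {t.subject_id: score(t.mean_frame, q, metric).oriented for t in gallery}
        assert res.subject_id == max(sorted(oriented), key=lambda s: oriented[s])


def test_identify_no_templates_rejected():
    with pytest.raises(ConfigurationError):
        identify(np.zeros(5), [], "cosine")


def test_shrinking_a_distance_increases_preference():
    """Oriented-score consistency under perturbation toward the query."""
    rng = np.random.default_rng(15)
    q = rng.standard_normal(40)
    far = Template(q + rng.standard_normal(40), 1, "far")
    near = Template(q + 0.1 * (far.mean_frame - q), 1, "near")
    for metric in (Metric.CITY_BLOCK, Metric.EUCLIDEAN):
        s_far = score(far.mean_frame, q, metric).oriented
        s_near = score(near.mean_frame, q, metric).oriented
        assert s_near > s_far
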