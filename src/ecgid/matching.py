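"""Template matching: four similarity/distance measures and nearest-template
identification.

For pattern vectors A (template) and B (query) of common length N the
measures are

* cosine similarity      sum(A_i B_i) / (||A|| ||B||)
* cross correlation      max_k f_AB(k) / sqrt(f_AA(0) f_BB(0)), |k| <= T,
                         with f_AB the biased (1/N) mean-removed cross
                         covariance at lag k
* city block distance    sum |A_i - B_i|
* Euclidean distance     sqrt(sum (A_i - B_i)^2)

Scores are carried with an *oriented* value where larger always means more
similar (distances are negated), so identification is a single argmax
regardless of metric.  Frames are matched raw — no z-scoring or amplitude
normalization — so the metrics genuinely differ in what they reward:
cosine ignores scale, the distances do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Metric",
    "MatchScore",
    "Template",
    "IdentificationResult",
    "cosine_similarity",
    "cross_correlation_score",
    "city_block_distance",
    "euclidean_distance",
    "score",
    "build_template",
    "identify",
]

DEFAULT_MAX_LAG = 10


class Metric(str, Enum):
    COSINE = "cosine"
    CROSS = "cross"
    CITY_BLOCK = "city_block"
    EUCLIDEAN = "euclidean"

    @property
    def is_distance(self) -> bool:
        return self in (Metric.CITY_BLOCK, Metric.EUCLIDEAN)


@dataclass(frozen=True)
class MatchScore:
    """One comparison outcome.  ``oriented`` is always larger-is-more-similar."""

    metric: Metric
    raw: float
    oriented: float
    lag: int | None = None


@dataclass
class Template:
    """Per-subject enrollment pattern: the pointwise mean of training frames."""

    mean_frame: np.ndarray
    n_sources: int
    subject_id: str

    def __post_init__(self) -> None:
        self.mean_frame = np.asarray(self.mean_frame, dtype=float)
        if self.n_sources < 1:
            raise ConfigurationError("a template needs at least one source frame")


@dataclass
class IdentificationResult:
    subject_id: str
    scores: list[tuple[str, MatchScore]]


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ConfigurationError("pattern vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ConfigurationError("pattern vectors need at least 2 samples")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigurationError("pattern vectors must be finite")
    return a, b


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between the two vectors; in [-1, 1]."""
    a, b = _check_pair(a, b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ConfigurationError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _cross_cov(a0: np.ndarray, b0: np.ndarray, k: int, n: int) -> float:
    """Biased mean-removed cross covariance f_AB(k); a0, b0 pre-centered."""
    if k >= 0:
        return float(a0[: n - k] @ b0[k:]) / n
    return float(b0[: n + k] @ a0[-k:]) / n


def cross_correlation_score(
    a: np.ndarray, b: np.ndarray, max_lag: int = DEFAULT_MAX_LAG
) -> MatchScore:
    """Maximum normalized cross covariance over lags |k| <= max_lag.

    Identical signals score 1 at lag 0.  Lags are searched ascending from
    -max_lag; ties keep the first maximum found.  Constant inputs have zero
    variance and are rejected.
    """
    a, b = _check_pair(a, b)
    n = len(a)
    if not (0 <= max_lag < n):
        raise ConfigurationError("max_lag must satisfy 0 <= max_lag < N")
    a0 = a - a.mean()
    b0 = b - b.mean()
    faa0 = float(a0 @ a0) / n
    fbb0 = float(b0 @ b0) / n
    if faa0 == 0 or fbb0 == 0:
        raise ConfigurationError("cross correlation undefined for a constant signal")
    denom = float(np.sqrt(faa0 * fbb0))
    best, best_lag = -np.inf, 0
    for k in range(-max_lag, max_lag + 1):
        d = _cross_cov(a0, b0, k, n) / denom
        if d > best:
            best, best_lag = d, k
    return MatchScore(Metric.CROSS, raw=best, oriented=best, lag=best_lag)


def city_block_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L1 distance; zero iff the signals are identical."""
    a, b = _check_pair(a, b)
    return float(np.abs(a - b).sum())


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L2 distance: length of the straight line between the two points."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


def score(
    a: np.ndarray, b: np.ndarray, metric: Metric | str, max_lag: int = DEFAULT_MAX_LAG
) -> MatchScore:
    """Compare two pattern vectors under the chosen metric."""
    metric = Metric(metric)
    if metric is Metric.COSINE:
        s = cosine_similarity(a, b)
        return MatchScore(metric, raw=s, oriented=s)
    if metric is Metric.CROSS:
        return cross_correlation_score(a, b, max_lag)
    if metric is Metric.CITY_BLOCK:
        d = city_block_distance(a, b)
        return MatchScore(metric, raw=d, oriented=-d)
    d = euclidean_distance(a, b)
    return MatchScore(metric, raw=d, oriented=-d)


def build_template(
    frames: list[np.ndarray], subject_id: str = ""
) -> Template:
    """Pointwise arithmetic mean of enrollment frames."""
    if not frames:
        raise ConfigurationError("cannot build a template from zero frames")
    arrs = [np.asarray(f, dtype=float) for f in frames]
    if len({len(a) for a in arrs}) != 1:
        raise ConfigurationError("all enrollment frames must share one length")
    return Template(np.mean(arrs, axis=0), n_sources=len(arrs), subject_id=subject_id)


def identify(
    query: np.ndarray,
    templates: list[Template],
    metric: Metric | str,
    max_lag: int = DEFAULT_MAX_LAG,
) -> IdentificationResult:
    """Assign the query to the template with the best oriented score.

    Ties break to the lexicographically lowest subject_id (deterministic).
    """
    if not templates:
        raise ConfigurationError("identification requires at least one template")
    scores = []
    for tpl in sorted(templates, key=lambda t: t.subject_id):
        scores.append((tpl.subject_id, score(tpl.mean_frame, query, metric, max_lag)))
    best_sid, _ = max(scores, key=lambda item: item[1].oriented)
    # max() keeps the first of equal values; list is sorted by subject_id
    return IdentificationResult(best_sid, scores)
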