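"""Local similarity analysis over replicate-averaged OTU time series.

Local similarity (LS) between two equal-length series is the maximal
nonnegative running sum of elementwise products over aligned contiguous
runs, where the two runs may be offset by a bounded time delay D.  Both a
positively and a negatively accumulating table are kept, so anti-correlated
stretches score as negative associations.  Significance comes from a
permutation test: the probability that a random reordering of one series
achieves an LS at least as large as the observed one (exact enumeration for
short series, Monte-Carlo with add-one correction otherwise).

The extended flavour for replicated designs enters upstream: replicates are
reduced to their simple average per time step (see ``tables.build_series``)
before the standard LS computation is applied.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from ._kernels import batch_max_ls
from .tables import SeriesSet, ValidationError

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("normal_scores", "zscore", "none")


@dataclass
class LsaConfig:
    """Settings for an LSA run.

    max_delay:
        maximal index offset D between the two aligned runs (default 1).
    normalization:
        per-series transform applied before scoring; rank-based normal
        scores by default (robust to the heavy-tailed marginals of
        relative-abundance data).
    n_perm:
        Monte-Carlo permutation count (default 1000).
    exact_below:
        series length at or below which the full n! permutation set is
        enumerated instead (default 6, i.e. at most 720 permutations).
    alpha:
        significance level used when thresholding edges downstream.
    """

    max_delay: int = 1
    normalization: str = "normal_scores"
    n_perm: int = 1000
    exact_below: int = 6
    alpha: float = 0.05
    seed: int = 0
    compute_upper: bool = True

    def __post_init__(self) -> None:
        if self.max_delay < 0:
            raise ValidationError("max_delay must be nonnegative")
        if self.normalization not in NORMALIZATIONS:
            raise ValidationError(f"normalization must be one of {NORMALIZATIONS}")
        if self.n_perm < 99:
            raise ValidationError("n_perm must be at least 99")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class LsaResult:
    """One OTU pair's local-similarity outcome."""

    otu_a: str
    otu_b: str
    ls_score: float  # length-normalized, nonnegative
    raw_score: float  # unnormalized maximal run sum
    sign: str  # '+' or '-'
    best_delay: int
    p_value: float
    p_upper: float | None = None

    @property
    def signed_score(self) -> float:
        return self.ls_score if self.sign == "+" else -self.ls_score


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_series(series, method: str = "normal_scores") -> np.ndarray:
    """Transform one series prior to LS scoring.

    ``normal_scores`` maps the value at (average, for ties) rank r of n to
    the standard normal quantile at r/(n+1); ``zscore`` centers and scales
    by the population SD; ``none`` is the identity.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("series must be 1-D with length >= 3")
    if method == "none":
        return x.copy()
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValidationError(
                "constant series has zero SD; use normal_scores (ties map to quantile 1/2 = 0)"
            )
        return (x - x.mean()) / sd
    if method == "normal_scores":
        ranks = sstats.rankdata(x, method="average")
        return sstats.norm.ppf(ranks / (x.size + 1))
    raise ValidationError(f"unknown normalization {method!r}")


# ---------------------------------------------------------------------------
# the dynamic program
# ---------------------------------------------------------------------------

def local_similarity(x, y, max_delay: int = 1) -> tuple[float, str, int]:
    """Local similarity score of two equal-length series with bounded delay.

    Returns ``(ls_score, sign, best_delay)`` where ``ls_score`` is the
    maximal run sum divided by the series length, ``sign`` is '+' when the
    positively accumulating table attains the maximum (ties break to '+'),
    and ``best_delay`` is the index offset j - i of the maximizing run
    (ties break to the smallest magnitude, then to the positive delay).
    """
    score, sign, delay, _raw = _local_similarity_full(x, y, max_delay)
    return score, sign, delay


def _local_similarity_full(x, y, max_delay: int) -> tuple[float, str, int, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"series length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValidationError("series must have length >= 2")
    if max_delay >= n:
        raise ValidationError(f"max_delay {max_delay} must be smaller than series length {n}")
    candidates: list[tuple[float, int, str]] = []
    for d in range(-max_delay, max_delay + 1):
        i0, i1 = max(0, -d), min(n, n - d)
        prods = x[i0:i1] * y[i0 + d : i1 + d]
        pos = neg = 0.0
        best_pos = best_neg = 0.0
        for s in prods:
            pos = max(0.0, pos + s)
            neg = max(0.0, neg - s)
            best_pos = max(best_pos, pos)
            best_neg = max(best_neg, neg)
        candidates.append((best_pos, d, "+"))
        candidates.append((best_neg, d, "-"))
    raw = max(c[0] for c in candidates)
    at_max = [c for c in candidates if c[0] == raw]
    sign = "+" if any(c[2] == "+" for c in at_max) else "-"
    with_sign = [c for c in at_max if c[2] == sign]
    delay = min((c[1] for c in with_sign), key=lambda d: (abs(d), -d))
    return raw / n, sign, delay, raw


def brute_force_local_similarity(x, y, max_delay: int = 1) -> float:
    """Independent oracle: enumerate every pair of equal-length contiguous
    runs with offset |j - i| <= max_delay and return the best normalized
    score over both signs.  Exponential in nothing, but O(n^3 D); test use
    only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    best = 0.0
    for d in range(-max_delay, max_delay + 1):
        for i in range(n):
            j = i + d
            if not 0 <= j < n:
                continue
            total = 0.0
            for k in range(min(n - i, n - j)):
                total += x[i + k] * y[j + k]
                best = max(best, total, -total)
    return best / n


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def permutation_pvalue(
    x,
    y,
    observed: float | None = None,
    config: LsaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """Permutation p-value for the LS score of ``x`` and ``y``.

    The p-value is the probability that a random permutation of ``y``
    yields an LS score at least as large as the observed one.  For series
    of length <= ``config.exact_below`` the full n! permutation set is
    enumerated (identity included); otherwise ``config.n_perm`` Monte-Carlo
    draws are used with the add-one correction (k+1)/(n_perm+1).

    Also returns a conservative upper bound min(1, p * (2D+1)) — a
    Bonferroni-style correction across the scanned delay offsets — or None
    when ``config.compute_upper`` is off.
    """
    config = config or LsaConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if observed is None:
        observed = local_similarity(x, y, config.max_delay)[0]
    raw_obs = observed * n - 1e-12  # same scale as the kernel's raw scores
    if n <= config.exact_below:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        scores = batch_max_ls(x, y[perms], config.max_delay)
        p = float(np.count_nonzero(scores >= raw_obs)) / len(perms)
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        perms = _permutation_indices(rng, n, config.n_perm)
        scores = batch_max_ls(x, y[perms], config.max_delay)
        p = (float(np.count_nonzero(scores >= raw_obs)) + 1.0) / (config.n_perm + 1.0)
    upper = min(1.0, p * (2 * config.max_delay + 1)) if config.compute_upper else None
    return p, upper


def _permutation_indices(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (m, 1))
    return rng.permuted(idx, axis=1)


def _pair_rng(seed: int, otu_a: str, otu_b: str) -> np.random.Generator:
    """One RNG stream per pair, independent of evaluation order."""
    a, b = sorted((otu_a, otu_b))
    return np.random.default_rng(
        [int(seed) % 2**31, zlib.crc32(a.encode()), zlib.crc32(b.encode())]
    )


# ---------------------------------------------------------------------------
# all pairs
# ---------------------------------------------------------------------------

def all_pairs_lsa(series: SeriesSet, config: LsaConfig | None = None) -> list[LsaResult]:
    """LS score + permutation p-value for every unordered OTU pair.

    Results are sorted by (otu_a, otu_b); a failing pair is logged and
    omitted rather than aborting the run.  Deterministic under a fixed
    ``config.seed`` regardless of evaluation order (per-pair RNG streams).
    """
    config = config or LsaConfig()
    otus = sorted(series.otu_ids)
    if len(otus) != len(set(otus)):
        seen: set[str] = set()
        dup = next(o for o in otus if o in seen or seen.add(o))
        raise ValidationError(f"duplicate OTU id in series set: {dup!r}")
    if len(otus) < 2:
        raise ValidationError("need at least 2 OTUs")
    n = len(series.generations)
    if config.max_delay >= n:
        raise ValidationError(f"max_delay {config.max_delay} >= series length {n}")
    normalized = {o: normalize_series(series.series(o), config.normalization) for o in otus}
    results: list[LsaResult] = []
    failures = 0
    for a, b in itertools.combinations(otus, 2):
        try:
            x, y = normalized[a], normalized[b]
            score, sign, delay, raw = _local_similarity_full(x, y, config.max_delay)
            rng = _pair_rng(config.seed, a, b)
            p, upper = permutation_pvalue(x, y, score, config, rng=rng)
            results.append(LsaResult(a, b, score, raw, sign, delay, p, upper))
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            failures += 1
            logger.warning("LSA failed for pair (%s, %s): %s", a, b, exc)
    if failures:
        logger.warning("%d pair(s) failed and were omitted", failures)
    return results


def results_to_frame(results: list[LsaResult]):
    """LsaResult list as a tidy DataFrame (one row per pair)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "otu_a": [r.otu_a for r in results],
            "otu_b": [r.otu_b for r in results],
            "ls_score": [r.ls_score for r in results],
            "sign": [r.sign for r in results],
            "delay": [r.best_delay for r in results],
            "p_value": [r.p_value for r in results],
            "p_upper": [r.p_upper for r in results],
        }
    )
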