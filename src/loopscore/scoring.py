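"""Background expected model, p-values, and interaction scores.

The local background of a contact-map pixel is estimated with the donut
construction: the ring of pixels between Chebyshev radius ``p_excl``
(exclusive center) and ``w`` supplies an observed sum which is rescaled by
the distance-decay reference (the mean observed value per diagonal) so
that the expected value at (i, j) reflects both the local neighbourhood
and the genomic distance |i - j|. Observed/expected ratios are fitted with
a logistic distribution; upper-tail p-values become interaction scores
score = -10 * log2(p), so p = 0.5 maps to 10 and p = 0.25 to 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .intervals_io import GenomicInterval, overlaps
from .matrix import ContactMatrix

__all__ = [
    "ExpectedMatrix",
    "ScoreMap",
    "LoopQuantification",
    "donut_expected",
    "background_normalize",
    "fit_logistic",
    "pvalues_and_scores",
    "quantify_loop_pixels",
    "distance_corrected_loop_strength",
]


@dataclass
class ExpectedMatrix:
    """Donut-background expected values; NaN where undefined."""

    values: np.ndarray
    donut_width: int
    exclusion_radius: int
    min_ring_pixels: int


@dataclass
class ScoreMap:
    """Per-pixel ratio, logistic p-value and interaction score."""

    ratio: np.ndarray
    p_value: np.ndarray
    score: np.ndarray
    logistic_location: float
    logistic_scale: float


class LoopQuantification(NamedTuple):
    mean: float  # NaN when no informative pixel falls in the rectangle
    n_pixels: int


def _decay_reference(matrix: ContactMatrix, trim: float = 0.0) -> np.ndarray:
    """Per-|i - j| diagonal reference over informative pixels.

    ``trim`` is the fraction cut from each tail of a diagonal's values
    before averaging; a modest trim makes the reference robust to the
    handful of genuinely looping pixels sitting on their own diagonal,
    which would otherwise inflate the expected value at loop pixels.
    """
    n = matrix.n
    ref = np.full((n, n), np.nan)
    idx = np.arange(n)
    for d in range(n):
        i, j = idx[: n - d], idx[: n - d] + d
        keep = matrix.informative[i, j]
        if keep.any():
            vals = matrix.values[i[keep], j[keep]]
            if trim > 0 and vals.size > 10:
                avg = stats.trim_mean(vals, trim)
            else:
                avg = vals.mean()
            ref[i, j] = avg
            ref[j, i] = avg
    return ref


def donut_expected(matrix: ContactMatrix, w: int = 5, p_excl: int = 2,
                   min_ring_pixels: int = 10,
                   decay_trim: float = 0.1) -> ExpectedMatrix:
    """Donut-background expected value at every informative pixel.

    expected(i, j) = ring_sum(observed) / ring_sum(decay reference)
                     * decay_reference(i, j)

    over ring members that are informative and carry a defined reference;
    pixels whose ring holds fewer than ``min_ring_pixels`` members are
    undefined (NaN). Rings are truncated at matrix edges. The decay
    reference is the per-diagonal trimmed mean (``decay_trim`` per tail);
    the exclusion radius should cover the expected peak width so the ring
    samples background rather than the peak's shoulders.
    """
    if w <= p_excl:
        raise ValueError(f"donut width ({w}) must exceed exclusion radius ({p_excl})")
    if p_excl < 1:
        raise ValueError("exclusion radius must be >= 1")
    n = matrix.n
    ref = _decay_reference(matrix, decay_trim)
    member = matrix.informative & ~np.isnan(ref)
    obs_m = np.where(member, matrix.values, 0.0)
    ref_m = np.where(member, ref, 0.0)
    cnt_m = member.astype(float)

    pad = w
    obs_p = np.pad(obs_m, pad)
    ref_p = np.pad(ref_m, pad)
    cnt_p = np.pad(cnt_m, pad)
    ring_obs = np.zeros((n, n))
    ring_ref = np.zeros((n, n))
    ring_cnt = np.zeros((n, n))
    for di in range(-w, w + 1):
        for dj in range(-w, w + 1):
            if max(abs(di), abs(dj)) <= p_excl:
                continue
            sl = (slice(pad + di, pad + di + n), slice(pad + dj, pad + dj + n))
            ring_obs += obs_p[sl]
            ring_ref += ref_p[sl]
            ring_cnt += cnt_p[sl]

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = ring_obs / ring_ref * ref
    bad = (~matrix.informative) | (ring_cnt < min_ring_pixels) | (ring_ref <= 0)
    expected[bad] = np.nan
    return ExpectedMatrix(expected, w, p_excl, min_ring_pixels)


def background_normalize(observed: ContactMatrix,
                         expected: ExpectedMatrix) -> np.ndarray:
    """Observed/expected ratio map; NaN where expected is undefined."""
    exp = expected.values
    if exp.shape != observed.values.shape:
        raise ValueError("observed and expected shapes differ")
    defined = observed.informative & ~np.isnan(exp)
    if np.any(exp[defined] <= 0):
        raise RuntimeError("expected values must be positive where defined")
    ratio = np.full_like(exp, np.nan)
    ratio[defined] = observed.values[defined] / exp[defined]
    return ratio


def fit_logistic(values: np.ndarray, min_n: int = 30) -> tuple[float, float]:
    """Maximum-likelihood logistic fit (location mu, scale s > 0).

    Numerical optimisation starts from the method-of-moments estimate
    (mu0 = mean, s0 = sd * sqrt(3) / pi).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_n:
        raise ValueError(f"need at least {min_n} finite values, got {vals.size}")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate sample: all values equal")
    mu0 = float(vals.mean())
    s0 = float(vals.std(ddof=1) * np.sqrt(3) / np.pi)
    mu, s = stats.logistic.fit(vals, loc=mu0, scale=s0)
    return float(mu), float(s)


def pvalues_and_scores(ratios: np.ndarray, mu: float, s: float,
                       p_floor: float = 1e-12) -> ScoreMap:
    """Upper-tail logistic p-values and interaction scores for a ratio map.

    p = 1 / (1 + exp((x - mu) / s)), floored at ``p_floor`` (which caps the
    score near 398.6); score = -10 * log2(p).
    """
    if s <= 0:
        raise ValueError("logistic scale must be positive")
    p = np.full_like(ratios, np.nan)
    defined = ~np.isnan(ratios)
    p[defined] = stats.logistic.sf(ratios[defined], loc=mu, scale=s)
    p[defined] = np.clip(p[defined], p_floor, 1.0)
    score = np.full_like(ratios, np.nan)
    score[defined] = -10.0 * np.log2(p[defined])
    return ScoreMap(ratios, p, score, mu, s)


def anchor_bins(matrix: ContactMatrix, anchor: GenomicInterval) -> np.ndarray:
    """Indices of matrix bins overlapping the anchor interval."""
    bins = matrix.bin_intervals()
    hit = np.array([overlaps(b, anchor) for b in bins])
    return np.flatnonzero(hit)


_anchor_bins = anchor_bins


def quantify_loop_pixels(matrix: ContactMatrix, anchor_a: GenomicInterval,
                         anchor_b: GenomicInterval) -> LoopQuantification:
    """Mean informative pixel value over the anchor-by-anchor rectangle."""
    rows = _anchor_bins(matrix, anchor_a)
    cols = _anchor_bins(matrix, anchor_b)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("anchor does not overlap the matrix axis")
    block = matrix.values[np.ix_(rows, cols)]
    mask = matrix.informative[np.ix_(rows, cols)]
    if not mask.any():
        return LoopQuantification(float("nan"), 0)
    return LoopQuantification(float(block[mask].mean()), int(mask.sum()))


def distance_corrected_loop_strength(observed: ContactMatrix,
                                     expected: ExpectedMatrix,
                                     anchor_a: GenomicInterval,
                                     anchor_b: GenomicInterval) -> LoopQuantification:
    """Mean observed/expected over the loop rectangle (distance-corrected)."""
    rows = _anchor_bins(observed, anchor_a)
    cols = _anchor_bins(observed, anchor_b)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("anchor does not overlap the matrix axis")
    obs = observed.values[np.ix_(rows, cols)]
    exp = expected.values[np.ix_(rows, cols)]
    mask = observed.informative[np.ix_(rows, cols)] & ~np.isnan(exp)
    if not mask.any():
        return LoopQuantification(float("nan"), 0)
    return LoopQuantification(float((obs[mask] / exp[mask]).mean()), int(mask.sum()))
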