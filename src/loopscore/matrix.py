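"""Raw 5C counts to binned relative-interaction-frequency matrices.

The chain implemented here: tally valid primer-pair read counts, remove
PCR-bias outliers against a local 5x5 median, average surviving primer
pairs into fragment-fragment counts, and sum fragments into adjacent
genomic bins through overlapping windows. All matrices are symmetric with
an explicit boolean mask of informative (queryable and not removed) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .intervals_io import GenomicInterval

__all__ = [
    "FORWARD_SENSE",
    "REVERSE_SENSE",
    "Primer",
    "PrimerDesign",
    "ContactMatrix",
    "TallyResult",
    "tally_pair_counts",
    "remove_outliers",
    "primer_to_fragment",
    "bin_to_grid",
]

# Double-alternating design: forward-sense primers (FOR and "left-forward"
# LFOR) may only ligate to reverse-sense primers (REV and LREV).
FORWARD_SENSE = frozenset({"FOR", "LFOR"})
REVERSE_SENSE = frozenset({"REV", "LREV"})
_ORIENTATIONS = FORWARD_SENSE | REVERSE_SENSE


@dataclass(frozen=True)
class Primer:
    primer_id: str
    fragment_index: int
    orientation: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def forward_sense(self) -> bool:
        return self.orientation in FORWARD_SENSE


@dataclass
class PrimerDesign:
    """Primers over a tiling set of restriction fragments.

    Fragments must tile a contiguous region without overlap; each primer's
    interval must lie inside its fragment. A primer pair is queryable iff
    the two primers have opposite sense.
    """

    primers: list[Primer]
    fragments: list[GenomicInterval]

    def __post_init__(self) -> None:
        for i, (a, b) in enumerate(zip(self.fragments, self.fragments[1:])):
            if a.chrom != b.chrom or a.end != b.start:
                raise ValueError(f"fragments {i} and {i + 1} do not tile contiguously")
        for p in self.primers:
            frag = self.fragments[p.fragment_index]
            if not (frag.start <= p.interval.start and p.interval.end <= frag.end):
                raise ValueError(f"primer {p.primer_id} not contained in fragment "
                                 f"{p.fragment_index}")
        ids = [p.primer_id for p in self.primers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate primer ids")

    @property
    def n_primers(self) -> int:
        return len(self.primers)

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.fragments[0].chrom,
                               self.fragments[0].start, self.fragments[-1].end)

    def primer_index(self) -> dict[str, int]:
        return {p.primer_id: i for i, p in enumerate(self.primers)}

    def queryable_mask(self) -> np.ndarray:
        """Symmetric boolean mask of opposite-sense primer pairs."""
        fwd = np.array([p.forward_sense for p in self.primers])
        return fwd[:, None] != fwd[None, :]

    def primer_axis(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [p.interval.chrom for p in self.primers],
            "start": [p.interval.start for p in self.primers],
            "end": [p.interval.end for p in self.primers],
        })

    def fragment_axis(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [f.chrom for f in self.fragments],
            "start": [f.start for f in self.fragments],
            "end": [f.end for f in self.fragments],
        })


@dataclass
class ContactMatrix:
    """A symmetric contact matrix with coordinates and an informative mask.

    ``values`` holds counts or frequencies; entries outside ``informative``
    carry no meaning and are kept at 0. ``level`` records the axis role:
    "primer", "fragment", or "bin".
    """

    values: np.ndarray
    informative: np.ndarray
    axis: pd.DataFrame
    level: str = "primer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.informative = np.asarray(self.informative, dtype=bool)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.informative.shape != (n, n):
            raise ValueError("values and informative must be square and same shape")
        if len(self.axis) != n:
            raise ValueError("axis length must match matrix size")
        if not np.array_equal(self.informative, self.informative.T):
            raise ValueError("informative mask must be symmetric")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")
        if np.any(self.values[self.informative] < 0):
            raise ValueError("informative values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.values.copy(), self.informative.copy(),
                             self.axis.copy(), self.level)

    def bin_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in self.axis.itertuples(index=False)]


class TallyResult(NamedTuple):
    matrix: ContactMatrix
    n_tallied: int
    n_discarded: int


def tally_pair_counts(assignments: Iterable[tuple[str, str]],
                      design: PrimerDesign) -> TallyResult:
    """Tally read pairs whose two ends map to opposite-sense primers.

    Pairs where both ends are forward-sense or both reverse-sense cannot
    arise from a genuine ligation junction in the double-alternating design
    and are discarded (counted, not tallied). Total input pairs equals
    tallied + discarded.
    """
    idx = design.primer_index()
    n = design.n_primers

    def lookup(name: str) -> int:
        try:
            return idx[name]
        except KeyError:
            raise KeyError(f"unknown primer id {name!r}") from None

    pairs = list(assignments)
    i_idx = np.fromiter((lookup(e1) for e1, _ in pairs), dtype=np.intp,
                        count=len(pairs))
    j_idx = np.fromiter((lookup(e2) for _, e2 in pairs), dtype=np.intp,
                        count=len(pairs))
    fwd = np.array([p.forward_sense for p in design.primers])
    valid = fwd[i_idx] != fwd[j_idx]
    upper = np.zeros((n, n))
    np.add.at(upper, (i_idx[valid], j_idx[valid]), 1.0)
    counts = upper + upper.T  # opposite-sense pairs are never i == j
    n_tallied = int(valid.sum())
    matrix = ContactMatrix(counts, design.queryable_mask(),
                           design.primer_axis(), level="primer")
    return TallyResult(matrix, n_tallied, len(pairs) - n_tallied)


def remove_outliers(matrix: ContactMatrix, fold: float = 8.0, *,
                    zero_median_floor: float = 1.0,
                    zero_fill: bool = False) -> tuple[ContactMatrix, list[tuple[int, int]]]:
    """Remove PCR-bias outlier counts against the local 5x5 window median.

    A pair (i, j) is removed when its count is at least ``fold`` times the
    median of the 5x5 index window centered at (i, j). The window is
    truncated at matrix edges, includes the center cell, and by default
    covers informative entries only (``zero_fill=True`` instead treats
    non-informative cells as zeros). Zero-median windows use
    ``zero_median_floor`` in place of the median so a sparse matrix is not
    wiped out. Decisions are made in a single pass on the input counts.
    """
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    n = matrix.n
    vals, info = matrix.values, matrix.informative
    remove = np.zeros((n, n), dtype=bool)
    half = 2  # 5x5 window
    for i in range(n):
        for j in range(i, n):
            if not info[i, j]:
                continue
            i0, i1 = max(0, i - half), min(n, i + half + 1)
            j0, j1 = max(0, j - half), min(n, j + half + 1)
            wv = vals[i0:i1, j0:j1]
            wm = info[i0:i1, j0:j1]
            if zero_fill:
                window = np.where(wm, wv, 0.0).ravel()
            else:
                window = wv[wm]
            med = float(np.median(window)) if window.size else 0.0
            if med <= 0:
                med = zero_median_floor
            if vals[i, j] >= fold * med:
                remove[i, j] = remove[j, i] = True
    out = matrix.copy()
    out.informative &= ~remove
    out.values[remove] = 0.0
    removed = [(i, j) for i in range(n) for j in range(i, n) if remove[i, j]]
    return out, removed


def primer_to_fragment(matrix: ContactMatrix, design: PrimerDesign) -> ContactMatrix:
    """Average surviving primer-pair counts into fragment-fragment counts.

    Each fragment pair collects the informative primer-pair counts that map
    to it (at most 2 in a design carrying both senses on a fragment) and
    takes their arithmetic mean; pairs with no surviving primer pair are
    non-informative.
    """
    if matrix.level != "primer":
        raise ValueError("expected a primer-level matrix")
    nf = len(design.fragments)
    frag_of = np.array([p.fragment_index for p in design.primers])
    total = np.zeros((nf, nf))
    count = np.zeros((nf, nf), dtype=int)
    n = matrix.n
    for i in range(n):
        for j in range(i, n):
            if not matrix.informative[i, j]:
                continue
            f, g = frag_of[i], frag_of[j]
            lo, hi = min(f, g), max(f, g)
            total[lo, hi] += matrix.values[i, j]
            count[lo, hi] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    mean = mean + np.triu(mean, 1).T
    info = (count > 0) | (count.T > 0)
    return ContactMatrix(mean, info, design.fragment_axis(), level="fragment")


def _bin_axis(region: GenomicInterval, bin_size: int) -> pd.DataFrame:
    starts = np.arange(region.start, region.end, bin_size)
    ends = np.minimum(starts + bin_size, region.end)
    return pd.DataFrame({"chrom": region.chrom, "start": starts, "end": ends})


def bin_to_grid(matrix: ContactMatrix, bin_size: int = 4000, window: int = 12000,
                region: GenomicInterval | None = None) -> ContactMatrix:
    """Sum fragment-pair counts into adjacent genomic bins via windows.

    Bin (i, j) sums every informative fragment pair (f, g) for which one
    fragment overlaps (at least partially) the ``window``-wide interval
    around bin i's center and the other overlaps the window around bin j's
    center, in either assignment; each fragment pair contributes its value
    once per bin pair. Windows are half-open and truncated at region edges.
    """
    if window < bin_size:
        raise ValueError(f"window ({window}) must be >= bin_size ({bin_size})")
    if matrix.level != "fragment":
        raise ValueError("expected a fragment-level matrix")
    frags = matrix.bin_intervals()
    if region is None:
        region = GenomicInterval(frags[0].chrom, frags[0].start, max(f.end for f in frags))
    axis = _bin_axis(region, bin_size)
    nb = len(axis)
    centers = axis["start"].to_numpy() + bin_size / 2
    win_lo = np.maximum(centers - window / 2, region.start)
    win_hi = np.minimum(centers + window / 2, region.end)
    # fragment f overlaps bin b's window (half-open overlap)
    fstart = np.array([f.start for f in frags], dtype=float)
    fend = np.array([f.end for f in frags], dtype=float)
    overlap = (fstart[:, None] < win_hi[None, :]) & (win_lo[None, :] < fend[:, None])

    values = np.zeros((nb, nb))
    contrib = np.zeros((nb, nb), dtype=int)
    nf = matrix.n
    bin_ranges: list[np.ndarray] = [np.flatnonzero(overlap[f]) for f in range(nf)]
    for f in range(nf):
        bf = bin_ranges[f]
        if bf.size == 0:
            continue
        for g in range(f, nf):
            if not matrix.informative[f, g]:
                continue
            bg = bin_ranges[g]
            if bg.size == 0:
                continue
            v = matrix.values[f, g]
            if f == g:
                ix = np.ix_(bf, bf)
                values[ix] += v
                contrib[ix] += 1
            else:
                ix1 = np.ix_(bf, bg)
                ix2 = np.ix_(bg, bf)
                values[ix1] += v
                values[ix2] += v
                contrib[ix1] += 1
                contrib[ix2] += 1
                both = np.intersect1d(bf, bg, assume_unique=True)
                if both.size:
                    ixb = np.ix_(both, both)
                    values[ixb] -= v  # counted under both assignments
                    contrib[ixb] -= 1
    return ContactMatrix(values, contrib > 0, axis, level="bin")
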