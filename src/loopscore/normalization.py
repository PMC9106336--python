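"""Matrix balancing and cross-replicate quantile normalization.

ICE (iterative correction) factors a symmetric contact matrix into
per-locus multiplicative visibility biases so that every informative row
carries equal total signal. Quantile normalization then forces the value
distributions of a group of replicate matrices to coincide, making
pixel-level comparisons across replicates and conditions meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ContactMatrix

__all__ = ["BalancedMatrix", "ice_balance", "quantile_normalize"]


@dataclass
class BalancedMatrix:
    """Result of ICE balancing: corrected matrix plus the bias vector.

    ``matrix.values[i, j] == raw[i, j] / (biases[i] * biases[j])`` on
    informative pixels; rows excluded from balancing (no informative mass
    off the near-diagonal) have bias NaN and are masked non-informative.
    """

    matrix: ContactMatrix
    biases: np.ndarray
    n_iterations: int
    converged: bool


def ice_balance(matrix: ContactMatrix, tol: float = 1e-8, max_iter: int = 500,
                min_separation: int = 1) -> BalancedMatrix:
    """Iterative correction with row-sum target equal to the mean row sum.

    Pixels closer to the diagonal than ``min_separation`` bins are excluded
    from the balancing sums (their short-range signal is dominated by
    self-ligation artefacts) but are still corrected by the fitted biases.
    Biases are normalized to geometric mean 1 over balanced rows.
    """
    n = matrix.n
    raw = matrix.values
    if not np.allclose(raw, raw.T):
        raise ValueError("matrix must be symmetric")
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    bal_mask = matrix.informative & (sep >= min_separation)
    include = bal_mask.sum(axis=1) > 0
    if not include.any():
        raise ValueError("no rows with informative mass to balance")

    b = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vals = raw / np.outer(b, b)
        s = np.where(bal_mask, vals, 0.0).sum(axis=1)
        mean_s = s[include].mean()
        if mean_s <= 0:
            raise ValueError("balancing mass vanished; matrix may be all zeros")
        rel = s[include] / mean_s
        if np.max(np.abs(rel - 1.0)) < tol:
            converged = True
            break
        b[include] *= rel

    # geometric-mean-1 normalization keeps the ratio structure, fixes scale
    g = np.exp(np.mean(np.log(b[include])))
    b = b / g
    b_out = np.where(include, b, np.nan)
    denom = np.outer(np.where(include, b, 1.0), np.where(include, b, 1.0))
    values = raw / denom
    info = matrix.informative & np.outer(include, include)
    values = np.where(info, values, 0.0)
    balanced = ContactMatrix(values, info, matrix.axis.copy(), matrix.level)
    return BalancedMatrix(balanced, b_out, it, converged)


def quantile_normalize(matrices: list[ContactMatrix],
                       ties: str = "stable") -> list[ContactMatrix]:
    """Quantile-normalize the informative upper-triangle values of a group.

    All matrices are restricted to the intersection of their informative
    masks (pixels informative in only some replicates are dropped from
    all, keeping the rank machinery well-defined). Each value is replaced
    by the mean, across matrices, of the values sharing its rank.

    ``ties`` controls tied values within a matrix: "stable" (default)
    assigns reference values by stable sort order, so the sorted
    informative vectors of all matrices come out exactly identical even
    for zero-inflated count data; "average" gives tied values the mean of
    their tied rank-means (the microarray convention), which preserves
    within-matrix equality of tied pixels but only approximates
    distribution identity when tie structures differ between replicates.
    """
    if ties not in {"stable", "average"}:
        raise ValueError(f"unknown tie convention {ties!r}")
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to quantile normalize")
    n = matrices[0].n
    for m in matrices[1:]:
        if m.n != n:
            raise ValueError("matrices must share an axis")
    inter = np.logical_and.reduce([m.informative for m in matrices])
    iu, ju = np.triu_indices(n)
    keep = inter[iu, ju]
    iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        raise ValueError("informative masks are disjoint; nothing to normalize")

    vectors = np.stack([m.values[iu, ju] for m in matrices])
    order = np.argsort(vectors, axis=1, kind="stable")
    ref = np.mean(np.take_along_axis(vectors, order, axis=1), axis=0)

    out: list[ContactMatrix] = []
    for k, m in enumerate(matrices):
        v = vectors[k]
        assigned = np.empty_like(ref)
        assigned[order[k]] = ref
        if ties == "average":
            uniq, inv, counts = np.unique(v, return_inverse=True,
                                          return_counts=True)
            if len(uniq) < len(v):
                sums = np.bincount(inv, weights=assigned)
                assigned = (sums / counts)[inv]
        values = np.zeros((n, n))
        values[iu, ju] = assigned
        values[ju, iu] = assigned
        out.append(ContactMatrix(values, inter.copy(), m.axis.copy(), m.level))
    return out
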