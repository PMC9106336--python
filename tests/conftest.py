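"""Shared fixtures: tiny hand-checkable designs and random matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from loopscore.intervals_io import GenomicInterval
from loopscore.matrix import ContactMatrix, Primer, PrimerDesign


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_design(n_fragments: int, fragment_length: int = 2000,
                chrom: str = "chrT") -> PrimerDesign:
    """A uniform-fragment design with the four-state orientation cycle."""
    cycle = ("FOR", "LREV", "REV", "LFOR")
    fragments = [GenomicInterval(chrom, i * fragment_length, (i + 1) * fragment_length)
                 for i in range(n_fragments)]
    primers = [Primer(f"P{i}_{cycle[i % 4]}", i, cycle[i % 4],
                      GenomicInterval(chrom, f.start, f.start + 30))
               for i, f in enumerate(fragments)]
    return PrimerDesign(primers, fragments)


@pytest.fixture()
def small_design() -> PrimerDesign:
    return make_design(8)


def random_contact_matrix(n: int, rng: np.random.Generator,
                          density: float = 1.0, level: str = "bin",
                          bin_size: int = 4000) -> ContactMatrix:
    """Random symmetric non-negative matrix with a symmetric mask."""
    vals = rng.integers(0, 20, size=(n, n)).astype(float)
    vals = np.triu(vals) + np.triu(vals, 1).T
    info = rng.random((n, n)) < density
    info = np.triu(info) | np.triu(info, 1).T
    vals[~info] = 0.0
    axis = pd.DataFrame({"chrom": "chrT",
                         "start": np.arange(n) * bin_size,
                         "end": (np.arange(n) + 1) * bin_size})
    return ContactMatrix(vals, info, axis, level=level)
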