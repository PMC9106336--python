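"""Genomic interval primitives and plain-text readers/writers.

Every coordinate in this package is 0-based, half-open (BED convention).
Dialects that use 1-based inclusive coordinates must be converted at the
reader boundary; nothing downstream ever re-interprets coordinates.
Strand is ignored throughout: the loop/peak logic implemented here is
strand-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "Enhancer",
    "Loop",
    "DEStatus",
    "GeneRecord",
    "BedParseError",
    "overlaps",
    "midpoint",
    "read_bed",
    "write_bed",
    "read_enhancers",
    "write_enhancers",
    "read_bedpe",
    "write_bedpe",
    "read_gene_table",
    "write_gene_table",
]


class BedParseError(ValueError):
    """A malformed line in a BED/BEDPE/TSV input; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval must satisfy end > start, got [{self.start}, {self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak interval with the name of the peak set it came from."""

    interval: GenomicInterval
    label: str = ""


@dataclass(frozen=True)
class Enhancer:
    """An enhancer interval, flagged activity-induced or constitutive."""

    interval: GenomicInterval
    inducible: bool = False


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two same-chromosome anchors ordered by coordinate.

    Anchors are stored so ``anchor1`` is the upstream (lower-coordinate)
    anchor; construction reorders them if needed. Overlapping anchors are
    rejected because a loop's two feet must be distinct loci.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if a.chrom == b.chrom:
            if b.start < a.start or (b.start == a.start and b.end < a.end):
                object.__setattr__(self, "anchor1", b)
                object.__setattr__(self, "anchor2", a)
                a, b = b, a
            if a.start < b.end and b.start < a.end:
                raise ValueError(f"loop anchors overlap: {a} vs {b}")

    @property
    def is_cis(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


@dataclass(frozen=True)
class DEStatus:
    """Differential-expression result of one gene under one contrast."""

    log2fc: float
    adj_p: float
    expressed: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p must lie in [0, 1], got {self.adj_p}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS, curated class label, and per-contrast DE status.

    ``class_label`` records curated membership (IEG / LRG / constitutive /
    other); the analysis-time expression class is assigned downstream from
    the DE table, not taken from this field.
    """

    gene_id: str
    tss: GenomicInterval
    class_label: str = "other"
    de_status: Mapping[str, DEStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tss.span != 1:
            raise ValueError(
                f"TSS of {self.gene_id} must be a width-1 interval, got span {self.tss.span}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap predicate; touching intervals do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def midpoint(a: GenomicInterval) -> int:
    """Integer midpoint, floored (anchor widths may be odd)."""
    return (a.start + a.end) // 2


def _parse_int(text: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise BedParseError(
            f"{path}:{lineno}: cannot parse {what} from {text!r}"
        ) from None


def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3+ file into peaks (4th column = peak-set label)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
            start = _parse_int(cols[1], str(path), lineno, "start")
            end = _parse_int(cols[2], str(path), lineno, "end")
            try:
                iv = GenomicInterval(cols[0], start, end)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            label = cols[3] if len(cols) > 3 else ""
            peaks.append(Peak(iv, label))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.label}\n")


def read_enhancers(path: str | Path) -> list[Enhancer]:
    """Read enhancers from BED3+; column 7 (if present) flags inducibility.

    Column 7 values ``inducible``/``1``/``true`` mark activity-induced
    enhancers; anything else (or a missing column) means constitutive.
    """
    enhancers: list[Enhancer] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
            start = _parse_int(cols[1], str(path), lineno, "start")
            end = _parse_int(cols[2], str(path), lineno, "end")
            try:
                iv = GenomicInterval(cols[0], start, end)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            inducible = len(cols) > 6 and cols[6].strip().lower() in {"inducible", "1", "true"}
            enhancers.append(Enhancer(iv, inducible))
    return enhancers


def write_enhancers(enhancers: Iterable[Enhancer], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            flag = "inducible" if e.inducible else "constitutive"
            fh.write(
                f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}"
                f"\tenhancer\t0\t.\t{flag}\n"
            )


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read cis loops from BEDPE; trans entries are skipped with a warning.

    Anchors are reordered so anchor1 is upstream, per the Loop invariant.
    """
    loops: list[Loop] = []
    n_trans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(cols)}")
            c1, s1, e1, c2, s2, e2 = cols[:6]
            if c1 != c2:
                n_trans += 1
                continue
            try:
                a = GenomicInterval(c1, _parse_int(s1, str(path), lineno, "start1"),
                                    _parse_int(e1, str(path), lineno, "end1"))
                b = GenomicInterval(c2, _parse_int(s2, str(path), lineno, "start2"),
                                    _parse_int(e2, str(path), lineno, "end2"))
                loops.append(Loop(a, b))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    if n_trans:
        warnings.warn(f"{path}: skipped {n_trans} trans (different-chromosome) entries",
                      stacklevel=2)
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_gene_table(path: str | Path, contrasts: Iterable[str]) -> list[GeneRecord]:
    """Read the gene TSV: gene_id, chrom, tss, class_label, then per-contrast
    columns log2fc_<c>, padj_<c>, expressed_<c>."""
    contrasts = list(contrasts)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    for c in contrasts:
        for col in (f"log2fc_{c}", f"padj_{c}", f"expressed_{c}"):
            if col not in df.columns:
                raise BedParseError(f"{path}: missing column {col!r} for contrast {c!r}")
    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        tss_pos = int(getattr(row, "tss"))
        de = {
            c: DEStatus(
                log2fc=float(getattr(row, f"log2fc_{c}")),
                adj_p=float(getattr(row, f"padj_{c}")),
                expressed=bool(getattr(row, f"expressed_{c}")),
            )
            for c in contrasts
        }
        genes.append(
            GeneRecord(
                gene_id=str(getattr(row, "gene_id")),
                tss=GenomicInterval(str(getattr(row, "chrom")), tss_pos, tss_pos + 1),
                class_label=str(getattr(row, "class_label")),
                de_status=de,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path,
                     contrasts: Iterable[str]) -> None:
    contrasts = list(contrasts)
    rows = []
    for g in genes:
        row: dict[str, object] = {
            "gene_id": g.gene_id,
            "chrom": g.tss.chrom,
            "tss": g.tss.start,
            "class_label": g.class_label,
        }
        for c in contrasts:
            st = g.de_status[c]
            row[f"log2fc_{c}"] = st.log2fc
            row[f"padj_{c}"] = st.adj_p
            row[f"expressed_{c}"] = int(st.expressed)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
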