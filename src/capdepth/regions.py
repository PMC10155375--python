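"""Genomic interval algebra and transcript-model handling.

All coordinates are 0-based half-open (BED / genePred convention). The
:class:`IntervalSet` is the unit of every target / coding-region computation:
merging follows BEDTools semantics (book-ended intervals merge by default),
subtraction and intersection operate on the covered base sets, and extension
pads intervals symmetrically with clamping to chromosome bounds.

Transcript tables are read in the UCSC genePred / refFlat dialects; coding
exons are the per-exon intersection with the CDS interval. Strand is kept for
record fidelity but plays no role in the interval algebra, which is
strand-agnostic by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TranscriptModel",
    "PanelDefinition",
    "parse_genepred",
    "coding_exons",
    "merge",
    "extend",
    "subtract",
    "intersect",
    "total_bp",
    "build_panel",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval`.

    Instances are kept sorted by (chrom, start). ``merged`` records whether
    the set is known to contain no overlapping or abutting intervals on any
    chromosome.
    """

    __slots__ = ("intervals", "merged")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), merged: bool = False):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.merged = merged

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        inner = ", ".join(f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.intervals[:4])
        if len(self.intervals) > 4:
            inner += f", ... ({len(self.intervals)} total)"
        return f"IntervalSet([{inner}], merged={self.merged})"

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Intervals grouped per chromosome as an (n, 2) int array."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class TranscriptModel:
    """A transcript with its exon structure and CDS bounds (0-based half-open)."""

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exon_starts: list[int]
    exon_ends: list[int]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(
                f"{self.transcript_id}: exon start/end lists differ in length"
            )
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty or inverted exon ({s}, {e})")
        for i in range(1, len(self.exon_starts)):
            if self.exon_starts[i] < self.exon_ends[i - 1]:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.transcript_id}: cds_start > cds_end")
        if self.is_coding:
            if self.cds_start < self.exon_starts[0] or self.cds_end > self.exon_ends[-1]:
                raise ValueError(
                    f"{self.transcript_id}: CDS outside the transcript's exon span"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def coding_length(self) -> int:
        if not self.is_coding:
            return 0
        return total_bp(coding_exons(self))


@dataclass
class PanelDefinition:
    """A named set of transcripts (e.g. a disease-gene panel)."""

    transcripts: list[TranscriptModel]
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError(f"panel {self.name!r}: duplicate transcript_ids")


class GenePredParseError(ValueError):
    """Raised on a malformed genePred / refFlat line."""


def parse_genepred(table_text: str) -> list[TranscriptModel]:
    """Parse genePred or refFlat lines into :class:`TranscriptModel` records.

    Both UCSC dialects are accepted: plain genePred
    (name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd, exonCount,
    exonStarts, exonEnds) and refFlat, which prepends a geneName column.
    Exon lists are comma-separated and may carry a trailing comma.
    Transcripts with ``cdsStart == cdsEnd`` are parsed but flagged non-coding
    via :attr:`TranscriptModel.is_coding`.
    """
    models: list[TranscriptModel] = []
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 4 and fields[2] in ("+", "-"):
            gene, name, rest = fields[0], fields[0], fields[1:]
        elif len(fields) >= 5 and fields[3] in ("+", "-"):
            gene, name, rest = fields[0], fields[1], fields[2:]
        else:
            raise GenePredParseError(
                f"line {lineno}: cannot locate strand column (not genePred/refFlat?)"
            )
        if len(rest) < 9:
            raise GenePredParseError(f"line {lineno}: expected >= 9 transcript fields")
        chrom, strand = rest[0], rest[1]
        try:
            cds_start, cds_end = int(rest[4]), int(rest[5])
            exon_count = int(rest[6])
            exon_starts = [int(x) for x in rest[7].rstrip(",").split(",") if x]
            exon_ends = [int(x) for x in rest[8].rstrip(",").split(",") if x]
        except ValueError as exc:
            raise GenePredParseError(f"line {lineno}: {exc}") from exc
        if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
            raise GenePredParseError(
                f"line {lineno}: exonCount={exon_count} but lists have "
                f"{len(exon_starts)}/{len(exon_ends)} entries"
            )
        try:
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            raise GenePredParseError(f"line {lineno}: {exc}") from exc
    return models


def coding_exons(t: TranscriptModel) -> IntervalSet:
    """Per-exon intersection with the CDS; empty intersections are dropped."""
    if not t.is_coding:
        raise ValueError(f"{t.transcript_id} is non-coding (cdsStart == cdsEnd)")
    out = []
    for s, e in zip(t.exon_starts, t.exon_ends):
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo < hi:
            out.append(GenomicInterval(t.chrom, lo, hi))
    return IntervalSet(out, merged=True)


def merge(s: IntervalSet, merge_bookended: bool = True) -> IntervalSet:
    """Collapse overlapping (and, by default, abutting) intervals.

    ``merge_bookended=True`` reproduces the BEDTools default in which
    (10, 20) and (20, 30) fuse into (10, 30).
    """
    out: list[GenomicInterval] = []
    for chrom, arr in s.by_chrom().items():
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        arr = arr[order]
        cur_s, cur_e = arr[0]
        for st, en in arr[1:]:
            joins = st <= cur_e if merge_bookended else st < cur_e
            if joins:
                cur_e = max(cur_e, en)
            else:
                out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = st, en
        out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return IntervalSet(out, merged=merge_bookended)


def extend(s: IntervalSet, pad: int, chrom_lengths: Mapping[str, int]) -> IntervalSet:
    """Widen every interval by ``pad`` bp on both sides, clamped to [0, chrom length].

    The result is re-merged, so extensions that bridge neighbouring intervals
    collapse into one.
    """
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    out = []
    for iv in s:
        if iv.chrom not in chrom_lengths:
            raise KeyError(f"chromosome {iv.chrom!r} absent from chrom_lengths")
        clen = chrom_lengths[iv.chrom]
        out.append(
            GenomicInterval(iv.chrom, max(0, iv.start - pad), min(clen, iv.end + pad))
        )
    return merge(IntervalSet(out))


def _merged_array(s: IntervalSet) -> dict[str, np.ndarray]:
    return merge(s).by_chrom() if not s.merged else s.by_chrom()


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by ``a`` and not by ``b``."""
    a_by = _merged_array(a)
    b_by = _merged_array(b)
    out: list[GenomicInterval] = []
    for chrom, arr in a_by.items():
        barr = b_by.get(chrom)
        if barr is None or len(barr) == 0:
            out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in arr)
            continue
        bs, be = barr[:, 0], barr[:, 1]
        for s, e in arr:
            cur = int(s)
            # b intervals overlapping [s, e)
            i = int(np.searchsorted(be, s, side="right"))
            while i < len(bs) and bs[i] < e:
                if bs[i] > cur:
                    out.append(GenomicInterval(chrom, cur, int(bs[i])))
                cur = max(cur, int(be[i]))
                i += 1
            if cur < e:
                out.append(GenomicInterval(chrom, cur, int(e)))
    return IntervalSet(out, merged=True)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by both ``a`` and ``b``."""
    a_by = _merged_array(a)
    b_by = _merged_array(b)
    out: list[GenomicInterval] = []
    for chrom, arr in a_by.items():
        barr = b_by.get(chrom)
        if barr is None or len(barr) == 0:
            continue
        bs, be = barr[:, 0], barr[:, 1]
        for s, e in arr:
            i = int(np.searchsorted(be, s, side="right"))
            while i < len(bs) and bs[i] < e:
                lo, hi = max(int(s), int(bs[i])), min(int(e), int(be[i]))
                if lo < hi:
                    out.append(GenomicInterval(chrom, lo, hi))
                i += 1
    return IntervalSet(out, merged=True)


def total_bp(s: IntervalSet) -> int:
    """Number of distinct bases covered (input merged internally)."""
    if len(s) == 0:
        return 0
    m = s if s.merged else merge(s)
    return int(sum(iv.end - iv.start for iv in m))


def build_panel(
    transcripts: Sequence[TranscriptModel], name: str = "panel"
) -> PanelDefinition:
    """Select the longest coding transcript per gene.

    "Longest" means maximal summed coding-exon length; ties break to the
    lexicographically smallest transcript_id.
    """
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        if not t.is_coding:
            continue
        cur = best.get(t.gene)
        if cur is None:
            best[t.gene] = t
            continue
        key_new = (-t.coding_length(), t.transcript_id)
        key_cur = (-cur.coding_length(), cur.transcript_id)
        if key_new < key_cur:
            best[t.gene] = t
    return PanelDefinition(transcripts=list(best.values()), name=name)


def read_bed(path_or_text: str, is_text: bool = False) -> IntervalSet:
    """Read a 3+-column BED file (or raw text) into an IntervalSet."""
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet(out)


def write_bed(s: IntervalSet, path: str) -> None:
    """Write intervals as 3-column BED (tab-separated, no header)."""
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def gap_report(
    rows: Sequence[tuple[str, str, IntervalSet, IntervalSet]], path: str
) -> None:
    """Write a TSV of coding sequence each kit fails to target.

    ``rows`` are (kit name, annotation name, coding regions, kit targets);
    the report gives the untargeted bases and interval count per pair.
    """
    with open(path, "w") as fh:
        fh.write("kit\tannotation\tmissing_bp\tmissing_intervals\n")
        for kit, annotation, coding, targets in rows:
            gap = subtract(coding, targets)
            fh.write(f"{kit}\t{annotation}\t{total_bp(gap)}\t{len(gap)}\n")
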