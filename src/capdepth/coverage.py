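"""Per-base coverage statistics over target intervals.

A :class:`CoverageProfile` holds an integer depth value for every base of a
merged target :class:`~capdepth.regions.IntervalSet`, concatenated in target
order. On top of it sit the statistics this package exists for:

* completeness — the fraction of target bases covered at or above a depth
  threshold (the familiar "% of coding bases >= 20x");
* evenness — the fraction of sequenced bases that would not need to move
  from above-mean to below-mean positions to equalise coverage (1 means
  perfectly uniform, and the score is largely depth-independent);
* GC stratification — GC content of insufficiently vs sufficiently covered
  sub-target regions, compared with a two-sided rank-sum test;
* panel coverage — per-transcript coverage adequacy for a gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .regions import (
    GenomicInterval,
    IntervalSet,
    PanelDefinition,
    coding_exons,
    merge,
    total_bp,
)

__all__ = [
    "CoverageProfile",
    "CompletenessResult",
    "GCStratification",
    "PanelCoverageResult",
    "load_depth",
    "completeness",
    "evenness",
    "low_coverage_regions",
    "gc_fraction",
    "gc_stratification",
    "panel_coverage",
    "load_genome",
]


class CoverageProfile:
    """Per-base integer depth over a merged target interval set.

    ``depth`` is aligned to the concatenation of target bases in
    (chrom, start) order; ``offsets[i]`` is the index of target i's first base.
    """

    __slots__ = ("targets", "depth", "offsets")

    def __init__(self, targets: IntervalSet, depth: np.ndarray):
        if not targets.merged:
            targets = merge(targets)
        lengths = np.fromiter((len(iv) for iv in targets), dtype=np.int64)
        depth = np.asarray(depth, dtype=np.int64)
        if depth.ndim != 1 or len(depth) != int(lengths.sum()):
            raise ValueError(
                f"depth length {len(depth)} != total target bases {int(lengths.sum())}"
            )
        if np.any(depth < 0):
            raise ValueError("depths must be non-negative")
        self.targets = targets
        self.depth = depth
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])

    @property
    def total_bases(self) -> int:
        return int(len(self.depth))

    @property
    def mean_coverage(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    def target_slices(self):
        """Yield (interval, depth slice) pairs in target order."""
        for i, iv in enumerate(self.targets):
            yield iv, self.depth[self.offsets[i] : self.offsets[i + 1]]

    def locate(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth slice for a genomic subinterval fully inside one target."""
        for i, iv in enumerate(self.targets):
            if iv.chrom == chrom and iv.start <= start and end <= iv.end:
                off = self.offsets[i]
                return self.depth[off + (start - iv.start) : off + (end - iv.start)]
        raise KeyError(f"{chrom}:{start}-{end} is not contained in any profile target")


@dataclass
class CompletenessResult:
    threshold: int
    fraction_covered: float
    per_target_fractions: list[float]


@dataclass
class GCStratification:
    insufficient_gc: list[float]
    sufficient_gc: list[float]
    u_statistic: float
    p_value: float
    median_insufficient: float
    median_sufficient: float
    applicable: bool = True


@dataclass
class PanelCoverageResult:
    fraction_fully_covered: float
    fraction_q_covered: float
    q: float
    threshold: int
    per_transcript_fractions: dict[str, float]


def load_depth(path_or_text: str, targets: IntervalSet, is_text: bool = False) -> CoverageProfile:
    """Build a profile from a bedGraph (4-column) or per-base depth TSV (3-column).

    bedGraph records are run-length encoded ``chrom start end depth``; the
    3-column form is ``chrom pos0 depth``. Target bases absent from the track
    get depth 0. Overlapping track records are an error (ambiguous depth).
    """
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    records: dict[str, list[tuple[int, int, int]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 4:
            chrom, s, e, d = fields[0], int(fields[1]), int(fields[2]), int(float(fields[3]))
        elif len(fields) == 3:
            chrom, s = fields[0], int(fields[1])
            e, d = s + 1, int(float(fields[2]))
        else:
            raise ValueError(f"depth track line {lineno}: expected 3 or 4 columns")
        records.setdefault(chrom, []).append((s, e, d))

    track_chroms = set(records)
    for chrom, recs in records.items():
        recs.sort()
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping depth records on {chrom} at {s2} < {e1} (ambiguous)"
                )

    if not targets.merged:
        targets = merge(targets)
    depth_parts = []
    for iv in targets:
        arr = np.zeros(len(iv), dtype=np.int64)
        for s, e, d in records.get(iv.chrom, ()):
            lo, hi = max(s, iv.start), min(e, iv.end)
            if lo < hi:
                arr[lo - iv.start : hi - iv.start] = d
        depth_parts.append(arr)
    # targets on chromosomes entirely absent from a non-empty track are suspicious
    missing = set(targets.chromosomes()) - track_chroms
    if track_chroms and missing == set(targets.chromosomes()):
        raise ValueError(
            f"no depth track chromosome matches the targets ({sorted(missing)})"
        )
    depth = np.concatenate(depth_parts) if depth_parts else np.zeros(0, dtype=np.int64)
    return CoverageProfile(targets, depth)


def completeness(p: CoverageProfile, threshold: int) -> CompletenessResult:
    """Fraction of target bases with depth >= ``threshold``."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    if p.total_bases == 0:
        raise ValueError("empty coverage profile")
    covered = p.depth >= threshold
    per_target = [
        float(covered[p.offsets[i] : p.offsets[i + 1]].mean())
        for i in range(len(p.targets))
    ]
    return CompletenessResult(
        threshold=threshold,
        fraction_covered=float(covered.mean()),
        per_target_fractions=per_target,
    )


def evenness(p: CoverageProfile | np.ndarray, method: str = "closed_form") -> float:
    """Evenness of coverage in [0, 1]; 1 iff depth is constant.

    ``closed_form``: E = 1 - sum(max(0, c_i - mu)) / sum(c_i), the fraction of
    sequenced bases that need no redistribution from above-mean to below-mean
    positions. Computed with exact integer arithmetic
    (sum max(0, n*c_i - S) / (n*S)) so the score is exactly invariant under
    integer depth scaling.

    ``cumulative``: E = (1/floor(mu)) * sum_{k=1..floor(mu)} F(k) with F(k)
    the fraction of bases at depth >= k; defined only for mu >= 1. The two
    forms agree when mu is an integer.
    """
    depth = p.depth if isinstance(p, CoverageProfile) else np.asarray(p, dtype=np.int64)
    if len(depth) == 0:
        raise ValueError("empty depth vector")
    total = int(depth.sum())
    if total == 0:
        raise ValueError("all-zero depth: evenness undefined")
    n = len(depth)
    if method == "closed_form":
        scaled = depth.astype(object) * n - total
        excess = int(np.sum(np.where(scaled > 0, scaled, 0)))
        return 1.0 - float(Fraction(excess, n * total))
    if method == "cumulative":
        mu_floor = total // n
        if mu_floor < 1:
            raise ValueError("cumulative evenness requires mean depth >= 1")
        ks = np.arange(1, mu_floor + 1)
        fracs = [(depth >= k).mean() for k in ks]
        return float(np.mean(fracs))
    raise ValueError(f"unknown evenness method {method!r}")


def _runs(mask: np.ndarray):
    """(start, end) index pairs of maximal True runs in a boolean vector."""
    if len(mask) == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def low_coverage_regions(p: CoverageProfile, threshold: int) -> IntervalSet:
    """Maximal runs of target bases with depth < threshold, in genomic coordinates.

    Runs never cross target boundaries, so two adjacent fully-low targets give
    two regions.
    """
    out = []
    for iv, d in p.target_slices():
        for s, e in _runs(d < threshold):
            out.append(GenomicInterval(iv.chrom, iv.start + s, iv.start + e))
    return IntervalSet(out, merged=False)


_GC = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; N/ambiguity codes excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    denom = sum(1 for b in seq if b in _UNAMBIG)
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    gc = sum(1 for b in seq if b in _GC)
    return gc / denom


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence for [start, end) from a dict of strings or a pyfaidx.Fasta."""
    rec = genome[chrom]
    seg = rec[start:end]
    return seg if isinstance(seg, str) else str(seg)


def load_genome(path: str):
    """Open an indexed FASTA as a sequence source for GC computations."""
    import pyfaidx

    return pyfaidx.Fasta(path)


def gc_stratification(
    p: CoverageProfile, genome: Mapping[str, str], threshold: int
) -> GCStratification:
    """GC of low-coverage vs adequately covered sub-target regions, rank-sum tested.

    Regions are maximal same-status base runs within each target. The test is
    a two-sided two-sample rank-sum (Mann-Whitney U); exact when both strata
    are small and tie-free, normal approximation with tie correction otherwise.
    """
    low: list[float] = []
    high: list[float] = []
    for iv, d in p.target_slices():
        mask = d < threshold
        for s, e in _runs(mask):
            low.append(gc_fraction(_fetch(genome, iv.chrom, iv.start + s, iv.start + e)))
        for s, e in _runs(~mask):
            high.append(gc_fraction(_fetch(genome, iv.chrom, iv.start + s, iv.start + e)))
    if not low or not high:
        return GCStratification(
            insufficient_gc=low,
            sufficient_gc=high,
            u_statistic=float("nan"),
            p_value=float("nan"),
            median_insufficient=float(np.median(low)) if low else float("nan"),
            median_sufficient=float(np.median(high)) if high else float("nan"),
            applicable=False,
        )
    exact_ok = (len(low) + len(high)) < 20 and len(set(low) | set(high)) == len(low) + len(high)
    res = stats.mannwhitneyu(
        low, high, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    return GCStratification(
        insufficient_gc=low,
        sufficient_gc=high,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_insufficient=float(np.median(low)),
        median_sufficient=float(np.median(high)),
    )


def panel_coverage(
    p: CoverageProfile,
    panel: PanelDefinition,
    threshold: int,
    q: float = 0.95,
) -> PanelCoverageResult:
    """Per-transcript coverage adequacy for a panel.

    A transcript is *fully covered* when every coding base has depth >=
    ``threshold``; *q-covered* when at least fraction ``q`` of its coding
    bases do. Coding exons must lie inside the profile's targets.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    fracs: dict[str, float] = {}
    for t in panel.transcripts:
        depths = []
        for iv in coding_exons(t):
            try:
                depths.append(p.locate(iv.chrom, iv.start, iv.end))
            except KeyError as exc:
                raise KeyError(
                    f"transcript {t.transcript_id}: coding exon outside profile targets"
                ) from exc
        d = np.concatenate(depths)
        fracs[t.transcript_id] = float((d >= threshold).mean())
    n = len(fracs)
    if n == 0:
        raise ValueError("panel has no coding transcripts")
    fully = sum(1 for f in fracs.values() if f == 1.0) / n
    qcov = sum(1 for f in fracs.values() if f >= q) / n
    return PanelCoverageResult(
        fraction_fully_covered=fully,
        fraction_q_covered=qcov,
        q=q,
        threshold=threshold,
        per_transcript_fractions=fracs,
    )
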