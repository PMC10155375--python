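"""Variant-detection sensitivity: AF filtering, callset comparison and a
depth-conditioned binomial detection model.

The detection model replaces a full variant caller with the part of it that
depth actually drives: at a site of depth ``d`` and variant allele fraction
``v``, the alternate-read count is Binomial(d, v), and the variant is
detected when that count reaches ``min_alt`` and the site depth reaches
``min_depth``. Sequencing error is ignored. Callset comparison mirrors
clinical concordance bookkeeping: filter both sets to common variants
(population AF strictly above a cutoff), then set-compare by
(chrom, pos, ref, alt, sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .coverage import CoverageProfile

__all__ = [
    "VariantRecord",
    "SimVariantTruth",
    "CallsetComparison",
    "filter_common",
    "detect_variants",
    "compare_callsets",
    "qual_fraction_below",
    "read_vcf",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    af: Optional[float] = None
    qual: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)


@dataclass(frozen=True)
class SimVariantTruth:
    """A simulated variant: index into the profile's target-base array plus VAF."""

    pos: int
    vaf: float

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 1:
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass
class CallsetComparison:
    """Set comparison of two filtered callsets.

    ``lost_a_only`` counts variants present only in A, ``lost_b_only`` those
    only in B, so ``n_a == shared + lost_a_only`` and
    ``n_b == shared + lost_b_only``.
    """

    n_a: int
    n_b: int
    shared: int
    lost_a_only: int
    lost_b_only: int

    @property
    def lost_fraction(self) -> float:
        """Fraction of A's variants absent from B (0 when A is empty)."""
        return self.lost_a_only / self.n_a if self.n_a else 0.0


def filter_common(
    vs: Iterable[VariantRecord], af_min: float
) -> tuple[list[VariantRecord], int]:
    """Keep records with population AF strictly greater than ``af_min``.

    Records lacking an AF annotation are dropped; the count of dropped
    records is returned alongside the kept list.
    """
    if not 0 <= af_min < 1:
        raise ValueError(f"af_min must be in [0, 1), got {af_min}")
    kept, n_missing = [], 0
    for v in vs:
        if v.af is None:
            n_missing += 1
        elif v.af > af_min:
            kept.append(v)
    return kept, n_missing


def detect_variants(
    p: CoverageProfile,
    truth: Sequence[SimVariantTruth],
    min_alt: int = 4,
    min_depth: int = 8,
    seed: int = 0,
) -> list[SimVariantTruth]:
    """Binomial depth-conditioned detection of simulated variants.

    For each truth variant the alternate-read count is drawn
    Binomial(depth at pos, vaf); the variant is detected iff that count is
    >= ``min_alt`` and the depth is >= ``min_depth``.
    """
    if min_alt < 1:
        raise ValueError("min_alt must be >= 1")
    rng = np.random.default_rng(seed)
    detected = []
    n = p.total_bases
    for t in truth:
        if t.pos >= n:
            raise IndexError(f"truth position {t.pos} outside profile ({n} bases)")
        d = int(p.depth[t.pos])
        if d < min_depth or d == 0:
            continue
        alt = rng.binomial(d, t.vaf)
        if alt >= min_alt:
            detected.append(t)
    return detected


def compare_callsets(
    a: Sequence[VariantRecord], b: Sequence[VariantRecord], af_min: float = 0.001
) -> CallsetComparison:
    """AF-filter both callsets, then set-compare by (chrom, pos, ref, alt, sample)."""
    fa, _ = filter_common(a, af_min)
    fb, _ = filter_common(b, af_min)
    keys_a = [v.key for v in fa]
    keys_b = [v.key for v in fb]
    for name, keys in (("a", keys_a), ("b", keys_b)):
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant keys within callset {name}")
    sa, sb = set(keys_a), set(keys_b)
    shared = len(sa & sb)
    return CallsetComparison(
        n_a=len(sa),
        n_b=len(sb),
        shared=shared,
        lost_a_only=len(sa - sb),
        lost_b_only=len(sb - sa),
    )


def qual_fraction_below(vs: Sequence[VariantRecord], qual_cut: float) -> float:
    """Fraction of quality-bearing records with qual strictly below the cut."""
    quals = [v.qual for v in vs if v.qual is not None]
    if not quals:
        raise ValueError("no records carry a quality score")
    return sum(1 for q in quals if q < qual_cut) / len(quals)


def read_vcf(path: str, sample_id: str = "", af_key: str = "AF") -> list[VariantRecord]:
    """Read a VCF into VariantRecords (QUAL column; AF from INFO ``af_key``).

    Multi-allelic sites expand to one record per ALT; per-allele AF values
    are matched positionally when the INFO field is a tuple.
    """
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            af_val = rec.info.get(af_key) if af_key in rec.info else None
            for i, alt in enumerate(rec.alts or ()):
                if isinstance(af_val, tuple):
                    af = float(af_val[i]) if i < len(af_val) and af_val[i] is not None else None
                else:
                    af = float(af_val) if af_val is not None else None
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        af=af,
                        qual=float(rec.qual) if rec.qual is not None else None,
                        sample_id=sample_id,
                    )
                )
    return out
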