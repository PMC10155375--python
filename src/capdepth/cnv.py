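"""Read-depth CNV calling via SVD-denoised z-scored RPKM (Conifer-style).

The pipeline: probe read counts are normalised to RPKM (reads per kilobase
of probe per million mapped reads), z-scored per probe against the median
and standard deviation of a reference pool (ZRPKM), denoised by zeroing the
top-k singular components of the probes x samples matrix (which absorb the
systematic capture/sequencing batch structure), and thresholded into
contiguous same-sign probe runs: deletions at ZRPKM <= -threshold,
duplications at >= +threshold (default 1.7, with k = 3 components removed
as read off the scree plot).

Probes whose reference-pool median RPKM falls below a floor (default 1.0)
are excluded before z-scoring — they carry too little signal to normalise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .regions import GenomicInterval

__all__ = [
    "ProbeCountMatrix",
    "ZRPKMMatrix",
    "ScreeData",
    "CNVCall",
    "TruthCNV",
    "TruthEvaluation",
    "rpkm",
    "zrpkm",
    "svd_denoise",
    "call_cnvs",
    "evaluate_truth",
    "read_counts_tsv",
    "write_counts_tsv",
]

logger = logging.getLogger(__name__)

RPKM_MEDIAN_FLOOR = 1.0
STD_FLOOR = 1e-6


@dataclass
class ProbeCountMatrix:
    """Probes x samples read counts with probe geometry and library sizes."""

    probes: list[GenomicInterval]
    samples: list[str]
    counts: np.ndarray
    total_reads: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.total_reads = np.asarray(self.total_reads, dtype=np.float64)
        if self.counts.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({len(self.probes)}, {len(self.samples)})"
            )
        if len(self.total_reads) != len(self.samples):
            raise ValueError("total_reads length != number of samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class ZRPKMMatrix:
    """Per-probe z-scores of RPKM against a reference pool."""

    values: np.ndarray  # kept probes x samples
    probes: list[GenomicInterval]  # kept probes only, genomic order
    samples: list[str]
    reference_median: np.ndarray
    reference_std: np.ndarray
    excluded_probes: list[int]  # indices into the original probe list
    reference_samples: list[str] = field(default_factory=list)


@dataclass
class ScreeData:
    singular_values: np.ndarray
    k_removed: int


@dataclass
class CNVCall:
    sample_id: str
    probe_start: int  # inclusive index into the kept-probe list
    probe_end: int  # exclusive
    chrom: str
    start: int  # genomic span
    end: int
    type: str  # "deletion" | "duplication"
    extremal_score: float
    n_probes: int


@dataclass(frozen=True)
class TruthCNV:
    sample_id: str
    probe_start: int  # inclusive, kept-probe indices
    probe_end: int  # exclusive
    type: str


@dataclass
class TruthEvaluation:
    """Status per truth CNV in the vocabulary used for validated-CNV review:
    called / segmented (m of n passing sub-runs recovered) /
    cannot_exceed_threshold / not_called."""

    status: str
    segments_called: int = 0
    segments_total: int = 0


def rpkm(m: ProbeCountMatrix) -> np.ndarray:
    """counts / ((probe_length/1e3) * (library_total/1e6)), probes x samples."""
    lengths = np.array([len(p) for p in m.probes], dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("probe lengths must be positive")
    bad = np.flatnonzero(m.total_reads <= 0)
    if len(bad):
        raise ValueError(f"zero total reads for sample(s): {[m.samples[i] for i in bad]}")
    return m.counts / (lengths[:, None] / 1e3) / (m.total_reads[None, :] / 1e6)


def zrpkm(
    m: ProbeCountMatrix,
    reference_samples: Sequence[str],
    median_floor: float = RPKM_MEDIAN_FLOOR,
) -> ZRPKMMatrix:
    """Z-score RPKM per probe against the reference pool's median and std.

    Probes with reference median RPKM below ``median_floor`` are excluded
    (and listed); a reference std that vanishes is floored at 1e-6 with a
    logged warning.
    """
    ref_idx = [m.samples.index(s) for s in reference_samples]
    if len(ref_idx) < 8:
        raise ValueError(f"need >= 8 reference samples, got {len(ref_idx)}")
    r = rpkm(m)
    ref = r[:, ref_idx]
    med = np.median(ref, axis=1)
    std = ref.std(axis=1, ddof=1)
    keep = med >= median_floor
    excluded = list(np.flatnonzero(~keep))
    n_degenerate = int(np.sum(std[keep] < STD_FLOOR))
    if n_degenerate:
        logger.warning("%d kept probe(s) have near-zero reference std; floored", n_degenerate)
    std = np.maximum(std, STD_FLOOR)
    values = (r[keep] - med[keep, None]) / std[keep, None]
    return ZRPKMMatrix(
        values=values,
        probes=[p for p, k in zip(m.probes, keep) if k],
        samples=list(m.samples),
        reference_median=med[keep],
        reference_std=std[keep],
        excluded_probes=excluded,
        reference_samples=list(reference_samples),
    )


def svd_denoise(values: np.ndarray, k: int) -> tuple[np.ndarray, ScreeData]:
    """Zero the top-k singular components of the probes x samples matrix."""
    values = np.asarray(values, dtype=np.float64)
    n_comp = min(values.shape)
    if not 0 <= k < n_comp:
        raise ValueError(f"k must be in [0, {n_comp}), got {k}")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    s_kept = s.copy()
    s_kept[:k] = 0.0
    denoised = (u * s_kept) @ vt
    return denoised, ScreeData(singular_values=s, k_removed=k)


def call_cnvs(
    denoised: np.ndarray,
    probes: Sequence[GenomicInterval],
    samples: Sequence[str],
    threshold: float = 1.7,
    min_probes: int = 3,
    call_samples: Optional[Sequence[str]] = None,
) -> list[CNVCall]:
    """Threshold the denoised matrix into contiguous same-sign probe runs.

    Per sample, maximal runs of genomically consecutive same-chromosome
    probes with value <= -threshold (deletion) or >= +threshold (duplication);
    runs shorter than ``min_probes`` are discarded. A sign change breaks a run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if call_samples is None:
        call_samples = samples
    chroms = [p.chrom for p in probes]
    calls: list[CNVCall] = []
    for sid in call_samples:
        col = denoised[:, list(samples).index(sid)]
        state = np.where(col >= threshold, 1, np.where(col <= -threshold, -1, 0))
        i = 0
        n = len(state)
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i + 1
            while j < n and state[j] == state[i] and chroms[j] == chroms[i]:
                j += 1
            if j - i >= min_probes:
                run = col[i:j]
                ext = run[np.argmax(np.abs(run))]
                calls.append(
                    CNVCall(
                        sample_id=sid,
                        probe_start=i,
                        probe_end=j,
                        chrom=chroms[i],
                        start=probes[i].start,
                        end=probes[j - 1].end,
                        type="deletion" if state[i] < 0 else "duplication",
                        extremal_score=float(ext),
                        n_probes=j - i,
                    )
                )
            i = j
    return calls


def _sign_runs(col: np.ndarray, chroms: Sequence[str], lo: int, hi: int,
               sign: int, threshold: float) -> list[tuple[int, int]]:
    """Maximal matching-sign threshold-passing runs within probe window [lo, hi)."""
    runs = []
    i = lo
    while i < hi:
        passing = (col[i] * sign) >= threshold
        if not passing:
            i += 1
            continue
        j = i + 1
        while j < hi and (col[j] * sign) >= threshold and chroms[j] == chroms[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def evaluate_truth(
    calls: Sequence[CNVCall],
    denoised: np.ndarray,
    probes: Sequence[GenomicInterval],
    samples: Sequence[str],
    truth: Sequence[TruthCNV],
    threshold: float = 1.7,
) -> dict[TruthCNV, TruthEvaluation]:
    """Classify each truth CNV against the call list.

    Rules (explicit so the classification is reproducible): *called* when a
    single matching-type call covers >= 50% of the truth probes; *segmented
    m/n* when multiple matching calls jointly hit the span (n = matching-sign
    threshold-passing sub-runs inside the span, m = those recovered as
    calls); *cannot_exceed_threshold* when >= 20% of truth probes carry
    matching-sign values of at least half the threshold yet no call
    survived filtering; otherwise *not_called*.
    """
    out: dict[TruthCNV, TruthEvaluation] = {}
    chroms = [p.chrom for p in probes]
    sample_list = list(samples)
    for t in truth:
        if t.probe_end <= t.probe_start or t.probe_start < 0 or t.probe_end > len(probes):
            raise ValueError(f"truth span contains no probes: {t}")
        sign = -1 if t.type == "deletion" else 1
        col = denoised[:, sample_list.index(t.sample_id)]
        n_truth = t.probe_end - t.probe_start
        matching = [
            c
            for c in calls
            if c.sample_id == t.sample_id
            and c.type == t.type
            and c.probe_start < t.probe_end
            and c.probe_end > t.probe_start
        ]
        if matching:
            best_cov = max(
                (min(c.probe_end, t.probe_end) - max(c.probe_start, t.probe_start))
                for c in matching
            )
            if best_cov >= 0.5 * n_truth:
                out[t] = TruthEvaluation(status="called")
                continue
            sub_runs = _sign_runs(col, chroms, t.probe_start, t.probe_end, sign, threshold)
            m = len(matching)
            n_seg = max(len(sub_runs), m, 1)
            out[t] = TruthEvaluation(status="segmented", segments_called=m,
                                     segments_total=n_seg)
            continue
        window = col[t.probe_start : t.probe_end] * sign
        if np.mean(window >= threshold / 2) >= 0.2:
            out[t] = TruthEvaluation(status="cannot_exceed_threshold")
        else:
            out[t] = TruthEvaluation(status="not_called")
    return out


def read_counts_tsv(path: str, probes_bed: str) -> ProbeCountMatrix:
    """Read probes (BED) plus a counts TSV (probe rows, sample-id header).

    The TSV's first three columns must be chrom/start/end matching the BED;
    a final ``#total_reads`` row supplies library sizes (else column sums
    are used).
    """
    import pandas as pd

    from .regions import read_bed

    probes = list(read_bed(probes_bed))
    df = pd.read_csv(path, sep="\t")
    sample_cols = list(df.columns[3:])
    totals = None
    if str(df.iloc[-1, 0]) == "#total_reads":
        totals = df.iloc[-1, 3:].to_numpy(dtype=float)
        df = df.iloc[:-1]
    counts = df[sample_cols].to_numpy(dtype=float)
    if totals is None:
        totals = counts.sum(axis=0)
    if len(df) != len(probes):
        raise ValueError(f"counts rows ({len(df)}) != probes ({len(probes)})")
    return ProbeCountMatrix(probes=probes, samples=sample_cols, counts=counts,
                            total_reads=totals)


def write_counts_tsv(m: ProbeCountMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(m.samples) + "\n")
        for i, p in enumerate(m.probes):
            row = "\t".join(f"{int(c)}" for c in m.counts[i])
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{row}\n")
        fh.write("#total_reads\t0\t0\t" + "\t".join(f"{int(t)}" for t in m.total_reads) + "\n")
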