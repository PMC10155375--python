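"""Synthetic capture-kit data generator.

Emulates the statistical structure of exome capture that the analysis
modules assume, so the whole pipeline is exercisable offline:

* a kit-specific GC-dependent capture-efficiency curve (piecewise-quadratic
  around an optimum, floored at 0.02) — Agilent-like kits lose efficiency in
  low-GC targets, Twist-like kits in high-GC targets;
* per-probe lognormal efficiency dispersion that is *shared across all
  samples of a pool* (capture bias is systematic, which is exactly what
  makes SVD denoising of the z-scored matrix effective);
* per-base Poisson depth noise around the probe rate (a negative-binomial
  overdispersion parameter is exposed);
* reference pools of ~100 samples and spiked heterozygous deletions
  (depth ratio 0.5) and duplications (ratio 1.5) as CNV ground truth.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .coverage import CoverageProfile
from .regions import GenomicInterval, IntervalSet
from .cnv import ProbeCountMatrix, TruthCNV

__all__ = [
    "KitProfile",
    "SimConfig",
    "CnvSpike",
    "SimulatedPool",
    "TWIST_LIKE",
    "AGILENT_V5_LIKE",
    "AGILENT_V7_LIKE",
    "KIT_PRESETS",
    "simulate_targets",
    "simulate_depth",
    "simulate_pool",
    "spike_cnvs",
    "sample_counts",
    "write_fixtures",
]

EFFICIENCY_FLOOR = 0.02
READ_LENGTH = 150  # bp per depth-unit read when converting depth to probe counts
TARGET_GAP = 100  # bp of spacer sequence between simulated targets


@dataclass(frozen=True)
class KitProfile:
    """Parametric capture-kit model: GC-efficiency curve + probe dispersion.

    ``efficiency(gc)`` is 1 at ``gc_optimum`` and falls off quadratically on
    each side with independent curvatures, floored at 0.02. ``probe_sigma``
    is the standard deviation of per-probe log-efficiency (lognormal,
    systematic across a pool).
    """

    name: str
    gc_optimum: float = 0.45
    gc_penalty_low: float = 0.0
    gc_penalty_high: float = 0.0
    probe_sigma: float = 0.0

    def efficiency(self, gc) -> np.ndarray:
        gc = np.asarray(gc, dtype=np.float64)
        delta = gc - self.gc_optimum
        pen = np.where(delta < 0, self.gc_penalty_low, self.gc_penalty_high)
        return np.maximum(EFFICIENCY_FLOOR, 1.0 - pen * delta**2)


# Presets spanning the two observed bias regimes: older hybridisation kits
# penalised in low-GC targets with wide probe dispersion; a modern
# rebalanced kit penalised (mildly) in high-GC targets with tight dispersion.
TWIST_LIKE = KitProfile("twist_like", gc_optimum=0.45, gc_penalty_low=0.8,
                        gc_penalty_high=12.0, probe_sigma=0.2)
AGILENT_V7_LIKE = KitProfile("agilent_v7_like", gc_optimum=0.50, gc_penalty_low=8.0,
                             gc_penalty_high=1.0, probe_sigma=0.35)
AGILENT_V5_LIKE = KitProfile("agilent_v5_like", gc_optimum=0.52, gc_penalty_low=12.0,
                             gc_penalty_high=1.0, probe_sigma=0.55)
KIT_PRESETS = {k.name: k for k in (TWIST_LIKE, AGILENT_V7_LIKE, AGILENT_V5_LIKE)}


@dataclass(frozen=True)
class CnvSpike:
    """A copy-number event to spike: probe index span [start, end), depth ratio."""

    sample_id: str
    probe_start: int
    probe_end: int
    ratio: float  # 0.5 heterozygous deletion, 1.5 heterozygous duplication

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.probe_end <= self.probe_start:
            raise ValueError("empty probe span")


@dataclass
class SimConfig:
    """Study conditions for a simulated capture experiment."""

    n_targets: int = 1000
    length_mean: float = 160.0
    length_sd: float = 60.0
    length_min: int = 50
    gc_mean: float = 0.46
    gc_sd: float = 0.10
    mean_coverage: float = 100.0
    n_samples: int = 20
    n_reference: int = 100
    seed: int = 0
    overdispersion: float = 0.0  # negative-binomial 1/size; 0 = Poisson
    cnv_spec: list[CnvSpike] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_samples", "n_reference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class SimulatedPool:
    """A simulated cohort: geometry, expected per-probe read rates, truth."""

    targets: IntervalSet
    gc: np.ndarray
    sequences: dict[str, str]
    probe_effects: np.ndarray
    sample_ids: list[str]  # test samples first, then reference pool
    reference_ids: list[str]
    expected_counts: np.ndarray  # probes x samples, before Poisson sampling
    truth: list[TruthCNV] = field(default_factory=list)
    config: Optional[SimConfig] = None


def _target_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """A sequence of given length whose G+C count equals round(gc * length)."""
    n_gc = int(round(gc * length))
    n_gc = min(max(n_gc, 0), length)
    bases = np.concatenate([
        rng.choice(np.frombuffer(b"GC", dtype="S1"), n_gc),
        rng.choice(np.frombuffer(b"AT", dtype="S1"), length - n_gc),
    ])
    rng.shuffle(bases)
    return bases.tobytes().decode()


def simulate_targets(cfg: SimConfig) -> tuple[IntervalSet, np.ndarray, dict[str, str]]:
    """Targets on one synthetic chromosome, with exact-GC sequences.

    Lengths are truncated-normal integers, GC fractions clipped normal; each
    target's sequence is constructed to match its GC within one base.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    lengths = np.maximum(
        cfg.length_min,
        np.round(rng.normal(cfg.length_mean, cfg.length_sd, cfg.n_targets)).astype(int),
    )
    gcs = np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd, cfg.n_targets), 0.05, 0.95)
    chrom = "sim1"
    parts: list[str] = []
    intervals: list[GenomicInterval] = []
    pos = 0
    for L, gc in zip(lengths, gcs):
        spacer = _target_sequence(rng, TARGET_GAP, 0.5)
        parts.append(spacer)
        pos += TARGET_GAP
        parts.append(_target_sequence(rng, int(L), float(gc)))
        intervals.append(GenomicInterval(chrom, pos, pos + int(L)))
        pos += int(L)
    parts.append(_target_sequence(rng, TARGET_GAP, 0.5))
    targets = IntervalSet(intervals, merged=True)
    # realized GC (within 1 base of requested by construction)
    realized = np.array([
        (seq.count("G") + seq.count("C")) / len(seq) for seq in parts[1::2]
    ])
    return targets, realized, {chrom: "".join(parts)}


def draw_probe_effects(kit: KitProfile, n: int, pool_seed: int) -> np.ndarray:
    """Lognormal per-probe efficiencies, systematic across a pool."""
    rng = np.random.default_rng(np.random.SeedSequence([pool_seed, 202]))
    if kit.probe_sigma == 0:
        return np.ones(n)
    return rng.lognormal(mean=-0.5 * kit.probe_sigma**2, sigma=kit.probe_sigma, size=n)


def _base_rates(targets: IntervalSet, gc: np.ndarray, kit: KitProfile,
                mean_coverage: float, probe_effects: np.ndarray) -> np.ndarray:
    """Per-target expected depth, renormalized so the profile mean is exact."""
    lengths = np.array([len(iv) for iv in targets], dtype=float)
    raw = kit.efficiency(gc) * probe_effects
    scale = mean_coverage * lengths.sum() / np.sum(raw * lengths)
    return raw * scale


def simulate_depth(
    targets: IntervalSet,
    gc: np.ndarray,
    kit: KitProfile,
    mean_coverage: float,
    sample_seed: int,
    probe_effects: Optional[np.ndarray] = None,
    overdispersion: float = 0.0,
) -> CoverageProfile:
    """Per-base depth for one sample: Poisson (or NB) noise around probe rates.

    The per-target rate is mean_coverage x efficiency(gc) x probe effect,
    renormalized so the *expected* profile mean equals ``mean_coverage``.
    """
    if probe_effects is None:
        probe_effects = draw_probe_effects(kit, len(targets), sample_seed)
    rates = _base_rates(targets, gc, kit, mean_coverage, probe_effects)
    rng = np.random.default_rng(np.random.SeedSequence([sample_seed, 303]))
    parts = []
    for iv, rate in zip(targets, rates):
        n = len(iv)
        if overdispersion > 0:
            size = 1.0 / overdispersion
            lam = rng.gamma(size, rate / size, n)
            parts.append(rng.poisson(lam))
        else:
            parts.append(rng.poisson(rate, n))
    return CoverageProfile(targets, np.concatenate(parts))


def simulate_pool(cfg: SimConfig, kit: KitProfile = TWIST_LIKE) -> SimulatedPool:
    """Expected probe read rates for a test + reference cohort (no noise yet).

    Expected reads per probe = depth rate x probe length / read length, so a
    ``mean_coverage`` of 100 over a 150-bp probe expects ~100 reads.
    """
    targets, gc, seqs = simulate_targets(cfg)
    probe_effects = draw_probe_effects(kit, cfg.n_targets, cfg.seed)
    rates = _base_rates(targets, gc, kit, cfg.mean_coverage, probe_effects)
    lengths = np.array([len(iv) for iv in targets], dtype=float)
    per_probe = rates * lengths / READ_LENGTH
    test_ids = [f"test_{i:03d}" for i in range(cfg.n_samples)]
    ref_ids = [f"ref_{i:03d}" for i in range(cfg.n_reference)]
    n_total = len(test_ids) + len(ref_ids)
    expected = np.tile(per_probe[:, None], (1, n_total))
    return SimulatedPool(
        targets=targets,
        gc=gc,
        sequences=seqs,
        probe_effects=probe_effects,
        sample_ids=test_ids + ref_ids,
        reference_ids=ref_ids,
        expected_counts=expected,
        config=cfg,
    )


def spike_cnvs(pool: SimulatedPool, cnv_spec: Sequence[CnvSpike]) -> SimulatedPool:
    """Multiply expected rates inside each spike span; emit truth records.

    Applied before Poisson sampling, so a ratio-0.5 spike halves the expected
    depth across its probes. Ratio 1.0 is a no-op and yields no truth record.
    Overlapping spikes within one sample are rejected.
    """
    expected = pool.expected_counts.copy()
    truth = list(pool.truth)
    seen: dict[str, list[tuple[int, int]]] = {}
    for sp in cnv_spec:
        if sp.probe_end > expected.shape[0]:
            raise ValueError(f"spike span {sp} outside probes (n={expected.shape[0]})")
        for lo, hi in seen.get(sp.sample_id, ()):
            if sp.probe_start < hi and sp.probe_end > lo:
                raise ValueError(f"overlapping spike-ins in sample {sp.sample_id}")
        seen.setdefault(sp.sample_id, []).append((sp.probe_start, sp.probe_end))
        if sp.ratio == 1.0:
            continue
        col = pool.sample_ids.index(sp.sample_id)
        expected[sp.probe_start : sp.probe_end, col] *= sp.ratio
        truth.append(
            TruthCNV(
                sample_id=sp.sample_id,
                probe_start=sp.probe_start,
                probe_end=sp.probe_end,
                type="deletion" if sp.ratio < 1 else "duplication",
            )
        )
    return replace(pool, expected_counts=expected, truth=truth)


def sample_counts(pool: SimulatedPool, seed: int,
                  overdispersion: float = 0.0) -> ProbeCountMatrix:
    """Draw observed probe read counts (Poisson/NB) from the pool's expected rates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    lam = pool.expected_counts
    if overdispersion > 0:
        size = 1.0 / overdispersion
        lam = rng.gamma(size, lam / size)
    counts = rng.poisson(lam).astype(np.float64)
    return ProbeCountMatrix(
        probes=list(pool.targets),
        samples=list(pool.sample_ids),
        counts=counts,
        total_reads=counts.sum(axis=0),
    )


def write_fixtures(pool: SimulatedPool, out_dir: str, seed: int = 0,
                   n_depth_samples: int = 2) -> dict[str, str]:
    """Write the pool to standard text formats; returns a path manifest.

    Emits targets BED, synthetic FASTA, per-sample bedGraph depth tracks for
    the first ``n_depth_samples`` test samples, probe counts TSV, truth BED
    and a manifest TSV. Round-tripping through the package readers
    reproduces the in-memory arrays exactly.
    """
    from .regions import write_bed
    from .cnv import write_counts_tsv

    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    bed = os.path.join(out_dir, "targets.bed")
    write_bed(pool.targets, bed)
    manifest["targets_bed"] = bed

    fasta = os.path.join(out_dir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom, seq in pool.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    manifest["genome_fasta"] = fasta

    lengths = np.array([len(iv) for iv in pool.targets], dtype=float)
    for i, sid in enumerate(pool.sample_ids[:n_depth_samples]):
        rates = pool.expected_counts[:, pool.sample_ids.index(sid)] * READ_LENGTH / lengths
        rng = np.random.default_rng(np.random.SeedSequence([seed, 505, i]))
        parts = [rng.poisson(r, int(L)) for r, L in zip(rates, lengths)]
        prof = CoverageProfile(pool.targets, np.concatenate(parts))
        path = os.path.join(out_dir, f"depth_{sid}.bedgraph")
        write_bedgraph(prof, path)
        manifest[f"depth_{sid}"] = path

    counts = sample_counts(pool, seed)
    counts_path = os.path.join(out_dir, "probe_counts.tsv")
    write_counts_tsv(counts, counts_path)
    manifest["probe_counts"] = counts_path

    truth_path = os.path.join(out_dir, "truth.bed")
    with open(truth_path, "w") as fh:
        for t in pool.truth:
            iv_s = pool.targets.intervals[t.probe_start]
            iv_e = pool.targets.intervals[t.probe_end - 1]
            fh.write(
                f"{iv_s.chrom}\t{iv_s.start}\t{iv_e.end}\t{t.sample_id}\t{t.type}"
                f"\t{t.probe_start}\t{t.probe_end}\n"
            )
    manifest["truth_bed"] = truth_path

    man_path = os.path.join(out_dir, "manifest.tsv")
    with open(man_path, "w") as fh:
        fh.write("key\tpath\n")
        for k, v in manifest.items():
            fh.write(f"{k}\t{os.path.basename(v)}\n")
    manifest["manifest"] = man_path
    return manifest


def write_bedgraph(p: CoverageProfile, path: str) -> None:
    """Run-length encode a profile's depth as 4-column bedGraph."""
    with open(path, "w") as fh:
        for iv, d in p.target_slices():
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(d)]])
            for s, e in zip(starts, ends):
                fh.write(f"{iv.chrom}\t{iv.start + s}\t{iv.start + e}\t{int(d[s])}\n")
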