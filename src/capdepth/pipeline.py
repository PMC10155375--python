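"""End-to-end kit-comparison runs.

``run`` composes the other modules in the order a kit evaluation proceeds:
simulate (or load) targets and depth per kit, compute completeness and
evenness per sample, stratify low-coverage regions by GC, trace the
downsampling ladder, score panel coverage, and call CNVs at two coverage
levels with cross-level concordance and truth evaluation. Every table is
written as TSV with the config snapshot embedded as a header comment so a
run is re-executable bit-identically from its own outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coverage as cov
from . import cnv as cnvmod
from . import simulate as sim
from .downsample import DownsampleSpec, sensitivity_curve, sub_seed
from .regions import PanelDefinition, TranscriptModel
from .sensitivity import SimVariantTruth

__all__ = ["RunConfig", "ComparisonReport", "run", "report_cnv_concordance"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every fixed constant of a comparison run, in one place."""

    thresholds: tuple[int, int] = (20, 10)
    ladder: tuple[float, ...] = (100, 70, 60, 50, 40, 30, 20)
    af_min: float = 0.001
    qual_cut: float = 500.0
    cnv_threshold: float = 1.7
    k: int = 3
    min_probes: int = 3
    panel_q: float = 0.95
    pad: int = 200
    seed: int = 0
    # simulation-mode knobs
    kits: tuple[str, ...] = ("twist_like", "agilent_v7_like")
    n_targets: int = 300
    n_samples_per_kit: int = 2
    mean_coverage: float = 100.0
    cnv_levels: tuple[float, float] = (100.0, 70.0)
    cnv_n_reference: int = 30
    cnv_n_test: int = 6
    cnv_n_probes: int = 300
    n_variants: int = 200
    panel_size: int = 50

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(self.ladder[i] <= self.ladder[i + 1] for i in range(len(self.ladder) - 1)):
            raise ValueError("ladder must be strictly decreasing")

    def snapshot(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class ComparisonReport:
    kit_summary: pd.DataFrame
    gc_table: pd.DataFrame
    curves: pd.DataFrame
    panel_table: pd.DataFrame
    cnv_calls: pd.DataFrame
    cnv_concordance: pd.DataFrame
    cnv_truth: pd.DataFrame
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tables = {
            "kit_summary": self.kit_summary,
            "gc_stratification": self.gc_table,
            "sensitivity_curves": self.curves,
            "panel_coverage": self.panel_table,
            "cnv_calls": self.cnv_calls,
            "cnv_concordance": self.cnv_concordance,
            "cnv_truth_evaluation": self.cnv_truth,
        }

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        header = f"# capdepth run config: {self.config.snapshot()}\n"
        paths = {}
        for name, df in self.tables.items():
            path = os.path.join(out_dir, f"{name}.tsv")
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            paths[name] = path
        man = os.path.join(out_dir, "manifest.tsv")
        with open(man, "w") as fh:
            fh.write("table\tfile\trows\n")
            for name in self.tables:
                fh.write(f"{name}\t{name}.tsv\t{len(self.tables[name])}\n")
        paths["manifest"] = man
        return paths


def report_cnv_concordance(
    calls_a: Sequence[cnvmod.CNVCall], calls_b: Sequence[cnvmod.CNVCall]
) -> tuple[int, int, int]:
    """Three-way partition (both, only_a, only_b) of calls across two levels.

    Calls match when they share sample and type and their probe runs overlap
    by >= 50% of the smaller run. Each call matches at most once; ties go to
    the largest overlap, then the leftmost candidate.
    """
    used_b: set[int] = set()
    both = 0
    for ca in calls_a:
        best: tuple[int, int, int] | None = None  # (-overlap, start, idx)
        for j, cb in enumerate(calls_b):
            if j in used_b or cb.sample_id != ca.sample_id or cb.type != ca.type:
                continue
            ov = min(ca.probe_end, cb.probe_end) - max(ca.probe_start, cb.probe_start)
            if ov <= 0:
                continue
            if ov >= 0.5 * min(ca.n_probes, cb.n_probes):
                cand = (-ov, cb.probe_start, j)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            used_b.add(best[2])
            both += 1
    return both, len(calls_a) - both, len(calls_b) - both


def _targets_as_panel(pool_targets, n: int) -> PanelDefinition:
    """Treat the first n simulated targets as single-exon coding transcripts."""
    txs = []
    for i, iv in enumerate(list(pool_targets)[:n]):
        txs.append(
            TranscriptModel(
                transcript_id=f"SIMTX{i:04d}",
                gene=f"SIMG{i:04d}",
                chrom=iv.chrom,
                strand="+",
                exon_starts=[iv.start],
                exon_ends=[iv.end],
                cds_start=iv.start,
                cds_end=iv.end,
            )
        )
    return PanelDefinition(transcripts=txs, name="sim_panel")


def run(config: RunConfig) -> ComparisonReport:
    """Simulation-mode comparison across kits; deterministic given the seed."""
    t20, t10 = config.thresholds
    kit_rows, gc_rows, curve_rows, panel_rows = [], [], [], []

    for ki, kit_name in enumerate(config.kits):
        kit = sim.KIT_PRESETS[kit_name]
        logger.info("stage coverage: kit=%s", kit_name)
        cfg = sim.SimConfig(
            n_targets=config.n_targets,
            mean_coverage=config.mean_coverage,
            n_samples=config.n_samples_per_kit,
            n_reference=1,
            seed=sub_seed(config.seed, 10, ki),
        )
        targets, gc, seqs = sim.simulate_targets(cfg)
        effects = sim.draw_probe_effects(kit, cfg.n_targets, cfg.seed)
        rng = np.random.default_rng(sub_seed(config.seed, 11, ki))
        var_pos = rng.choice(
            sum(len(iv) for iv in targets), size=config.n_variants, replace=False
        )
        variants = [SimVariantTruth(pos=int(p), vaf=0.5) for p in sorted(var_pos)]
        for si in range(config.n_samples_per_kit):
            prof = sim.simulate_depth(
                targets, gc, kit, config.mean_coverage,
                sample_seed=sub_seed(config.seed, 12, ki, si),
                probe_effects=effects,
            )
            kit_rows.append({
                "kit": kit_name,
                "sample": f"{kit_name}_s{si}",
                "mean_coverage": prof.mean_coverage,
                f"completeness_{t20}x": cov.completeness(prof, t20).fraction_covered,
                f"completeness_{t10}x": cov.completeness(prof, t10).fraction_covered,
                "evenness": cov.evenness(prof),
            })
            if si == 0:
                strat = cov.gc_stratification(prof, seqs, t20)
                gc_rows.append({
                    "kit": kit_name,
                    "n_insufficient": len(strat.insufficient_gc),
                    "n_sufficient": len(strat.sufficient_gc),
                    "median_gc_insufficient": strat.median_insufficient,
                    "median_gc_sufficient": strat.median_sufficient,
                    "u_statistic": strat.u_statistic,
                    "p_value": strat.p_value,
                    "applicable": strat.applicable,
                })
                spec = DownsampleSpec(
                    levels=[l for l in config.ladder if l <= prof.mean_coverage],
                    seed=sub_seed(config.seed, 13, ki),
                )
                curve = sensitivity_curve(prof, spec, threshold=t20, variants=variants)
                for lv, c20, c10, nv in curve.rows():
                    curve_rows.append({
                        "kit": kit_name, "level": lv,
                        f"completeness_{t20}x": c20,
                        f"completeness_{t10}x": c10,
                        "n_variants": nv,
                    })
                panel = _targets_as_panel(targets, config.panel_size)
                pres = cov.panel_coverage(prof, panel, t20, q=config.panel_q)
                panel_rows.append({
                    "kit": kit_name,
                    "threshold": t20,
                    "q": config.panel_q,
                    "fraction_fully_covered": pres.fraction_fully_covered,
                    "fraction_q_covered": pres.fraction_q_covered,
                })

    # CNV stage: one pool, called at both coverage levels
    logger.info("stage cnv: %d probes, %d ref", config.cnv_n_probes, config.cnv_n_reference)
    cnv_cfg = sim.SimConfig(
        n_targets=config.cnv_n_probes,
        mean_coverage=config.cnv_levels[0],
        n_samples=config.cnv_n_test,
        n_reference=config.cnv_n_reference,
        seed=sub_seed(config.seed, 20),
    )
    pool = sim.simulate_pool(cnv_cfg, sim.KIT_PRESETS[config.kits[0]])
    spikes = []
    span = 12
    for i in range(config.cnv_n_test):
        start = 20 + i * 40
        if start + span <= config.cnv_n_probes:
            spikes.append(sim.CnvSpike(
                sample_id=f"test_{i:03d}", probe_start=start,
                probe_end=start + span, ratio=0.5 if i % 2 == 0 else 1.5,
            ))
    pool = sim.spike_cnvs(pool, spikes)

    call_rows, truth_rows = [], []
    calls_by_level: dict[float, list[cnvmod.CNVCall]] = {}
    for li, level in enumerate(config.cnv_levels):
        scaled = sim.SimulatedPool(
            targets=pool.targets, gc=pool.gc, sequences=pool.sequences,
            probe_effects=pool.probe_effects, sample_ids=pool.sample_ids,
            reference_ids=pool.reference_ids,
            expected_counts=pool.expected_counts * (level / config.cnv_levels[0]),
            truth=pool.truth, config=pool.config,
        )
        counts = sim.sample_counts(scaled, seed=sub_seed(config.seed, 21, li))
        z = cnvmod.zrpkm(counts, pool.reference_ids)
        den, scree = cnvmod.svd_denoise(z.values, config.k)
        test_ids = [s for s in pool.sample_ids if s not in set(pool.reference_ids)]
        calls = cnvmod.call_cnvs(
            den, z.probes, z.samples, threshold=config.cnv_threshold,
            min_probes=config.min_probes, call_samples=test_ids,
        )
        calls_by_level[level] = calls
        for c in calls:
            call_rows.append({
                "level": level, "sample": c.sample_id, "chrom": c.chrom,
                "start": c.start, "end": c.end, "type": c.type,
                "extremal_score": c.extremal_score, "n_probes": c.n_probes,
            })
        kept = set(range(len(pool.targets))) - set(z.excluded_probes)
        index_map = {orig: new for new, orig in enumerate(sorted(kept))}
        truth_kept = []
        for t in pool.truth:
            idx = [index_map[i] for i in range(t.probe_start, t.probe_end) if i in index_map]
            if idx:
                truth_kept.append(cnvmod.TruthCNV(t.sample_id, min(idx), max(idx) + 1, t.type))
        ev = cnvmod.evaluate_truth(calls, den, z.probes, z.samples, truth_kept,
                                   threshold=config.cnv_threshold)
        for t, e in ev.items():
            truth_rows.append({
                "level": level, "sample": t.sample_id, "type": t.type,
                "probe_start": t.probe_start, "probe_end": t.probe_end,
                "status": e.status, "segments_called": e.segments_called,
                "segments_total": e.segments_total,
            })

    both, only_a, only_b = report_cnv_concordance(
        calls_by_level[config.cnv_levels[0]], calls_by_level[config.cnv_levels[1]]
    )
    conc = pd.DataFrame([{
        "level_a": config.cnv_levels[0], "level_b": config.cnv_levels[1],
        "both": both, "only_a": only_a, "only_b": only_b,
        "n_a": len(calls_by_level[config.cnv_levels[0]]),
        "n_b": len(calls_by_level[config.cnv_levels[1]]),
    }])

    return ComparisonReport(
        kit_summary=pd.DataFrame(kit_rows),
        gc_table=pd.DataFrame(gc_rows),
        curves=pd.DataFrame(curve_rows),
        panel_table=pd.DataFrame(panel_rows),
        cnv_calls=pd.DataFrame(call_rows),
        cnv_concordance=conc,
        cnv_truth=pd.DataFrame(truth_rows),
        config=config,
    )
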