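"""Depth downsampling and coverage/sensitivity ladders.

Thinning emulates sequencing a library to a lower mean depth: each base's
depth is replaced by a binomial draw with success probability
``target_mean / source_mean``. This preserves expected completeness and is
exactly analysable, unlike read-level subsampling which it stands in for.
``read_run`` mode thins whole 150-bp blocks of depth units together to
approximate the positional correlation that reads induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coverage import CoverageProfile, completeness

__all__ = ["DownsampleSpec", "SensitivityCurve", "thin_profile", "sensitivity_curve", "sub_seed"]

DEFAULT_LADDER = (100, 70, 60, 50, 40, 30, 20)

READ_BLOCK_BP = 150  # block size for read_run mode, one short read


@dataclass
class DownsampleSpec:
    """A ladder of target mean depths plus the seeding/mode policy."""

    levels: Sequence[float] = DEFAULT_LADDER
    seed: int = 0
    mode: str = "per_base"

    def __post_init__(self) -> None:
        levels = list(self.levels)
        if not levels or any(l <= 0 for l in levels):
            raise ValueError("levels must be positive")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly decreasing")
        if self.mode not in ("per_base", "read_run"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.levels = levels

    def validate_against(self, p: CoverageProfile) -> None:
        if self.levels[0] > p.mean_coverage:
            raise ValueError(
                f"ladder top {self.levels[0]} exceeds source mean {p.mean_coverage:.2f}"
            )


@dataclass
class SensitivityCurve:
    """One row per downsampling level."""

    levels: list[float] = field(default_factory=list)
    completeness_20x: list[float] = field(default_factory=list)
    completeness_10x: list[float] = field(default_factory=list)
    n_variants_detected: list[Optional[int]] = field(default_factory=list)

    def rows(self):
        for row in zip(self.levels, self.completeness_20x, self.completeness_10x,
                       self.n_variants_detected):
            yield row


def sub_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed < 2**31 derived from (seed, *keys)."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


def thin_profile(
    p: CoverageProfile, target_mean: float, seed: int, mode: str = "per_base"
) -> CoverageProfile:
    """Binomially thin a profile to ``target_mean`` average depth.

    The target geometry is unchanged; only depths shrink. ``target_mean``
    equal to the source mean returns the profile unchanged (no sampling).
    """
    mu = p.mean_coverage
    if not 0 < target_mean <= mu:
        raise ValueError(
            f"target_mean must be in (0, source mean {mu:.3f}], got {target_mean}"
        )
    ratio = target_mean / mu
    if ratio == 1.0:
        return CoverageProfile(p.targets, p.depth.copy())
    rng = np.random.default_rng(seed)
    if mode == "per_base":
        new_depth = rng.binomial(p.depth, ratio)
        return CoverageProfile(p.targets, new_depth)
    if mode == "read_run":
        new_depth = np.empty_like(p.depth)
        for i in range(len(p.targets)):
            lo, hi = p.offsets[i], p.offsets[i + 1]
            d = p.depth[lo:hi]
            out = np.empty_like(d)
            for bs in range(0, len(d), READ_BLOCK_BP):
                block = d[bs : bs + READ_BLOCK_BP]
                m = int(block.max()) if len(block) else 0
                if m == 0:
                    out[bs : bs + READ_BLOCK_BP] = 0
                    continue
                # one Bernoulli per depth unit ("read layer"), shared by the block
                keep = rng.random(m) < ratio
                kept_cum = np.concatenate([[0], np.cumsum(keep)])
                out[bs : bs + READ_BLOCK_BP] = kept_cum[block]
            new_depth[lo:hi] = out
        return CoverageProfile(p.targets, new_depth)
    raise ValueError(f"unknown mode {mode!r}")


def sensitivity_curve(
    p: CoverageProfile,
    spec: DownsampleSpec,
    threshold: int = 20,
    variants=None,
    detect_kwargs: Optional[dict] = None,
) -> SensitivityCurve:
    """Completeness (and optional variant detection) across the downsampling ladder.

    Each level is thinned independently from the source profile with a
    deterministic per-level sub-seed, so levels are reproducible and mutually
    independent. ``variants`` is a list of simulated variant truths handed to
    :func:`capdepth.sensitivity.detect_variants`.
    """
    spec.validate_against(p)
    curve = SensitivityCurve()
    for level in spec.levels:
        thinned = thin_profile(p, level, sub_seed(spec.seed, round(level * 1000)), spec.mode)
        curve.levels.append(level)
        curve.completeness_20x.append(completeness(thinned, threshold).fraction_covered)
        curve.completeness_10x.append(completeness(thinned, 10).fraction_covered)
        if variants is not None:
            from .sensitivity import detect_variants

            kwargs = dict(min_alt=4, min_depth=8)
            if detect_kwargs:
                kwargs.update(detect_kwargs)
            detected = detect_variants(
                thinned, variants,
                seed=sub_seed(spec.seed, round(level * 1000), 1), **kwargs
            )
            curve.n_variants_detected.append(len(detected))
        else:
            curve.n_variants_detected.append(None)
    return curve
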