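# Methods

## Scope and coordinate conventions

All interval arithmetic is 0-based half-open (BED/genePred convention);
1-based inputs must be converted at the parser boundary. Merging follows
BEDTools semantics: book-ended intervals ((10,20),(20,30)) fuse by default,
with a flag to disable. Strand is preserved on transcript records for
fidelity but ignored by all interval algebra — coverage completeness is
strand-agnostic. Transcript tables are accepted in both UCSC dialects
(genePred and refFlat, auto-detected from the strand column position). For
panel construction, the "longest transcript" of a gene is the one with the
maximal summed coding-exon length, ties broken by lexicographically smallest
transcript id.

## Coverage statistics

**Completeness** at threshold T is the fraction of target bases with depth
≥ T; the overall fraction equals the base-weighted mean of per-target
fractions. Defaults are 20× (primary) and 10× (secondary), the conventional
adequacy thresholds in diagnostic exome QC.

**Evenness.** The primary definition is the closed form
`E = 1 − Σ max(0, cᵢ − μ)/Σ cᵢ`: the fraction of sequenced bases that need
no redistribution from above-mean to below-mean positions. It is computed
with exact integer arithmetic (`E = 1 − Σ max(0, n·cᵢ − S)/(n·S)` with
S = Σ cᵢ), which makes invariance under integer depth scaling *exact* rather
than approximate. The cumulative form `E = (1/⌊μ⌋) Σ_{k=1..⌊μ⌋} F(k)` is
implemented independently and serves as a test oracle; the two agree
exactly when μ is an integer and to within 1/μ otherwise (the cumulative
form truncates μ). E is undefined for all-zero depth (error), equals 1 iff
depth is constant, and lies in [0, 1].

**Insufficiently covered regions** are *maximal runs of consecutive bases
below threshold within a target*, not whole targets; runs never cross
target boundaries. This granularity choice degrades gracefully — a target
with one bad pocket contributes one small region, not its whole footprint —
but it also means very short runs are common, and a short run inside a
high-GC target is frequently 100% G/C. Region GC therefore skews more
extreme than a per-target statistic would; the *direction* of the contrast
is the meaningful output. GC is computed from the reference sequence of the
exact region, case-insensitively, with N/ambiguity codes excluded from the
denominator (standard nucleotide-content behaviour). The two strata are
compared with a two-sided Mann–Whitney rank-sum test: exact enumeration
when both groups are small (< 20 total) and tie-free, otherwise the normal
approximation with tie correction (scipy's implementation). If either
stratum is empty the result is marked not applicable rather than an error.

## Downsampling

Thinning replaces each base's depth with a Binomial(depth, r) draw,
r = target mean / source mean. This is a depth-level stand-in for read-level
subsampling: it preserves expected completeness exactly and composes
(thinning to 50× then 25× is distributionally identical to thinning to 25×),
at the cost of ignoring the positional correlation that reads induce. The
`read_run` mode bounds that approximation: within 150-bp blocks (one
short-read length) all depth units share Bernoulli keep decisions, giving
block-correlated thinning. Each ladder level is thinned independently from
the source profile with a sub-seed derived deterministically from
(seed, level), so levels are reproducible and mutually independent;
sequential thinning would give the same marginal law but correlated noise
across levels.

## Variant detection model

Calling engines are out of scope; the model keeps only the part of calling
that depth drives. At a site of depth d and variant allele fraction v, the
alternate count is Binomial(d, v); the variant is detected iff the count
≥ min_alt (default 4) and d ≥ min_depth (default 8), sequencing error
ignored. The defaults are ordinary short-read heuristics and are
config-exposed; the model's value is that its detection probability has the
closed form 1 − BinomCDF(min_alt−1; d, v), against which the implementation
is tested. Callset comparison filters both sets to population AF *strictly*
greater than af_min (default 0.001; AF-less records are dropped and
counted), then set-compares by (chrom, pos, ref, alt, sample). Including
the sample id in the key makes multi-sample comparisons aggregate
per sample. The quality-tail statistic is the fraction of quality-bearing
records with QUAL strictly below a cut (default 500).

## CNV calling (SVD-ZRPKM)

Probe counts are normalised to RPKM
(`count / ((probe_length/1000) · (library_total/10⁶))`), then z-scored per
probe against the *median* and sample standard deviation (ddof = 1) of a
reference pool of presumed-CNV-neutral samples (≥ 8 required; ~100 is the
intended regime). Probes whose reference median RPKM falls below 1.0 are
excluded (too little signal to normalise — the established default for this
caller family); a vanishing reference sd is floored at 1e−6 with a logged
warning. The probes × samples ZRPKM matrix is denoised by zeroing its top-k
singular values (full SVD, k default 3); the scree (all singular values) is
emitted so users can re-derive the inflection-point choice of k — no
automatic inflection detection is attempted, since the choice is
conventionally made by eye. Calls are maximal same-sign runs of genomically
consecutive, same-chromosome probes at |ZRPKM| ≥ threshold (default 1.7),
discarded below min_probes (default 3; single-probe calls are
noise-dominated).

Truth evaluation needs explicit rules to be reproducible: a truth CNV is
**called** when a single matching-type call covers ≥ 50% of its probes;
**segmented m/n** when matching calls exist but none covers half (n =
matching-sign threshold-passing sub-runs inside the span, m = calls);
**cannot_exceed_threshold** when no call survives but ≥ 20% of truth probes
carry matching-sign values of at least half the threshold; otherwise
**not_called**. Cross-level concordance matches calls by sample, type and
≥ 50% probe overlap of the smaller run (greedy, largest overlap first, then
leftmost), yielding a three-way partition (both / only-A / only-B) that
always sums to the union of matched clusters.

A known behaviour worth stating: a strong copy-number signal confined to
one sample can partially align with the removed singular components when
the matrix is small or the signal is large relative to the noise singular
values, attenuating the denoised scores. This is intrinsic to SVD-based
callers and is exactly what produces "segmented" and "cannot exceed
threshold" outcomes on real validated CNVs; the simulator reproduces it.

## The simulator

The generator emulates the structure the analyses assume, with these study
conditions as defaults: 1,000 targets with truncated-normal lengths
(mean 160 bp, sd 60, floor 50 — exon-like), clipped-normal GC (mean 0.46,
sd 0.10 — coding-exon-like), 100× mean coverage, 20 test samples, and a
100-sample reference pool for CNV work.

Capture efficiency is piecewise-quadratic in GC around a kit-specific
optimum, `eff(g) = max(0.02, 1 − pen·(g − g₀)²)` with independent low/high
side curvatures — one family covers both observed regimes (hybridisation
kits penalised at low GC; a modern rebalanced kit penalised at high GC).
Three presets encode those regimes (twist_like: g₀ 0.45, pen_low 0.8,
pen_high 12, probe σ 0.2; agilent_v7_like: g₀ 0.50, pens 8/1, σ 0.35;
agilent_v5_like: g₀ 0.52, pens 12/1, σ 0.55). Curvatures were chosen so
that, at 100×, a few percent of high-GC (respectively low-GC) targets fall
below 20× — the magnitude seen in kit comparisons — and the dispersion σ
ordering reproduces the observed evenness ordering across kit generations.

Per-probe efficiencies are lognormal (mean-one parameterisation) and
*shared across every sample of a pool*: capture bias is systematic, which
is precisely the premise that makes SVD denoising work, and the batch-effect
tests verify that consequence. Per-target rates are renormalised so the
expected profile mean equals the requested coverage exactly; per-base depth
is Poisson around the target rate (a negative-binomial overdispersion
parameter is exposed, default 0). Target sequences are constructed to match
each target's GC within one base, so sequence-derived GC agrees with the
generative GC. Probe read counts derive from depth via an implied 150-bp
read length (expected reads = rate × length / 150). CNV spike-ins multiply
expected rates before noise sampling (ratio 0.5 = heterozygous deletion,
1.5 = heterozygous duplication); overlapping spikes in one sample are
rejected.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: mappability and homology artifacts, read-level
error and duplication structure, alignment effects, inter-sample library
chemistry variation beyond the Poisson/NB noise, and real exome target
geometry. Results on simulated pools demonstrate correctness of the
statistics and the qualitative kit contrasts, not kit performance claims.

## Pipeline and reproducibility

The orchestrated run uses reduced problem sizes by default (300 targets,
2 samples/kit, a 30-reference CNV pool over 300 probes) — large enough for
every stage to exercise its logic, small enough to run in seconds; all
sizes are config fields. Every source of randomness descends from the run
seed through named SeedSequence-derived sub-seeds (< 2³¹), so identical
configs give byte-identical TSVs; each table embeds the JSON config
snapshot as a header comment. Warnings (excluded probes, AF-less variants)
are tallied, never silent.

## Known limitations

* Depth-level thinning understates the completeness variance that
  read-length correlation induces; `read_run` mode brackets the effect.
* The detection model ignores base-quality, mapping and error processes;
  it is a depth-response model only.
* Truth-evaluation and concordance rules (50% coverage, 20%/half-threshold)
  are this package's explicit definitions of otherwise informal vocabulary;
  alternative reasonable rules would shift borderline statuses.
* The rank-sum exact/asymptotic switch at 20 observations follows common
  practice; p-values near the switch are approximation-sensitive.
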