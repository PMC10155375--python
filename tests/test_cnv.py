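"""RPKM / ZRPKM transforms, SVD denoising and threshold calling."""

import numpy as np
import pytest

from capdepth import (
    GenomicInterval,
    ProbeCountMatrix,
    TruthCNV,
    call_cnvs,
    evaluate_truth,
    rpkm,
    svd_denoise,
    zrpkm,
)
from capdepth.cnv import read_counts_tsv, write_counts_tsv


def probes_of(lengths, chrom="c"):
    out, pos = [], 0
    for L in lengths:
        out.append(GenomicInterval(chrom, pos, pos + L))
        pos += L + 10
    return out


def matrix(counts, lengths=None, totals=None, prefix="s"):
    counts = np.asarray(counts, dtype=float)
    n_probes, n_samples = counts.shape
    lengths = lengths or [100] * n_probes
    totals = totals if totals is not None else counts.sum(axis=0)
    return ProbeCountMatrix(
        probes=probes_of(lengths),
        samples=[f"{prefix}{i}" for i in range(n_samples)],
        counts=counts,
        total_reads=np.asarray(totals, dtype=float),
    )


class TestRpkm:
    def test_hand_evaluated(self):
        m = matrix([[10]], lengths=[100], totals=[1_000_000])
        assert rpkm(m)[0, 0] == pytest.approx(100.0)

    def test_zero_counts_zero_rpkm(self):
        m = matrix([[0], [5]], totals=[1000])
        assert rpkm(m)[0, 0] == 0.0

    def test_doubling_totals_halves_column(self):
        c = np.array([[10.0], [20.0]])
        r1 = rpkm(matrix(c, totals=[1000]))
        r2 = rpkm(matrix(c, totals=[2000]))
        assert np.allclose(r1, 2 * r2)

    def test_zero_total_reads_names_sample(self):
        m = matrix([[1, 1]], totals=[100, 0])
        with pytest.raises(ValueError, match="s1"):
            rpkm(m)


class TestZrpkm:
    def _pool(self, rng, n_probes=50, n_ref=20, n_test=2, scale=50):
        counts = rng.poisson(scale, (n_probes, n_ref + n_test)).astype(float) + 1
        m = matrix(counts, totals=[1e6] * (n_ref + n_test))
        refs = m.samples[n_test:]
        return m, refs

    def test_reference_median_column_zero(self, rng):
        m, refs = self._pool(rng)
        z = zrpkm(m, refs)
        # a sample whose RPKM equals the per-probe reference median scores 0
        r = rpkm(m)
        ref_idx = [m.samples.index(s) for s in refs]
        med = np.median(r[:, ref_idx], axis=1)
        kept = [i for i in range(len(m.probes)) if i not in z.excluded_probes]
        manual = (r[kept][:, 0] - med[kept]) / z.reference_std
        assert np.allclose(z.values[:, 0], manual, atol=1e-12)

    def test_pool_median_is_zero(self, rng):
        m, refs = self._pool(rng)
        z = zrpkm(m, refs)
        ref_cols = [z.samples.index(s) for s in refs]
        assert np.allclose(np.median(z.values[:, ref_cols], axis=1), 0.0, atol=1e-12)

    def test_median_floor_excludes_probes(self, rng):
        m, refs = self._pool(rng)
        m.counts[3, :] = 0  # reference median RPKM 0 < floor
        z = zrpkm(m, refs)
        assert 3 in z.excluded_probes
        assert z.values.shape[0] == len(m.probes) - len(z.excluded_probes)

    def test_requires_eight_references(self, rng):
        m, refs = self._pool(rng)
        with pytest.raises(ValueError):
            zrpkm(m, refs[:5])

    def test_against_per_row_recomputation(self, rng):
        counts = rng.poisson(80, (50, 30)).astype(float) + 1
        m = matrix(counts, totals=counts.sum(axis=0))
        refs = m.samples[:20]
        z = zrpkm(m, refs)
        r = rpkm(m)
        ref_idx = [m.samples.index(s) for s in refs]
        for row, orig in enumerate(i for i in range(50) if i not in z.excluded_probes):
            med = np.median(r[orig, ref_idx])
            std = np.std(r[orig, ref_idx], ddof=1)
            assert np.allclose(z.values[row], (r[orig] - med) / max(std, 1e-6), atol=1e-12)


class TestSvdDenoise:
    def test_k_zero_identity(self, rng):
        x = rng.normal(size=(30, 10))
        d, scree = svd_denoise(x, 0)
        assert np.allclose(d, x, atol=1e-10)
        assert scree.k_removed == 0

    def test_rank_one_annihilated(self, rng):
        x = np.outer(rng.normal(size=40), rng.normal(size=8))
        d, _ = svd_denoise(x, 1)
        assert np.max(np.abs(d)) < 1e-10

    def test_orthogonal_to_removed_components(self, rng):
        x = rng.normal(size=(40, 20))
        d, _ = svd_denoise(x, 3)
        u, s, vt = np.linalg.svd(x, full_matrices=False)  # independent decomposition
        assert np.max(np.abs(u[:, :3].T @ d)) < 1e-8

    def test_scree_sorted_nonincreasing(self, rng):
        _, scree = svd_denoise(rng.normal(size=(25, 12)), 2)
        sv = scree.singular_values
        assert np.all(sv[:-1] >= sv[1:]) and np.all(sv >= 0)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            svd_denoise(rng.normal(size=(10, 5)), 5)


class TestCallCnvs:
    def _call(self, values, **kw):
        values = np.asarray(values, dtype=float)
        probes = probes_of([100] * values.shape[0])
        kw.setdefault("threshold", 1.7)
        kw.setdefault("min_probes", 3)
        return call_cnvs(values, probes, ["s0"], **kw)

    def test_subthreshold_silent(self):
        assert self._call([[0.5], [-1.0], [1.2]]) == []

    def test_run_scan_with_extremal_score(self):
        calls = self._call([[0], [-2], [-2.5], [-1.9], [0]])
        assert len(calls) == 1
        c = calls[0]
        assert (c.type, c.n_probes, c.probe_start, c.probe_end) == ("deletion", 3, 1, 4)
        assert c.extremal_score == pytest.approx(-2.5)

    def test_sign_change_breaks_runs(self):
        calls = self._call([[2.0], [-2.0], [2.0], [2.0]], min_probes=1)
        assert [c.type for c in calls] == ["duplication", "deletion", "duplication"]
        assert calls[2].n_probes == 2

    def test_min_probes_filter(self):
        assert self._call([[-2], [-2], [0]], min_probes=3) == []
        assert len(self._call([[-2], [-2], [0]], min_probes=2)) == 1

    def test_runs_do_not_cross_chromosomes(self):
        probes = [GenomicInterval("c1", 0, 100), GenomicInterval("c1", 200, 300),
                  GenomicInterval("c2", 0, 100)]
        values = np.array([[-2.0], [-2.0], [-2.0]])
        calls = call_cnvs(values, probes, ["s0"], threshold=1.7, min_probes=1)
        assert [c.chrom for c in calls] == ["c1", "c2"]


class TestEvaluateTruth:
    def _setup(self, col, calls_kw=None):
        values = np.asarray(col, dtype=float)[:, None]
        probes = probes_of([100] * len(col))
        calls = call_cnvs(values, probes, ["s0"], threshold=1.7,
                          min_probes=(calls_kw or {}).get("min_probes", 3))
        return values, probes, calls

    def test_exact_match_called(self):
        col = [0, 0, -2, -2.2, -2.1, 0, 0]
        values, probes, calls = self._setup(col)
        truth = [TruthCNV("s0", 2, 5, "deletion")]
        ev = evaluate_truth(calls, values, probes, ["s0"], truth)
        assert ev[truth[0]].status == "called"

    def test_hovering_below_threshold(self):
        col = [0, -1.0, -1.0, -1.0, -1.0, 0]
        values, probes, calls = self._setup(col)
        truth = [TruthCNV("s0", 1, 5, "deletion")]
        ev = evaluate_truth(calls, values, probes, ["s0"], truth)
        assert ev[truth[0]].status == "cannot_exceed_threshold"

    def test_two_disjoint_runs_segmented(self):
        col = [-2, -2, -2, 0, 0, 0, 0, 0, -2, -2, -2, 0]
        values, probes, calls = self._setup(col)
        truth = [TruthCNV("s0", 0, 11, "deletion")]
        ev = evaluate_truth(calls, values, probes, ["s0"], truth)
        e = ev[truth[0]]
        assert e.status == "segmented"
        assert (e.segments_called, e.segments_total) == (2, 2)

    def test_flat_noise_not_called(self):
        col = [0.1, -0.2, 0.0, 0.1, -0.1]
        values, probes, calls = self._setup(col)
        truth = [TruthCNV("s0", 0, 5, "duplication")]
        ev = evaluate_truth(calls, values, probes, ["s0"], truth)
        assert ev[truth[0]].status == "not_called"

    def test_empty_truth_span_errors(self):
        values, probes, calls = self._setup([0, 0, 0])
        with pytest.raises(ValueError):
            evaluate_truth(calls, values, probes, ["s0"], [TruthCNV("s0", 2, 2, "deletion")])


class TestCountsIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.poisson(50, (20, 5)).astype(float)
        m = matrix(counts, totals=[1e5] * 5)
        from capdepth import write_bed

        bed = tmp_path / "probes.bed"
        tsv = tmp_path / "counts.tsv"
        from capdepth import IntervalSet

        write_bed(IntervalSet(m.probes, merged=True), str(bed))
        write_counts_tsv(m, str(tsv))
        m2 = read_counts_tsv(str(tsv), str(bed))
        assert m2.samples == m.samples
        assert np.array_equal(m2.counts, m.counts)
        assert np.array_equal(m2.total_reads, m.total_reads)
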