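"""Coding-region extraction and kit-target gap analysis.

Parses a tiny transcript table, extracts merged coding exons, extends a
capture kit's targets by ±200 bp, and reports how much coding sequence the
kit fails to target — the "missing kb" bookkeeping of a kit comparison.
"""

import capdepth as cd

GENEPRED = """\
NM_0001\tchr1\t+\t100\t1000\t150\t950\t3\t100,400,800,\t300,600,1000,
NM_0002\tchr1\t-\t2000\t2600\t2050\t2550\t2\t2000,2400,\t2200,2600,
NR_0003\tchr1\t+\t5000\t5400\t5200\t5200\t1\t5000,\t5400,
"""

transcripts = cd.parse_genepred(GENEPRED)
coding = [t for t in transcripts if t.is_coding]
print(f"parsed {len(transcripts)} transcripts, {len(coding)} coding")

exons = cd.merge(cd.IntervalSet(
    [iv for t in coding for iv in cd.coding_exons(t)]
))
print(f"merged coding exons: {[(iv.start, iv.end) for iv in exons]}")
print(f"coding bases: {cd.total_bp(exons)}")

# a kit that targets most but not all of the coding sequence
kit = cd.IntervalSet([cd.GenomicInterval("chr1", 140, 610),
                      cd.GenomicInterval("chr1", 2100, 2500)])
kit_ext = cd.extend(kit, 200, {"chr1": 10_000})
gap = cd.subtract(exons, kit_ext)
print(f"coding bases missed by the extended kit: {cd.total_bp(gap)} "
      f"in {len(gap)} interval(s): {[(iv.start, iv.end) for iv in gap]}")
# The missed span is the third exon's CDS portion (800-950): the kit's
# extended targets stop at 810, leaving 140 coding bases untargeted.
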