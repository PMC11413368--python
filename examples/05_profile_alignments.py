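"""Profile aligned reads into tract-length histograms.

Builds a tiny synthetic BAM in a temporary directory — 20 reads spanning a
(A)27 repeat, a few carrying 2-base deletions, plus reads that do not reach
the right flank — and extracts the per-locus length histogram using the
flank-anchored spanning-read rule.
"""

import tempfile
from pathlib import Path

import pysam

from msikit import MicrosatelliteLocus, profile_sample

locus = MicrosatelliteLocus(
    locus_id="BAT27", chrom="chr1", start=1000, end=1027, unit="A",
    ref_len=27, left_flank="GGATC", right_flank="CTTGA",
)

header = {"HD": {"VN": "1.6", "SO": "coordinate"},
          "SQ": [{"SN": "chr1", "LN": 10_000}]}
with tempfile.TemporaryDirectory() as tmp:
    bam_path = Path(tmp) / "sample.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        reads = (
            [("GGATC" + "A" * 27 + "CTTGA", 15)]  # germline tract
            + [("GGATC" + "A" * 25 + "CTTGA", 5)]  # 2-base somatic deletion
            + [("GGATC" + "A" * 30, 4)]  # no right anchor: not spanning
        )
        i = 0
        for seq, n in reads:
            for _ in range(n):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"; i += 1
                a.query_sequence = seq
                a.reference_id = 0
                a.reference_start = 995
                a.mapping_quality = 60
                a.cigar = [(0, len(seq))]
                bam.write(a)
    pysam.index(str(bam_path))

    profile = profile_sample(bam_path, [locus], sample_id="demo")

hist = profile.histograms["BAT27"]
print(f"spanning depth: {hist.depth} of 24 reads overlap with both anchors")
print(f"tract-length histogram: {dict(sorted(hist.counts.items()))}")
# Expected: {25: 5, 27: 15} — the four anchor-less reads contribute nothing,
# so the histogram records only reads that fully traverse the repeat.
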