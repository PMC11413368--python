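"""Per-locus repeat tract-length histograms from aligned reads.

A read is *spanning* when it contains the locus' left flank anchor followed,
after any number of tract bases, by the right flank anchor; the tract length
is the number of bases strictly between the two anchors.  Anchors are located
by exact substring match (leftmost left-flank hit, first right-flank hit after
it) on the read as given and on its reverse complement — CIGAR-based
extraction is deliberately avoided because aligner gap placement inside
homopolymers is unreliable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .loci import MicrosatelliteLocus

DEFAULT_MAPQ_MIN = 1

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class LengthHistogram:
    """Spanning-read counts per observed tract length for one locus/sample."""

    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if length < 0 or count < 0:
                raise ValueError(
                    f"{self.locus_id}: negative length or count ({length}: {count})"
                )

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def add(self, length: int, n: int = 1) -> None:
        self.counts[length] = self.counts.get(length, 0) + n


@dataclass
class SampleProfile:
    """One histogram per panel locus for a single sample."""

    sample_id: str
    histograms: dict[str, LengthHistogram]
    known_status: str = "UNKNOWN"

    def depth(self, locus_id: str) -> int:
        return self.histograms[locus_id].depth


def extract_tract_length(read_sequence: str, locus: MicrosatelliteLocus) -> int | None:
    """Tract length (bases between flank anchors) or None if not spanning.

    The read is searched as given and reverse-complemented; the first
    orientation with both anchors in order wins (a read can only derive from
    one strand of the locus, so the two cannot disagree on genuine data).
    """
    for seq in (read_sequence, reverse_complement(read_sequence)):
        left = seq.find(locus.left_flank)
        if left < 0:
            continue
        tract_start = left + len(locus.left_flank)
        right = seq.find(locus.right_flank, tract_start)
        if right < 0:
            continue
        return right - tract_start
    return None


def profile_sample(
    alignment_path: str | Path,
    loci: Sequence[MicrosatelliteLocus],
    sample_id: str,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    known_status: str = "UNKNOWN",
) -> SampleProfile:
    """Profile an indexed SAM/BAM/CRAM into per-locus length histograms.

    Only primary, mapped alignments with MAPQ >= ``mapq_min`` whose alignment
    overlaps the locus window are inspected; each contributes at most one
    count, at its extracted tract length.  Mates are treated independently
    (PCR duplicates are assumed already collapsed upstream).
    """
    import pysam

    hists = {loc.locus_id: LengthHistogram(loc.locus_id) for loc in loci}
    with pysam.AlignmentFile(str(alignment_path)) as bam:
        if not bam.has_index():
            raise OSError(f"{alignment_path}: alignment file has no index")
        for loc in loci:
            window_start = max(loc.start - loc.flank_k, 0)
            window_end = loc.end + loc.flank_k
            for read in bam.fetch(loc.chrom, window_start, window_end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < mapq_min
                    or read.query_sequence is None
                ):
                    continue
                tract = extract_tract_length(read.query_sequence.upper(), loc)
                if tract is not None:
                    hists[loc.locus_id].add(tract)
    return SampleProfile(sample_id=sample_id, histograms=hists, known_status=known_status)


def derive_seed(global_seed: int, *tokens: str) -> int:
    """Stable per-(sample, locus) stream seed, independent of processing order."""
    h = zlib.crc32("\x1f".join(tokens).encode())
    return (int(global_seed) * 2654435761 + h) % (2**31 - 1)


def subsample_histogram(
    hist: LengthHistogram,
    max_depth: int,
    seed: int,
    sample_id: str = "",
) -> LengthHistogram:
    """Draw at most ``max_depth`` reads without replacement from a histogram.

    Histograms at or below the cap are returned unchanged (same object).  The
    draw is multivariate hypergeometric, seeded from (seed, sample_id,
    locus_id) so results do not depend on processing order.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if hist.depth <= max_depth:
        return hist
    lengths = sorted(hist.counts)
    colors = np.array([hist.counts[l] for l in lengths], dtype=np.int64)
    rng = np.random.default_rng(derive_seed(seed, sample_id, hist.locus_id))
    drawn = rng.multivariate_hypergeometric(colors, max_depth)
    return LengthHistogram(
        hist.locus_id,
        {l: int(n) for l, n in zip(lengths, drawn) if n > 0},
    )


def subsample_profile(
    profile: SampleProfile, max_depth: int, seed: int
) -> SampleProfile:
    """Apply subsample_histogram to every locus of a sample."""
    return SampleProfile(
        sample_id=profile.sample_id,
        known_status=profile.known_status,
        histograms={
            lid: subsample_histogram(h, max_depth, seed, profile.sample_id)
            for lid, h in profile.histograms.items()
        },
    )


def write_histograms(profile: SampleProfile, path: str | Path) -> None:
    """Write one sample's histograms as TSV (locus_id, length, count)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tlength\tcount\n")
        for lid in sorted(profile.histograms):
            hist = profile.histograms[lid]
            for length in sorted(hist.counts):
                fh.write(f"{lid}\t{length}\t{hist.counts[length]}\n")


def read_histograms(
    path: str | Path,
    locus_ids: Iterable[str],
    sample_id: str | None = None,
    known_status: str = "UNKNOWN",
) -> SampleProfile:
    """Read a histogram TSV back into a SampleProfile.

    ``locus_ids`` supplies the panel, so loci absent from the file come back
    as depth-0 histograms.
    """
    locus_ids = list(locus_ids)
    hists = {lid: LengthHistogram(lid) for lid in locus_ids}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["locus_id", "length", "count"]:
            raise ValueError(f"{path}: unexpected histogram header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            lid, length_s, count_s = line.rstrip("\n").split("\t")
            if lid not in hists:
                raise ValueError(f"{path}:{lineno}: locus {lid!r} not in panel")
            hists[lid].add(int(length_s), int(count_s))
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    return SampleProfile(sample_id=sample_id, histograms=hists, known_status=known_status)
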