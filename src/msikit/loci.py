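"""Microsatellite locus definitions, sample sheets and tabular report writers.

Locus files are BED6+2: ``chrom start end locus_id unit ref_len`` with optional
``left_flank right_flank`` columns.  Coordinates are 0-based half-open (BED
convention) both on disk and in memory.  Flanks are the reference anchor
sequences immediately outside the repeat tract; they are either supplied in
columns 7-8 or extracted from a reference FASTA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .caller import SampleCall

DEFAULT_FLANK_K = 5
TRACT_PURITY_MIN = 0.8

_STATUS_ALIASES = {
    "MSI": "MSI",
    "DMMR": "MSI",
    "MSS": "MSS",
    "PMMR": "MSS",
    "UNKNOWN": "UNKNOWN",
}


class LocusFileError(ValueError):
    """Malformed or inconsistent locus definition file."""


class SampleSheetError(ValueError):
    """Malformed sample sheet."""


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One panel repeat region.

    ``start``/``end`` delimit the repeat tract (0-based half-open); ``unit`` is
    the repeat unit; ``left_flank``/``right_flank`` are the anchor sequences of
    equal length immediately outside the tract, used to recognise spanning
    reads.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    ref_len: int
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise LocusFileError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.ref_len != self.end - self.start:
            raise LocusFileError(
                f"locus {self.locus_id!r}: ref_len {self.ref_len} != end - start "
                f"({self.end - self.start})"
            )
        if not self.unit or any(b not in "ACGT" for b in self.unit):
            raise LocusFileError(f"locus {self.locus_id!r}: invalid repeat unit {self.unit!r}")
        if len(self.left_flank) != len(self.right_flank) or len(self.left_flank) < 3:
            raise LocusFileError(
                f"locus {self.locus_id!r}: flanks must have equal length >= 3"
            )

    @property
    def flank_k(self) -> int:
        return len(self.left_flank)


@dataclass(frozen=True)
class SampleSheetRow:
    """One cohort sample: identifier, known dMMR/MSI label and data path."""

    sample_id: str
    known_status: str  # MSI | MSS | UNKNOWN
    source_path: str


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice a sequence store (pyfaidx.Fasta or a plain mapping of strings)."""
    seq = reference[chrom][start:end]
    if hasattr(seq, "seq"):
        seq = seq.seq
    return str(seq).upper()


def tract_purity(tract: str, unit: str) -> float:
    """Fraction of tract bases matching a tiling of ``unit``, best over phases."""
    if not tract:
        return 0.0
    best = 0
    for phase in range(len(unit)):
        hits = sum(
            1 for i, base in enumerate(tract) if base == unit[(i + phase) % len(unit)]
        )
        best = max(best, hits)
    return best / len(tract)


def read_locus_bed(
    path: str | Path,
    reference=None,
    flank_k: int = DEFAULT_FLANK_K,
) -> list[MicrosatelliteLocus]:
    """Read a panel definition (BED6+2 TSV) into validated locus records.

    With ``reference`` the flanks are extracted from the genome and the tract
    is required to be >= 80% repeat-unit content; without it, flank columns 7-8
    must be present in the file.
    """
    loci: list[MicrosatelliteLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise LocusFileError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, locus_id, unit, ref_len_s = fields[:6]
            try:
                start, end, ref_len = int(start_s), int(end_s), int(ref_len_s)
            except ValueError as exc:
                raise LocusFileError(f"{path}:{lineno}: non-integer coordinate") from exc
            if locus_id in seen:
                raise LocusFileError(f"{path}:{lineno}: duplicate locus_id {locus_id!r}")
            seen.add(locus_id)
            unit = unit.upper()
            if reference is not None:
                left = _fetch(reference, chrom, max(start - flank_k, 0), start)
                right = _fetch(reference, chrom, end, end + flank_k)
                tract = _fetch(reference, chrom, start, end)
                if tract_purity(tract, unit) < TRACT_PURITY_MIN:
                    raise LocusFileError(
                        f"locus {locus_id!r}: tract is < {TRACT_PURITY_MIN:.0%} "
                        f"{unit!r}-repeat content in the reference"
                    )
            elif len(fields) >= 8:
                left, right = fields[6].upper(), fields[7].upper()
            else:
                raise LocusFileError(
                    f"{path}:{lineno}: no reference given and flank columns 7-8 missing"
                )
            loci.append(
                MicrosatelliteLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    unit=unit,
                    ref_len=ref_len,
                    left_flank=left,
                    right_flank=right,
                )
            )
    return loci


def write_locus_bed(loci: Sequence[MicrosatelliteLocus], path: str | Path) -> None:
    """Write loci as BED6+2 (flanks in columns 7-8); round-trips read_locus_bed."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t{loc.unit}\t"
                f"{loc.ref_len}\t{loc.left_flank}\t{loc.right_flank}\n"
            )


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """Read the cohort sample sheet (TSV: sample_id, known_status, source_path).

    Status tokens are case-insensitive; pathology aliases dMMR -> MSI and
    pMMR -> MSS are accepted.
    """
    rows: list[SampleSheetRow] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "known_status", "source_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SampleSheetError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for idx, rec in enumerate(reader, start=2):
            token = (rec["known_status"] or "").strip().upper()
            if token not in _STATUS_ALIASES:
                raise SampleSheetError(
                    f"{path}: row {idx}: unknown status token {rec['known_status']!r}"
                )
            sid = rec["sample_id"].strip()
            if sid in seen:
                raise SampleSheetError(f"{path}: row {idx}: duplicate sample_id {sid!r}")
            seen.add(sid)
            rows.append(SampleSheetRow(sid, _STATUS_ALIASES[token], rec["source_path"].strip()))
    return rows


def write_sample_sheet(rows: Iterable[SampleSheetRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tknown_status\tsource_path\n")
        for r in rows:
            fh.write(f"{r.sample_id}\t{r.known_status}\t{r.source_path}\n")


def write_sample_report(
    calls: Sequence["SampleCall"],
    path: str | Path,
    known_status: Mapping[str, str] | None = None,
) -> None:
    """Write the per-sample call report (TSV).

    Columns: sample_id, score (4 d.p., empty for FAIL), n_evaluable, n_unstable,
    status, known_status, concordant.  ``concordant`` is empty when the known
    status is UNKNOWN or the call is FAIL.
    """
    if not calls:
        raise ValueError("refusing to write an empty report")
    known_status = known_status or {}
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tscore\tn_evaluable\tn_unstable\tstatus\tknown_status\tconcordant\n"
        )
        for call in calls:
            known = known_status.get(call.sample_id, call.known_status or "UNKNOWN")
            score = "" if call.status == "FAIL" else f"{call.score:.4f}"
            if call.status == "FAIL" or known == "UNKNOWN":
                concordant = ""
            else:
                concordant = "TRUE" if call.status == known else "FALSE"
            fh.write(
                f"{call.sample_id}\t{score}\t{call.n_evaluable}\t{call.n_unstable}\t"
                f"{call.status}\t{known}\t{concordant}\n"
            )
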