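"""The mSINGS-style instability caller.

For each locus the caller counts *alleles* — distinct tract lengths whose
read support is at least ``allele_fraction`` of the modal length's support.
A baseline (mean and sample SD of allele counts) is learned per locus from
known-MSS training samples; a test locus is *unstable* when its allele count
exceeds mean + ``sd_multiplier``·SD.  The sample score is the fraction of
evaluable loci (spanning depth >= ``depth_min``) called unstable; samples with
too few evaluable loci FAIL rather than being called.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .profiler import LengthHistogram, SampleProfile


@dataclass(frozen=True)
class CallerParams:
    """Tunable caller thresholds.

    allele_fraction : minimum count, as a fraction of the modal count, for a
        length to count as an allele (lineage default 0.05).
    sd_multiplier : baseline SDs above the mean allele count to flag a locus
        unstable (lineage default 2.0).
    depth_min : minimum spanning reads for a locus to be evaluable; 30 by
        default, with 10/15/20 as common lower-depth alternatives.
    min_evaluable : minimum evaluable loci for a sample to be called at all
        (~20% of a 29-locus panel); capped at the panel size when scoring
        restricted panels.
    msi_cutoff : fraction-unstable threshold used when no trained cutoff is
        supplied (the classical "enough regions have mutated", 20%).
    """

    allele_fraction: float = 0.05
    sd_multiplier: float = 2.0
    depth_min: int = 30
    min_evaluable: int = 6
    msi_cutoff: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.allele_fraction <= 1:
            raise ValueError("allele_fraction must be in (0, 1]")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.depth_min < 1 or self.min_evaluable < 1:
            raise ValueError("depth_min and min_evaluable must be >= 1")
        if not 0 < self.msi_cutoff < 1:
            raise ValueError("msi_cutoff must be in (0, 1)")

    def with_depth_min(self, depth_min: int) -> "CallerParams":
        return replace(self, depth_min=depth_min)


@dataclass(frozen=True)
class LocusBaseline:
    locus_id: str
    mean_alleles: float
    sd_alleles: float
    n_train: int

    def __post_init__(self) -> None:
        if self.n_train < 2:
            raise ValueError(f"{self.locus_id}: baseline needs >= 2 training samples")
        if self.sd_alleles < 0:
            raise ValueError(f"{self.locus_id}: negative SD")


@dataclass(frozen=True)
class Baseline:
    """Per-locus MSS null model plus the parameters it was built with."""

    loci: dict[str, LocusBaseline]
    params: CallerParams
    excluded: tuple[str, ...] = ()  # loci with < 2 evaluable training samples

    @property
    def locus_ids(self) -> list[str]:
        return sorted(self.loci)


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    evaluable: bool
    unstable: bool | None  # None when not evaluable
    allele_count: int | None


@dataclass(frozen=True)
class SampleCall:
    """A sample's fraction-unstable score and MSI/MSS/FAIL status."""

    sample_id: str
    n_evaluable: int
    n_unstable: int
    status: str  # MSI | MSS | FAIL
    known_status: str = "UNKNOWN"

    @property
    def score(self) -> float | None:
        if self.status == "FAIL":
            return None
        return self.n_unstable / self.n_evaluable


class TrainingError(ValueError):
    """Baseline construction impossible (too few MSS training samples)."""


def count_alleles(hist: LengthHistogram, allele_fraction: float = 0.05) -> int:
    """Number of distinct lengths with support >= allele_fraction x modal count."""
    if hist.depth == 0:
        raise ValueError(f"{hist.locus_id}: cannot count alleles of an empty histogram")
    modal = max(hist.counts.values())
    threshold = allele_fraction * modal
    return sum(1 for c in hist.counts.values() if c >= threshold)


def _sample_sd(values: Sequence[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def build_baseline(
    training_profiles: Sequence[SampleProfile],
    params: CallerParams = CallerParams(),
) -> Baseline:
    """Learn per-locus allele-count mean/SD from known-MSS training samples.

    Only loci with spanning depth >= ``params.depth_min`` in a given training
    sample contribute that sample's allele count; loci with fewer than two
    contributing samples are excluded from the baseline (and recorded).
    """
    if len(training_profiles) < 2:
        raise TrainingError(
            f"need >= 2 MSS training samples, got {len(training_profiles)}"
        )
    locus_ids = sorted(
        {lid for prof in training_profiles for lid in prof.histograms}
    )
    loci: dict[str, LocusBaseline] = {}
    excluded: list[str] = []
    for lid in locus_ids:
        counts = [
            count_alleles(prof.histograms[lid], params.allele_fraction)
            for prof in training_profiles
            if lid in prof.histograms and prof.histograms[lid].depth >= params.depth_min
        ]
        if len(counts) < 2:
            excluded.append(lid)
            continue
        loci[lid] = LocusBaseline(
            locus_id=lid,
            mean_alleles=sum(counts) / len(counts),
            sd_alleles=_sample_sd(counts),
            n_train=len(counts),
        )
    return Baseline(loci=loci, params=params, excluded=tuple(excluded))


def call_locus(
    hist: LengthHistogram,
    baseline_entry: LocusBaseline,
    params: CallerParams,
) -> LocusCall:
    """Evaluate one locus against its baseline: unstable iff the allele count
    strictly exceeds mean + sd_multiplier x SD (strict, so zero-variance
    baselines still require an excess allele)."""
    if hist.depth < params.depth_min:
        return LocusCall(hist.locus_id, evaluable=False, unstable=None, allele_count=None)
    n_alleles = count_alleles(hist, params.allele_fraction)
    threshold = baseline_entry.mean_alleles + params.sd_multiplier * baseline_entry.sd_alleles
    return LocusCall(
        hist.locus_id,
        evaluable=True,
        unstable=n_alleles > threshold,
        allele_count=n_alleles,
    )


def score_sample(
    profile: SampleProfile,
    baseline: Baseline,
    params: CallerParams | None = None,
    panel_subset: Iterable[str] | None = None,
    cutoff: float | None = None,
) -> SampleCall:
    """Score a sample as the fraction of evaluable loci called unstable.

    ``panel_subset`` restricts scoring to those loci; the failure rule then
    uses min(min_evaluable, panel size) so that deliberately small panels can
    still call samples.  Classification is score >= cutoff -> MSI, with the
    trained ``cutoff`` taking precedence over ``params.msi_cutoff``.
    """
    params = params or baseline.params
    if panel_subset is not None:
        subset = list(dict.fromkeys(panel_subset))
        if not subset:
            raise ValueError("panel_subset must not be empty")
        missing = [lid for lid in subset if lid not in baseline.loci]
        if missing:
            raise ValueError(f"panel_subset loci missing from baseline: {missing}")
        locus_ids = subset
    else:
        locus_ids = baseline.locus_ids
    n_evaluable = 0
    n_unstable = 0
    for lid in locus_ids:
        hist = profile.histograms.get(lid)
        if hist is None:
            continue
        call = call_locus(hist, baseline.loci[lid], params)
        if call.evaluable:
            n_evaluable += 1
            if call.unstable:
                n_unstable += 1
    min_eval = min(params.min_evaluable, len(locus_ids))
    if n_evaluable < min_eval:
        return SampleCall(profile.sample_id, n_evaluable, n_unstable, "FAIL",
                          known_status=profile.known_status)
    score = n_unstable / n_evaluable
    threshold = params.msi_cutoff if cutoff is None else cutoff
    status = "MSI" if score >= threshold else "MSS"
    return SampleCall(profile.sample_id, n_evaluable, n_unstable, status,
                      known_status=profile.known_status)


def write_baseline(baseline: Baseline, path: str | Path) -> None:
    """Write baseline TSV plus a JSON sidecar holding the caller parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("locus_id\tmean_alleles\tsd_alleles\tn_train\n")
        for lid in baseline.locus_ids:
            b = baseline.loci[lid]
            fh.write(f"{b.locus_id}\t{b.mean_alleles:.6g}\t{b.sd_alleles:.6g}\t{b.n_train}\n")
    sidecar = {"params": asdict(baseline.params), "excluded": list(baseline.excluded)}
    path.with_suffix(path.suffix + ".params.json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_baseline(path: str | Path) -> Baseline:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".params.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        params = CallerParams(**sidecar["params"])
        excluded = tuple(sidecar.get("excluded", ()))
    else:
        params, excluded = CallerParams(), ()
    loci: dict[str, LocusBaseline] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["locus_id", "mean_alleles", "sd_alleles", "n_train"]:
            raise ValueError(f"{path}: unexpected baseline header {header}")
        for line in fh:
            if not line.strip():
                continue
            lid, mean_s, sd_s, n_s = line.rstrip("\n").split("\t")
            loci[lid] = LocusBaseline(lid, float(mean_s), float(sd_s), int(n_s))
    return Baseline(loci=loci, params=params, excluded=excluded)
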