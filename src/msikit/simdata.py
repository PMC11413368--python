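"""Synthetic FFPE-tumour cohort simulator.

Generates per-locus tract-length histograms that mimic the failure modes of
targeted sequencing of formalin-fixed colorectal tumours: PCR stutter around
the germline tract length, a tumour-fraction-diluted somatic deletion mode at
unstable loci, MSI-high vs MSI-low mutation loads, and per-sample median
depths that are log-normal with a deliberately under-sequenced stratum so
that sample failures occur.  Simulation is at the histogram level — the
caller's input surface — not at the read-sequence level.

Stutter model: a read's slippage magnitude is geometric-tailed
(P(magnitude = j) = (1 - s)·s^j for stutter parameter s), deletion-biased
(an ``insertion_share`` of slipped reads gain rather than lose bases), which
mirrors the classical slippage profile of mononucleotide repeats.  A mutated
locus emits a mixture: with probability ``tumour_fraction`` a read comes from
the somatic allele centred ``shift`` bases below the reference length, with
doubled stutter; otherwise from the germline distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .loci import MicrosatelliteLocus, write_locus_bed, write_sample_sheet, SampleSheetRow
from .profiler import LengthHistogram, SampleProfile, write_histograms


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings (defaults emulate an FFPE CRC cohort:
    14% MSI prevalence, tumour fractions 0.3-0.7, panel of 29 mononucleotide
    repeats, heavy-tailed per-locus depth spanning near-zero to thousands)."""

    n_samples: int = 120
    prevalence: float = 0.14
    n_loci: int = 29
    stutter: float = 0.15
    insertion_share: float = 0.2
    tumour_fraction_range: tuple[float, float] = (0.3, 0.7)
    msi_locus_rate: float = 0.85
    msi_low_rate: float = 0.25
    msi_low_share: float = 0.1
    shift_range: tuple[int, int] = (2, 8)
    depth_median: float = 200.0
    depth_sigma: float = 1.0
    locus_depth_sigma: float = 0.6
    lowdepth_share: float = 0.05
    lowdepth_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "stutter", "insertion_share", "msi_locus_rate",
                     "msi_low_rate", "msi_low_share", "lowdepth_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        if self.shift_range[0] < 1 or self.shift_range[1] < self.shift_range[0]:
            raise ValueError("shift_range must be positive and ordered")
        if self.depth_median <= 0:
            raise ValueError("depth_median must be positive")


@dataclass
class SimulatedCohort:
    """Profiles plus ground truth for a simulated cohort."""

    config: SimulationConfig
    loci: list[MicrosatelliteLocus]
    profiles: list[SampleProfile]
    truth_samples: pd.DataFrame  # sample_id, status, msi_low, tumour_fraction, median_depth
    truth_loci: pd.DataFrame  # sample_id, locus_id, mutated, shift

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.truth_samples.sample_id, self.truth_samples.status))


_FLANK_ALPHABET = np.array(list("CGT"))  # avoids the unit base, keeping anchors unambiguous


def make_synthetic_panel(
    n_loci: int = 29,
    rng: np.random.Generator | None = None,
    flank_k: int = 5,
    unit: str = "A",
) -> list[MicrosatelliteLocus]:
    """An illustrative panel of mononucleotide repeats on a synthetic contig.

    Reference tract lengths are spread over 15-30 bases, the typical range of
    clinically used mononucleotide markers.  Flanks are drawn from non-unit
    bases so that anchor matching is unambiguous.
    """
    rng = rng or np.random.default_rng(0)
    loci = []
    pos = 1000
    for i in range(n_loci):
        ref_len = int(rng.integers(15, 31))
        left = "".join(rng.choice(_FLANK_ALPHABET, size=flank_k))
        right = "".join(rng.choice(_FLANK_ALPHABET, size=flank_k))
        loci.append(
            MicrosatelliteLocus(
                locus_id=f"MSI_{i + 1:02d}",
                chrom="chrSim",
                start=pos,
                end=pos + ref_len,
                unit=unit,
                ref_len=ref_len,
                left_flank=left,
                right_flank=right,
            )
        )
        pos += ref_len + 1000
    return loci


def _stutter_lengths(
    n: int, center: int, stutter: float, insertion_share: float, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if stutter <= 0.0:
        return np.full(n, center, dtype=np.int64)
    # geometric(p) on {1,2,...}; subtract 1 for magnitude on {0,1,...}
    magnitude = rng.geometric(1.0 - stutter, size=n) - 1
    sign = np.where(rng.random(n) < insertion_share, 1, -1)
    return np.maximum(center + sign * magnitude, 0)


def simulate_locus_histogram(
    ref_len: int,
    mutated: bool,
    tumour_fraction: float,
    depth: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    shift: int | None = None,
) -> LengthHistogram:
    """Simulate one locus' spanning-read length histogram.

    Stable loci emit germline stutter around ``ref_len``; mutated loci mix in
    a somatic mode at ``ref_len - shift`` with doubled stutter, weighted by
    the tumour fraction.  Depth 0 yields an empty histogram.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    hist = LengthHistogram(locus_id="", counts={})
    if depth == 0:
        return hist
    if mutated:
        if shift is None:
            shift = int(rng.integers(config.shift_range[0], config.shift_range[1] + 1))
        n_somatic = int(rng.binomial(depth, tumour_fraction))
    else:
        shift, n_somatic = 0, 0
    germline = _stutter_lengths(
        depth - n_somatic, ref_len, config.stutter, config.insertion_share, rng
    )
    somatic = _stutter_lengths(
        n_somatic,
        max(ref_len - shift, 0),
        min(2 * config.stutter, 0.9),
        config.insertion_share,
        rng,
    )
    lengths, counts = np.unique(np.concatenate([germline, somatic]), return_counts=True)
    hist.counts.update({int(l): int(c) for l, c in zip(lengths, counts)})
    return hist


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Simulate a full cohort, reproducibly from ``config.seed``.

    Sample statuses are Bernoulli(prevalence); an ``msi_low_share`` of MSI
    samples carries the low mutation load.  Per-sample median depth is
    log-normal (median ``depth_median``, sigma ``depth_sigma``), scaled down
    hard for the under-sequenced stratum; per-locus depth is Poisson around
    the sample median with an extra log-normal factor.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    loci = make_synthetic_panel(config.n_loci, rng)

    profiles: list[SampleProfile] = []
    sample_rows = []
    locus_rows = []
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        is_msi = rng.random() < config.prevalence
        is_low = bool(is_msi and rng.random() < config.msi_low_share)
        locus_rate = config.msi_low_rate if is_low else config.msi_locus_rate
        tf = float(rng.uniform(*config.tumour_fraction_range))
        median = config.depth_median * float(np.exp(config.depth_sigma * rng.standard_normal()))
        if rng.random() < config.lowdepth_share:
            median *= config.lowdepth_scale
        hists: dict[str, LengthHistogram] = {}
        for loc in loci:
            depth = int(rng.poisson(
                median * float(np.exp(config.locus_depth_sigma * rng.standard_normal()))
            ))
            mutated = bool(is_msi and rng.random() < locus_rate)
            shift = int(rng.integers(config.shift_range[0], config.shift_range[1] + 1)) if mutated else 0
            hist = simulate_locus_histogram(
                loc.ref_len, mutated, tf, depth, config, rng, shift=shift or None
            )
            hist.locus_id = loc.locus_id
            hists[loc.locus_id] = hist
            locus_rows.append(
                {"sample_id": sid, "locus_id": loc.locus_id, "mutated": mutated, "shift": shift}
            )
        status = "MSI" if is_msi else "MSS"
        profiles.append(SampleProfile(sample_id=sid, histograms=hists, known_status=status))
        sample_rows.append(
            {
                "sample_id": sid,
                "status": status,
                "msi_low": is_low,
                "tumour_fraction": round(tf, 4),
                "median_depth": round(median, 2),
            }
        )
    return SimulatedCohort(
        config=config,
        loci=loci,
        profiles=profiles,
        truth_samples=pd.DataFrame(sample_rows),
        truth_loci=pd.DataFrame(locus_rows),
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write the cohort as the exact input surface of the other modules:
    per-sample histogram TSVs, a sample sheet, truth tables and the panel BED."""
    out = Path(out_dir)
    hist_dir = out / "hists"
    hist_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for prof in cohort.profiles:
        hist_path = hist_dir / f"{prof.sample_id}.hist.tsv"
        write_histograms(prof, hist_path)
        rows.append(SampleSheetRow(prof.sample_id, prof.known_status, str(hist_path)))
    write_sample_sheet(rows, out / "samples.tsv")
    write_locus_bed(cohort.loci, out / "panel.bed")
    cohort.truth_samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    cohort.truth_loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
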