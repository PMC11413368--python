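from __future__ import annotations

import pytest

from msikit import (
    Baseline,
    CallerParams,
    LengthHistogram,
    MicrosatelliteLocus,
    SampleProfile,
    SimulationConfig,
    build_baseline,
    make_cv_splits,
    simulate_cohort,
)


def make_hist(locus_id: str, counts: dict[int, int]) -> LengthHistogram:
    return LengthHistogram(locus_id, dict(counts))


def stable_hist(locus_id: str, depth: int = 100) -> LengthHistogram:
    """One clean allele: modal length only."""
    return make_hist(locus_id, {10: depth})


def unstable_hist(locus_id: str, depth: int = 100) -> LengthHistogram:
    """Three well-supported alleles — clearly above a 1-allele baseline."""
    return make_hist(locus_id, {10: depth, 12: depth, 14: depth})


def make_profile(sample_id, locus_ids, unstable=(), status="UNKNOWN", depth=100):
    hists = {
        lid: (unstable_hist(lid, depth) if lid in unstable else stable_hist(lid, depth))
        for lid in locus_ids
    }
    return SampleProfile(sample_id=sample_id, histograms=hists, known_status=status)


@pytest.fixture
def toy_loci() -> list[MicrosatelliteLocus]:
    return [
        MicrosatelliteLocus(
            locus_id=f"L{i}",
            chrom="chrT",
            start=1000 * i,
            end=1000 * i + 20,
            unit="A",
            ref_len=20,
            left_flank="GGATC",
            right_flank="CTTGA",
        )
        for i in range(1, 4)
    ]


@pytest.fixture
def toy_baseline() -> Baseline:
    """3-locus baseline from four clean MSS samples (1 allele everywhere)."""
    locus_ids = ["L1", "L2", "L3"]
    training = [make_profile(f"T{i}", locus_ids, status="MSS") for i in range(4)]
    return build_baseline(training, CallerParams())


@pytest.fixture(scope="session")
def default_cohort():
    """The standard simulated study cohort (simulator defaults, seed 0)."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def default_cohort_cv(default_cohort):
    """1:2 x 10 replicates CV scheme on the standard cohort, seed 0."""
    profiles = {p.sample_id: p for p in default_cohort.profiles}
    labels = default_cohort.labels
    scheme = make_cv_splits(sorted(profiles), labels, "1:2", 10, seed=0)
    return profiles, labels, scheme


def toy_selection_cohort():
    """12-sample, 6-locus cohort where LA alone mis-calls one MSI sample and
    {LA, LB} separates perfectly; L3-L6 carry no signal."""
    locus_ids = ["LA", "LB", "L3", "L4", "L5", "L6"]
    profiles = {}
    labels = {}
    for i in range(8):
        sid = f"N{i}"
        profiles[sid] = make_profile(sid, locus_ids, status="MSS")
        labels[sid] = "MSS"
    plans = {"M1": ("LA", "LB"), "M2": ("LA",), "M3": ("LA",), "M4": ("LB",)}
    for sid, unstable in plans.items():
        profiles[sid] = make_profile(sid, locus_ids, unstable=unstable, status="MSI")
        labels[sid] = "MSI"
    return profiles, labels
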