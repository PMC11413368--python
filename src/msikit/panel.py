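"""Marker-panel experiments: random subsets, greedy backward-forward panel
selection, and depth-threshold / depth-subsampling sweeps.

Panels are judged on cross-validated performance: fewest mis-called samples
summed across all CV runs, with fewest failing samples splitting ties, and
lexicographic locus order as the final deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .caller import CallerParams
from .evaluation import CVResult, CVScheme, run_cv
from .profiler import SampleProfile, subsample_profile


@dataclass(frozen=True)
class PanelSubset:
    """An ordered, duplicate-free subset of panel locus ids with provenance."""

    locus_ids: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("panel subset contains duplicate loci")

    @property
    def size(self) -> int:
        return len(self.locus_ids)


@dataclass
class SelectionStep:
    k: int
    panel: PanelSubset
    miscalls: int
    failures: int


@dataclass
class SelectionTrace:
    """Best panel found at each size k, with its cross-validated objective."""

    steps: list[SelectionStep] = field(default_factory=list)
    stop_reason: str = ""

    def best_at(self, k: int) -> SelectionStep:
        for step in self.steps:
            if step.k == k:
                return step
        raise KeyError(f"no recorded panel of size {k}")


def random_subsets(
    panel_locus_ids: Sequence[str],
    sizes: Iterable[int] = (3, 5, 10, 20),
    replicates: int = 10,
    seed: int = 0,
) -> list[PanelSubset]:
    """Seeded without-replacement random subsets: ``replicates`` per size."""
    ids = list(panel_locus_ids)
    rng = np.random.default_rng(seed)
    subsets: list[PanelSubset] = []
    for size in sorted(set(sizes)):
        if size > len(ids):
            raise ValueError(f"subset size {size} exceeds panel size {len(ids)}")
        for rep in range(replicates):
            draw = tuple(rng.choice(ids, size=size, replace=False))
            subsets.append(PanelSubset(draw, provenance=f"random(seed={seed}, replicate={rep})"))
    return subsets


def evaluate_panel(
    profiles: Mapping[str, SampleProfile],
    labels: Mapping[str, str],
    scheme: CVScheme,
    params: CallerParams,
    subset: Sequence[str] | None = None,
) -> tuple[int, int, CVResult]:
    """Cross-validated objective of a panel: (total miscalls, total failures)."""
    cv = run_cv(profiles, labels, scheme, params, panel_subset=subset)
    agg = cv.aggregate()
    return agg["total_miscalls"], agg["total_failures"], cv


def backward_forward_select(
    profiles: Mapping[str, SampleProfile],
    labels: Mapping[str, str],
    cv_scheme: CVScheme,
    params: CallerParams = CallerParams(),
    max_size: int | None = None,
    candidate_loci: Sequence[str] | None = None,
) -> SelectionTrace:
    """Greedy backward-forward search for minimal high-performing marker sets.

    Starting from one locus, each target size k is reached by adding the
    single best absent locus, then refined by alternating a strictly-improving
    removal with the best re-addition; refinement stops when no removal
    improves the objective or a size-k panel repeats.  The best size-k panel
    seen is recorded before growing to k+1.
    """
    if candidate_loci is None:
        any_profile = next(iter(profiles.values()))
        candidate_loci = sorted(any_profile.histograms)
    else:
        candidate_loci = list(candidate_loci)
    if max_size is None:
        max_size = len(candidate_loci)
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    max_size = min(max_size, len(candidate_loci))

    cache: dict[frozenset, tuple[int, int]] = {}

    def objective(subset: frozenset) -> tuple[int, int]:
        if subset not in cache:
            miscalls, failures, _ = evaluate_panel(
                profiles, labels, cv_scheme, params, sorted(subset)
            )
            cache[subset] = (miscalls, failures)
        return cache[subset]

    def best_addition(current: frozenset) -> frozenset:
        candidates = [lid for lid in candidate_loci if lid not in current]
        return min(
            (current | {lid} for lid in candidates),
            key=lambda s: (objective(s), tuple(sorted(s))),
        )

    trace = SelectionTrace()
    current: frozenset = frozenset()
    for k in range(1, max_size + 1):
        current = best_addition(current)
        best_k = current
        visited = {current}
        while len(current) > 1:
            reduced = min(
                (current - {lid} for lid in current),
                key=lambda s: (objective(s), tuple(sorted(s))),
            )
            if objective(reduced) >= objective(current):
                break
            regrown = best_addition(reduced)
            if (objective(regrown), tuple(sorted(regrown))) < (
                objective(best_k),
                tuple(sorted(best_k)),
            ):
                best_k = regrown
            if regrown in visited:
                break
            visited.add(regrown)
            current = regrown
        current = best_k
        miscalls, failures = objective(best_k)
        trace.steps.append(
            SelectionStep(
                k=k,
                panel=PanelSubset(tuple(sorted(best_k)), provenance=f"selected(step {k})"),
                miscalls=miscalls,
                failures=failures,
            )
        )
    trace.stop_reason = f"reached max_size {max_size}"
    return trace


def depth_threshold_sweep(
    profiles: Mapping[str, SampleProfile],
    labels: Mapping[str, str],
    cv_scheme: CVScheme,
    params: CallerParams = CallerParams(),
    thresholds: Iterable[int] = (10, 15, 20, 30),
) -> dict[int, dict]:
    """Re-run the full CV at several minimum locus depths.

    Returns per-threshold aggregates (miscalls, failures, mean AUC...) keyed by
    the depth threshold.
    """
    thresholds = sorted(set(thresholds))
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    out: dict[int, dict] = {}
    for t in thresholds:
        cv = run_cv(profiles, labels, cv_scheme, params.with_depth_min(t))
        out[t] = cv.aggregate()
    return out


def depth_subsample_sweep(
    profiles: Mapping[str, SampleProfile],
    labels: Mapping[str, str],
    cv_scheme: CVScheme,
    params: CallerParams = CallerParams(),
    max_depths: Iterable[int] = (40, 60, 80),
    seed: int = 0,
) -> dict[int, dict]:
    """Re-run the CV with validation samples depth-capped per locus.

    Subsampling caps each validation histogram at ``max_depth`` spanning reads
    (training untouched), probing whether reduced per-locus data — rather than
    fewer passing loci — degrades calling.  Caps below ``depth_min`` would
    fail every locus and are rejected.
    """
    max_depths = sorted(set(max_depths))
    for d in max_depths:
        if d < params.depth_min:
            raise ValueError(
                f"max_depth {d} is below depth_min {params.depth_min}: "
                "every locus would fail"
            )
    out: dict[int, dict] = {}
    for d in max_depths:
        transform: Callable[[SampleProfile], SampleProfile] = (
            lambda prof, _d=d: subsample_profile(prof, _d, seed)
        )
        cv = run_cv(profiles, labels, cv_scheme, params, validation_transform=transform)
        out[d] = cv.aggregate()
    return out
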