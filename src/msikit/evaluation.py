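"""Cutoff optimisation, ROC/AUC, confusion accounting and cross-validation.

The optimal cutoff minimises total mis-called samples (false positives plus
false negatives) under the rule "call MSI iff score >= cutoff"; among
minimising intervals the midpoint of the widest open gap between adjacent
observed scores is returned, which maximises the decision margin and is
deterministic.  AUC is the Mann-Whitney pair statistic (ties count 1/2),
identical to trapezoidal ROC area but with an unambiguous tie rule.

Cross-validation follows a replicated train:validation design: samples are
dealt into 3, 5 or 10 stratified folds (ratios 1:2, 1:4, 1:9); each fold
serves once as the TRAINING set, with the remainder as validation, and the
whole dealing is repeated for several replicates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .caller import Baseline, CallerParams, SampleCall, build_baseline, score_sample
from .profiler import SampleProfile

RATIO_FOLDS = {"1:2": 3, "1:4": 5, "1:9": 10}


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts, failure tally and derived percentages for a cohort.

    Percentages use the conventions of clinical concordance reporting:
    fp_pct and fn_pct are relative to ALL known-MSS / known-MSI samples
    (including failures); fail_pct is relative to the whole cohort; and
    concordance is relative to assessable (non-failing) samples only.
    """

    n_total: int
    true_pos: int
    true_neg: int
    false_pos: int
    false_neg: int
    n_fail: int
    n_known_msi: int
    n_known_mss: int
    auc: float | None = None

    def __post_init__(self) -> None:
        if self.true_pos + self.true_neg + self.false_pos + self.false_neg != self.n_assessable:
            raise ValueError("confusion cells must sum to assessable samples")

    @property
    def n_assessable(self) -> int:
        return self.n_total - self.n_fail

    @property
    def n_miscalled(self) -> int:
        return self.false_pos + self.false_neg

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.false_pos / self.n_known_mss if self.n_known_mss else 0.0

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.false_neg / self.n_known_msi if self.n_known_msi else 0.0

    @property
    def fail_pct(self) -> float:
        return 100.0 * self.n_fail / self.n_total if self.n_total else 0.0

    @property
    def concordance_pct(self) -> float:
        if self.n_assessable == 0:
            return 0.0
        return 100.0 * (self.true_pos + self.true_neg) / self.n_assessable

    def as_dict(self) -> dict:
        """Reportable summary; percentages rounded to one decimal."""
        return {
            "n_total": self.n_total,
            "n_assessable": self.n_assessable,
            "true_pos": self.true_pos,
            "true_neg": self.true_neg,
            "false_pos": self.false_pos,
            "false_neg": self.false_neg,
            "n_fail": self.n_fail,
            "fp_pct": round(self.fp_pct, 1),
            "fn_pct": round(self.fn_pct, 1),
            "fail_pct": round(self.fail_pct, 1),
            "concordance_pct": round(self.concordance_pct, 1),
            "auc": None if self.auc is None else round(self.auc, 4),
        }


def optimal_cutoff(scores: Sequence[tuple[float, str]]) -> float:
    """Cutoff minimising mis-calls under "MSI iff score >= cutoff".

    ``scores`` are (score, known_status) pairs with status MSI or MSS; FAIL
    samples must be excluded upstream.  Among cutoffs achieving the minimum,
    the midpoint of the widest open interval between adjacent observed scores
    is returned (unbounded end intervals count as width 0, so they are chosen
    only when no interior gap attains the minimum; remaining ties go to the
    lowest cutoff).
    """
    msi = sorted(s for s, lab in scores if lab == "MSI")
    mss = sorted(s for s, lab in scores if lab == "MSS")
    if not msi or not mss:
        raise ValueError("optimal_cutoff needs at least one score of each class")
    uniq = sorted({s for s, _ in scores})
    m = len(uniq)
    # interval i: cutoffs in (uniq[i-1], uniq[i]]; i = 0 means c <= uniq[0]
    # (everything MSI), i = m means c > uniq[-1] (everything MSS).
    best: tuple[int, float, int] | None = None  # (miscalls, -width, index)
    best_cut = uniq[0]
    import bisect

    for i in range(m + 1):
        if i == 0:
            cut, width = uniq[0], 0.0
        elif i == m:
            cut, width = float(np.nextafter(uniq[-1], np.inf)), 0.0
        else:
            cut, width = (uniq[i - 1] + uniq[i]) / 2.0, uniq[i] - uniq[i - 1]
        boundary = uniq[i - 1] if i > 0 else -math.inf
        fn = bisect.bisect_right(msi, boundary)  # MSI scores < cut
        fp = len(mss) - bisect.bisect_right(mss, boundary)  # MSS scores >= cut
        key = (fn + fp, -width, i)
        if best is None or key < best:
            best, best_cut = key, cut
    return best_cut


def auc(scores: Sequence[tuple[float, str]]) -> float:
    """Mann-Whitney AUC: P(MSI score > MSS score) + P(equal)/2."""
    msi = [s for s, lab in scores if lab == "MSI"]
    mss = [s for s, lab in scores if lab == "MSS"]
    if not msi or not mss:
        raise ValueError("auc needs at least one score of each class")
    ranks = rankdata(msi + mss)
    r_msi = float(np.sum(ranks[: len(msi)]))
    u = r_msi - len(msi) * (len(msi) + 1) / 2.0
    return u / (len(msi) * len(mss))


def confusion(
    calls: Sequence[SampleCall],
    labels: Mapping[str, str],
    auc_value: float | None = None,
) -> EvaluationResult:
    """Tally a cohort of calls against known MSI/MSS labels.

    FAIL calls contribute only to the failure tally; positives are MSI.
    """
    tp = tn = fp = fn = n_fail = 0
    n_msi = n_mss = 0
    for call in calls:
        known = labels[call.sample_id]
        if known not in ("MSI", "MSS"):
            raise ValueError(f"{call.sample_id}: label must be MSI or MSS, got {known!r}")
        if known == "MSI":
            n_msi += 1
        else:
            n_mss += 1
        if call.status == "FAIL":
            n_fail += 1
        elif call.status == "MSI":
            tp += known == "MSI"
            fp += known == "MSS"
        else:
            tn += known == "MSS"
            fn += known == "MSI"
    return EvaluationResult(
        n_total=len(calls),
        true_pos=tp,
        true_neg=tn,
        false_pos=fp,
        false_neg=fn,
        n_fail=n_fail,
        n_known_msi=n_msi,
        n_known_mss=n_mss,
        auc=auc_value,
    )


@dataclass(frozen=True)
class CVScheme:
    """Replicated stratified fold assignments for one train:validation ratio."""

    ratio: str
    n_replicates: int
    folds: tuple[tuple[tuple[str, ...], ...], ...]  # [replicate][fold] -> sample_ids
    seed: int

    @property
    def n_folds(self) -> int:
        return RATIO_FOLDS[self.ratio]

    @property
    def n_runs(self) -> int:
        return self.n_replicates * self.n_folds

    def runs(self):
        """Yield (replicate, fold_index, train_ids, validation_ids)."""
        for rep, rep_folds in enumerate(self.folds):
            for fi, fold in enumerate(rep_folds):
                validation = tuple(
                    sid for fj, other in enumerate(rep_folds) if fj != fi for sid in other
                )
                yield rep, fi, fold, validation


def make_cv_splits(
    sample_ids: Sequence[str],
    labels: Mapping[str, str],
    ratio: str = "1:2",
    n_replicates: int = 10,
    seed: int = 0,
) -> CVScheme:
    """Deal samples into stratified folds, repeated ``n_replicates`` times.

    Each fold later serves once as the training set; stratification keeps each
    fold's MSI fraction within one sample of the cohort's, which matters at
    low prevalence where unstratified small folds can lack MSI entirely.
    """
    if ratio not in RATIO_FOLDS:
        raise ValueError(f"ratio must be one of {sorted(RATIO_FOLDS)}, got {ratio!r}")
    n_folds = RATIO_FOLDS[ratio]
    ids = np.asarray(sample_ids)
    y = np.asarray([labels[s] for s in sample_ids])
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} samples cannot fill {n_folds} folds")
    replicates = []
    for rep in range(n_replicates):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=(seed + rep) % (2**31 - 1)
        )
        rep_folds = []
        for _, fold_idx in skf.split(ids.reshape(-1, 1), y):
            fold = tuple(ids[fold_idx])
            n_mss = sum(labels[s] == "MSS" for s in fold)
            if n_mss < 2:
                raise ValueError(
                    f"replicate {rep}: a training fold has only {n_mss} MSS samples; "
                    "baseline construction needs >= 2"
                )
            rep_folds.append(fold)
        replicates.append(tuple(rep_folds))
    return CVScheme(ratio=ratio, n_replicates=n_replicates,
                    folds=tuple(replicates), seed=seed)


@dataclass
class CVRun:
    replicate: int
    fold_index: int
    cutoff: float | None
    result: EvaluationResult | None
    valid: bool
    reason: str = ""


@dataclass
class CVResult:
    """Per-run evaluation results plus per-sample mean validation scores."""

    runs: list[CVRun]
    mean_scores: dict[str, float]

    @property
    def valid_runs(self) -> list[CVRun]:
        return [r for r in self.runs if r.valid]

    def aggregate(self) -> dict:
        """Totals and ranges across valid runs (AUC range, failure-rate range)."""
        valid = self.valid_runs
        aucs = [r.result.auc for r in valid if r.result.auc is not None]
        fail_rates = [r.result.fail_pct for r in valid]
        total_assessable = sum(r.result.n_assessable for r in valid)
        total_miscalls = sum(r.result.n_miscalled for r in valid)
        return {
            "n_runs": len(self.runs),
            "n_valid": len(valid),
            "total_miscalls": total_miscalls,
            "total_failures": sum(r.result.n_fail for r in valid),
            "total_assessable": total_assessable,
            "miscall_rate_pct": (
                100.0 * total_miscalls / total_assessable if total_assessable else 0.0
            ),
            "mean_auc": float(np.mean(aucs)) if aucs else None,
            "auc_range": (min(aucs), max(aucs)) if aucs else None,
            "fail_pct_range": (min(fail_rates), max(fail_rates)) if fail_rates else None,
        }


def run_cv(
    profiles: Mapping[str, SampleProfile],
    labels: Mapping[str, str],
    scheme: CVScheme,
    params: CallerParams = CallerParams(),
    panel_subset: Sequence[str] | None = None,
    validation_transform: Callable[[SampleProfile], SampleProfile] | None = None,
) -> CVResult:
    """Run the full replicated cross-validation.

    Per run: a baseline is built from the MSS members of the training fold,
    the cutoff is trained on all non-failing training-fold scores, and the
    validation fold is scored and classified with that cutoff.  Runs whose
    training fold cannot support baseline or cutoff training are recorded as
    invalid, never silently skipped.  ``validation_transform`` (e.g. depth
    subsampling) is applied to validation profiles only.
    """
    runs: list[CVRun] = []
    score_sums: dict[str, float] = {}
    score_ns: dict[str, int] = {}
    for rep, fi, train_ids, val_ids in scheme.runs():
        mss_train = [profiles[s] for s in train_ids if labels[s] == "MSS"]
        if len(mss_train) < 2:
            runs.append(CVRun(rep, fi, None, None, False, "training fold has < 2 MSS"))
            continue
        try:
            baseline = build_baseline(mss_train, params)
        except ValueError as exc:
            runs.append(CVRun(rep, fi, None, None, False, str(exc)))
            continue
        subset = panel_subset
        if subset is not None:
            subset = [lid for lid in subset if lid in baseline.loci]
            if not subset:
                runs.append(CVRun(rep, fi, None, None, False,
                                  "no panel_subset locus survives the baseline"))
                continue
        train_scores = []
        for sid in train_ids:
            call = score_sample(profiles[sid], baseline, params, subset)
            if call.status != "FAIL":
                train_scores.append((call.score, labels[sid]))
        classes = {lab for _, lab in train_scores}
        if classes != {"MSI", "MSS"}:
            runs.append(CVRun(rep, fi, None, None, False,
                              "training fold lacks a non-failing class"))
            continue
        cutoff = optimal_cutoff(train_scores)
        val_calls = []
        val_scores = []
        for sid in val_ids:
            prof = profiles[sid]
            if validation_transform is not None:
                prof = validation_transform(prof)
            call = score_sample(prof, baseline, params, subset, cutoff=cutoff)
            val_calls.append(call)
            if call.status != "FAIL":
                val_scores.append((call.score, labels[sid]))
                score_sums[sid] = score_sums.get(sid, 0.0) + call.score
                score_ns[sid] = score_ns.get(sid, 0) + 1
        val_classes = {lab for _, lab in val_scores}
        auc_value = auc(val_scores) if val_classes == {"MSI", "MSS"} else None
        runs.append(
            CVRun(rep, fi, cutoff, confusion(val_calls, labels, auc_value), True)
        )
    mean_scores = {sid: score_sums[sid] / score_ns[sid] for sid in score_sums}
    return CVResult(runs=runs, mean_scores=mean_scores)


def import_external_scores(path: str | Path) -> list[tuple[str, float | None]]:
    """Read an external tool's score table (TSV: sample_id, score).

    Unparseable numeric tokens raise; an empty or NA score means the tool
    failed that sample and is returned as None.
    """
    out: list[tuple[str, float | None]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"sample_id", "score"}.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns sample_id, score")
        for idx, rec in enumerate(reader, start=2):
            token = (rec["score"] or "").strip()
            if token in ("", "NA", "NaN", "nan", "."):
                out.append((rec["sample_id"], None))
                continue
            try:
                out.append((rec["sample_id"], float(token)))
            except ValueError as exc:
                raise ValueError(f"{path}: row {idx}: unparseable score {token!r}") from exc
    return out


def write_roc_points(scores: Sequence[tuple[float, str]], path: str | Path) -> None:
    """Dump ROC coordinates (threshold, fpr, tpr) as TSV for external plotting."""
    msi = np.array(sorted(s for s, lab in scores if lab == "MSI"))
    mss = np.array(sorted(s for s, lab in scores if lab == "MSS"))
    thresholds = sorted({s for s, _ in scores})
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t in thresholds:
            tpr = float(np.mean(msi >= t))
            fpr = float(np.mean(mss >= t))
            fh.write(f"{t:.6g}\t{fpr:.6g}\t{tpr:.6g}\n")
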