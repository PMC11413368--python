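import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit import (
    CallerParams,
    SampleCall,
    auc,
    confusion,
    import_external_scores,
    make_cv_splits,
    optimal_cutoff,
    run_cv,
)

from _oracles import (
    exhaustive_min_miscalls,
    miscalls_at_cutoff,
    pair_counting_auc,
    random_score_instance,
)
from conftest import make_profile, toy_selection_cohort


def _scores(mss, msi):
    return [(s, "MSS") for s in mss] + [(s, "MSI") for s in msi]


class TestOptimalCutoff:
    def test_clean_separation_widest_gap(self):
        cut = optimal_cutoff(_scores([0.0, 0.05, 0.1], [0.3, 0.4]))
        assert cut == pytest.approx(0.2)

    def test_one_miscall_minimum_prefers_wider_gap(self):
        cut = optimal_cutoff(_scores([0.0, 0.25], [0.2, 0.4]))
        assert cut == pytest.approx(0.1)

    def test_degenerate_tie_is_deterministic(self):
        scores = _scores([0.1], [0.1])
        cuts = {optimal_cutoff(scores) for _ in range(5)}
        assert len(cuts) == 1
        assert miscalls_at_cutoff(scores, cuts.pop()) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff(_scores([0.1, 0.2], []))

    def test_matches_exhaustive_scan(self):
        """Achieved mis-call count equals the exhaustive candidate minimum."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores = random_score_instance(rng)
            cut = optimal_cutoff(scores)
            assert miscalls_at_cutoff(scores, cut) == exhaustive_min_miscalls(scores)


class TestAUC:
    @pytest.mark.parametrize(
        "mss,msi,expected",
        [
            ([0.0, 0.05, 0.1], [0.4, 0.35], 1.0),
            ([0.2], [0.2], 0.5),
            ([0.2, 0.0], [0.3, 0.1], 0.75),
        ],
    )
    def test_examples(self, mss, msi, expected):
        assert auc(_scores(mss, msi)) == pytest.approx(expected)

    def test_matches_pair_counting_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = random_score_instance(rng, n_max=30)
            got = auc(scores)
            assert got == pytest.approx(pair_counting_auc(scores))
            y = [1 if lab == "MSI" else 0 for _, lab in scores]
            assert got == pytest.approx(roc_auc_score(y, [s for s, _ in scores]))

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_increasing_transform(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        scores = random_score_instance(rng, n_max=20)
        transformed = [(np.exp(3 * s) - 0.5, lab) for s, lab in scores]
        assert auc(transformed) == pytest.approx(auc(scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(_scores([], [0.4]))


def _cohort_calls(n_msi, n_mss, fn=0, fp=0, fails_msi=0, fails_mss=0):
    calls, labels = [], {}
    idx = 0
    for kind, n, miscalled, failed in (
        ("MSI", n_msi, fn, fails_msi),
        ("MSS", n_mss, fp, fails_mss),
    ):
        wrong = "MSS" if kind == "MSI" else "MSI"
        for j in range(n):
            sid = f"{kind}{j}"
            labels[sid] = kind
            if j < failed:
                status = "FAIL"
            elif j < failed + miscalled:
                status = wrong
            else:
                status = kind
            calls.append(SampleCall(sid, 20, 5, status))
            idx += 1
    return calls, labels


class TestConfusion:
    def test_published_style_percentages(self):
        calls, labels = _cohort_calls(47, 288, fn=3, fp=3)
        result = confusion(calls, labels)
        assert result.fn_pct == pytest.approx(6.4, abs=0.05)
        assert result.fp_pct == pytest.approx(1.0, abs=0.05)
        assert result.n_miscalled == 6

    def test_failures_counted_separately(self):
        calls, labels = _cohort_calls(47, 288, fn=2, fails_msi=5, fails_mss=14)
        result = confusion(calls, labels)
        assert result.n_fail == 19
        assert result.n_assessable == 335 - 19
        assert result.fail_pct == pytest.approx(100 * 19 / 335)

    def test_cells_recompose(self):
        calls, labels = _cohort_calls(10, 40, fn=2, fp=3, fails_msi=1, fails_mss=2)
        r = confusion(calls, labels)
        assert r.true_pos + r.false_neg == 10 - 1  # assessable known-MSI
        assert r.true_neg + r.false_pos == 40 - 2  # assessable known-MSS
        assert r.true_pos + r.true_neg + r.false_pos + r.false_neg == r.n_assessable


class TestMakeCVSplits:
    @pytest.mark.parametrize("ratio,n_folds", [("1:2", 3), ("1:4", 5), ("1:9", 10)])
    def test_fold_counts_and_partition(self, ratio, n_folds):
        ids = [f"S{i}" for i in range(40)]
        labels = {s: ("MSI" if i % 7 == 0 else "MSS") for i, s in enumerate(ids)}
        scheme = make_cv_splits(ids, labels, ratio, n_replicates=4, seed=1)
        assert scheme.n_folds == n_folds
        assert scheme.n_runs == 4 * n_folds
        for rep_folds in scheme.folds:
            flat = [s for fold in rep_folds for s in fold]
            assert sorted(flat) == sorted(ids)  # exact partition
            sizes = [len(f) for f in rep_folds]
            assert max(sizes) - min(sizes) <= 1

    def test_stratification_within_one_sample(self):
        ids = [f"S{i}" for i in range(60)]
        labels = {s: ("MSI" if i < 9 else "MSS") for i, s in enumerate(ids)}
        scheme = make_cv_splits(ids, labels, "1:2", n_replicates=5, seed=2)
        for rep_folds in scheme.folds:
            msi_per_fold = [sum(labels[s] == "MSI" for s in f) for f in rep_folds]
            assert max(msi_per_fold) - min(msi_per_fold) <= 1

    def test_thirty_runs_for_default_replicates(self):
        ids = [f"S{i}" for i in range(30)]
        labels = {s: ("MSI" if i < 6 else "MSS") for i, s in enumerate(ids)}
        scheme = make_cv_splits(ids, labels, "1:2", n_replicates=10, seed=0)
        assert scheme.n_runs == 30

    def test_deterministic_for_seed(self):
        ids = [f"S{i}" for i in range(24)]
        labels = {s: ("MSI" if i < 6 else "MSS") for i, s in enumerate(ids)}
        a = make_cv_splits(ids, labels, "1:4", 3, seed=9)
        b = make_cv_splits(ids, labels, "1:4", 3, seed=9)
        assert a.folds == b.folds

    def test_unsatisfiable_mss_constraint(self):
        ids = [f"S{i}" for i in range(9)]
        labels = {s: ("MSS" if i < 4 else "MSI") for i, s in enumerate(ids)}
        with pytest.raises(ValueError, match="MSS"):
            make_cv_splits(ids, labels, "1:2", 2, seed=0)


class TestRunCV:
    def test_perfect_separation_gives_auc_one(self):
        profiles, labels = toy_selection_cohort()
        scheme = make_cv_splits(sorted(profiles), labels, "1:2", 3, seed=0)
        result = run_cv(profiles, labels, scheme, CallerParams(min_evaluable=1))
        assert result.valid_runs
        for run in result.valid_runs:
            if run.result.auc is not None:
                assert run.result.auc == 1.0

    def test_mean_scores_cover_validated_samples(self):
        profiles, labels = toy_selection_cohort()
        scheme = make_cv_splits(sorted(profiles), labels, "1:2", 3, seed=0)
        result = run_cv(profiles, labels, scheme, CallerParams(min_evaluable=1))
        assert set(result.mean_scores) == set(profiles)
        for sid, score in result.mean_scores.items():
            assert 0.0 <= score <= 1.0

    def test_degenerate_training_fold_recorded_invalid(self):
        """MSI samples below callable depth leave no MSI training scores."""
        locus_ids = [f"L{i}" for i in range(6)]
        profiles, labels = {}, {}
        for i in range(9):
            sid = f"N{i}"
            profiles[sid] = make_profile(sid, locus_ids, status="MSS")
            labels[sid] = "MSS"
        for i in range(3):
            sid = f"M{i}"
            profiles[sid] = make_profile(sid, locus_ids, status="MSI", depth=2)
            labels[sid] = "MSI"
        scheme = make_cv_splits(sorted(profiles), labels, "1:2", 2, seed=0)
        result = run_cv(profiles, labels, scheme, CallerParams(min_evaluable=1))
        assert result.runs and not result.valid_runs
        assert all("class" in r.reason for r in result.runs)


class TestImportExternalScores:
    def test_values_na_and_empty(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("sample_id\tscore\nS1\t0.31\nS2\tNA\n")
        assert import_external_scores(path) == [("S1", 0.31), ("S2", None)]

    def test_header_only(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("sample_id\tscore\n")
        assert import_external_scores(path) == []

    def test_unparseable_score_names_row(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("sample_id\tscore\nS1\t0.2\nS2\tabc\n")
        with pytest.raises(ValueError, match="row 3"):
            import_external_scores(path)
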