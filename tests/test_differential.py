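"""ROC/AUC screening, Mann-Whitney on ROI means, BH correction."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from msihet.containers import FeatureMatrix
from msihet.differential import (
    ScreenConfig,
    auc,
    balanced_sample,
    bh_adjust,
    mann_whitney_p,
    roc_screen,
    roi_mean_test,
    screen_features,
    select_significant,
)


def brute_force_auc(a, b):
    """Pair-counting oracle: P(b > a) + 0.5 P(b == a)."""
    wins = sum((y > x) + 0.5 * (y == x) for x in a for y in b)
    return wins / (len(a) * len(b))


def _matrix(intensities, classes, patients, rois):
    n = len(classes)
    meta = pd.DataFrame(
        {
            "spectrum_index": range(n),
            "x": range(1, n + 1),
            "y": [1] * n,
            "patient_id": patients,
            "roi_id": rois,
            "roi_class": classes,
        }
    )
    intensities = np.asarray(intensities, dtype=float)
    return FeatureMatrix(
        feature_mz=np.arange(intensities.shape[1], dtype=float) + 700.0,
        intensities=intensities,
        meta=meta,
    )


def _labelled_matrix(rng, n_features=20, n_pat=4, rois_per=3, px=10,
                     effect_features=(), fold=2.0):
    classes, patients, rois, rows = [], [], [], []
    for p in range(n_pat):
        for cls in ("WD", "PD"):
            for r in range(rois_per):
                for _ in range(px):
                    classes.append(cls)
                    patients.append(f"P{p}")
                    rois.append(f"P{p}_{cls}_{r}")
    n = len(classes)
    base = rng.lognormal(2.0, 0.4, (n, n_features))
    pd_mask = np.array([c == "PD" for c in classes])
    for f in effect_features:
        base[pd_mask, f] *= fold
    return _matrix(base, classes, patients, rois)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3], [4, 5, 6]) == 1.0

    def test_tie_handling_worked_example(self):
        assert auc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    def test_self_comparison_is_half(self, rng):
        x = rng.normal(size=20)
        assert auc(x, x) == pytest.approx(0.5)

    def test_complement_symmetry(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=12)
        assert auc(a, b) == pytest.approx(1.0 - auc(b, a))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=25),
        st.lists(st.integers(0, 8), min_size=1, max_size=25),
    )
    def test_equals_brute_force_pair_counting(self, a, b):
        assert auc(a, b) == pytest.approx(brute_force_auc(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_reference_step_up_on_1000_random_vectors(self, rng):
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m)
            ref = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)

    def test_monotone_and_rank_bound(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        ranks = np.empty(50, dtype=int)
        ranks[order] = np.arange(1, 51)
        # p <= q <= p * m / rank (the step-up sandwich)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= np.minimum(1.0, p * 50 / ranks) + 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestMannWhitney:
    def test_exact_worked_example(self):
        # full enumeration over C(6,3)=20 labelings: 2 * 1/20
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert mann_whitney_p([2, 2, 2], [2, 2, 2]) == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        assert mann_whitney_p(a, b) == pytest.approx(mann_whitney_p(b, a))

    def test_exact_branch_matches_scipy_exact(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 8)))
            b = rng.normal(size=int(rng.integers(3, 8)))
            ref = stats.mannwhitneyu(b, a, alternative="two-sided",
                                     method="exact").pvalue
            assert mann_whitney_p(a, b) == pytest.approx(ref, abs=1e-12)

    def test_exact_vs_asymptotic_close_at_8v8(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = mann_whitney_p(a, b, exact_max_n=8)
            approx = mann_whitney_p(a, b, exact_max_n=0)
            assert abs(exact - approx) <= 0.02


class TestBalancedSample:
    def _labels(self, per_patient=40):
        classes, patients = [], []
        for p in range(5):
            for cls in ("WD", "PD"):
                classes += [cls] * per_patient
                patients += [f"P{p}"] * per_patient
        return np.array(classes), np.array(patients)

    def test_equal_quota_per_patient(self):
        classes, patients = self._labels(40)
        idx = balanced_sample(classes, patients, 150, rng=0)
        for cls in ("WD", "PD"):
            assert len(idx[cls]) == 150  # 30 per patient x 5
            drawn_patients = patients[idx[cls]]
            counts = pd.Series(drawn_patients).value_counts()
            assert (counts == 30).all()
            assert (classes[idx[cls]] == cls).all()

    def test_single_patient_gets_full_quota(self):
        classes = np.array(["WD"] * 50 + ["PD"] * 50)
        patients = np.array(["P1"] * 100)
        idx = balanced_sample(classes, patients, 30, rng=1)
        assert len(idx["WD"]) == 30

    def test_deterministic_under_seed(self):
        classes, patients = self._labels()
        i1 = balanced_sample(classes, patients, 100, rng=7)
        i2 = balanced_sample(classes, patients, 100, rng=7)
        assert all(np.array_equal(i1[c], i2[c]) for c in i1)

    def test_quota_reduced_with_warning_when_insufficient(self):
        classes, patients = self._labels(10)
        with pytest.warns(UserWarning, match="quota reduced"):
            idx = balanced_sample(classes, patients, 500, rng=2)
        assert len(idx["WD"]) == 50  # 10 per patient, all available

    def test_absent_class_rejected(self):
        classes = np.array(["WD"] * 10)
        patients = np.array(["P1"] * 10)
        with pytest.raises(ValueError, match="absent"):
            balanced_sample(classes, patients, 5, rng=0)


class TestRocScreen:
    def test_disjoint_supports_give_auc_one(self, rng):
        mat = _labelled_matrix(rng, n_features=3)
        pd_mask = (mat.meta["roi_class"] == "PD").to_numpy()
        mat.intensities[:, 0] = np.where(pd_mask, 100.0, 1.0) + rng.random(mat.n_spectra)
        cfg = ScreenConfig(n_per_condition=80, seed=3)
        aucs, n_pass = roc_screen(mat, cfg)
        assert np.all(aucs[0] == 1.0)
        assert n_pass[0] == cfg.n_replicates

    def test_null_features_fail_the_gate(self, rng):
        mat = _labelled_matrix(rng, n_features=30)
        cfg = ScreenConfig(n_per_condition=100, seed=0)
        _, n_pass = roc_screen(mat, cfg)
        assert np.all(n_pass < cfg.min_pass)

    def test_low_auc_counts_via_complement(self, rng):
        mat = _labelled_matrix(rng, n_features=2)
        pd_mask = (mat.meta["roi_class"] == "PD").to_numpy()
        mat.intensities[:, 1] = np.where(pd_mask, 1.0, 100.0) + rng.random(mat.n_spectra)
        aucs, n_pass = roc_screen(mat, ScreenConfig(n_per_condition=80, seed=3))
        assert np.all(aucs[1] == 0.0)
        assert n_pass[1] == 5  # direction-agnostic gate

    def test_per_patient_mode_gives_one_replicate_per_patient(self, rng):
        mat = _labelled_matrix(rng, n_features=4, n_pat=3)
        cfg = ScreenConfig(n_per_condition=50, seed=0, replicate_mode="per-patient")
        aucs, _ = roc_screen(mat, cfg)
        assert aucs.shape == (4, 3)


class TestRoiMeanTest:
    def test_roi_means_not_pixels_drive_the_test(self, rng):
        mat = _labelled_matrix(rng, n_features=2, n_pat=2, rois_per=3, px=20)
        pvals, roi_means = roi_mean_test(mat)
        assert len(pvals) == 2
        assert len(roi_means) == 12  # 2 patients x 2 classes x 3 ROIs

    def test_requires_two_rois_per_class(self, rng):
        mat = _labelled_matrix(rng, n_features=2, n_pat=1, rois_per=1, px=5)
        with pytest.raises(ValueError, match="ROIs"):
            roi_mean_test(mat)


class TestSelection:
    def test_conjunction_of_thresholds(self):
        screen = pd.DataFrame(
            {
                "feature_mz": [700.0, 701.0, 702.0],
                "candidate": [True, True, False],
                "p_value": [0.04, 0.04, 0.001],
                "fdr_q": [0.06, 0.04, 0.001],
            }
        )
        out = select_significant(screen)
        assert out["feature_mz"].tolist() == [701.0]

    def test_planted_effects_recovered_null_features_quiet(self, rng):
        mat = _labelled_matrix(rng, n_features=40, n_pat=4, rois_per=3, px=15,
                               effect_features=range(8), fold=2.0)
        cfg = ScreenConfig(n_per_condition=120, seed=5)
        screen = screen_features(mat, cfg)
        sig = screen["significant"].to_numpy()
        assert sig[:8].sum() >= 7  # >= 80% of planted effects
        assert sig[8:].sum() == 0

    def test_null_matrix_significance_rate_controlled(self, rng):
        hits, total = 0, 0
        for seed in range(10):
            mat = _labelled_matrix(np.random.default_rng(seed), n_features=30)
            screen = screen_features(mat, ScreenConfig(n_per_condition=100, seed=seed))
            hits += screen["significant"].sum()
            total += len(screen)
        assert hits / total <= 0.05 + 0.05
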