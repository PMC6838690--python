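import numpy as np
import pandas as pd
import pytest

from pmflex import mvpa, synthetic_cohort as sc
from pmflex.synthetic_cohort import CLASSES, NeuralDataset


def toy_dataset(n_per_class=40, n_runs=4, snr=2.0, seed=0, n_features=16):
    return sc.simulate_balanced_neural(
        n_per_class=n_per_class, n_runs=n_runs,
        nparams=sc.NeuralSynthParams(n_features=n_features, snr=snr),
        seed=seed)


class TestScreenFeatures:
    def test_informative_features_retained(self):
        rng = np.random.default_rng(0)
        n = 400
        labels = np.array([CLASSES[i % 4] for i in range(n)])
        X = rng.normal(size=(n, 6))
        X[labels == "face", 0] += 3.0       # planted separation
        idx = mvpa.screen_features(X, labels)
        assert 0 in idx

    def test_null_feature_retained_at_alpha_rate(self):
        rng = np.random.default_rng(1)
        labels = np.array([CLASSES[i % 4] for i in range(200)])
        kept = 0
        n_feat, reps = 40, 25
        for r in range(reps):
            X = rng.normal(size=(200, n_feat))
            kept += len(mvpa.screen_features(X, labels))
        rate = kept / (n_feat * reps)
        assert abs(rate - 0.05) < 0.02

    def test_zero_variance_feature_excluded(self):
        rng = np.random.default_rng(2)
        labels = np.array([CLASSES[i % 4] for i in range(100)])
        X = rng.normal(size=(100, 3))
        X[:, 1] = 7.0
        X[labels == "scene", 0] += 5
        X[labels == "og", 2] += 5
        idx = mvpa.screen_features(X, labels)
        assert 1 not in idx and len(idx) <= 3


class TestOvrClassifiers:
    def test_separable_toy_set_is_perfect(self):
        ds = toy_dataset(snr=6.0, seed=3)
        clf = mvpa.train_ovr_classifiers(ds.X, ds.labels)
        ev = clf.evidence(ds.X)
        assert (ev["predicted"] == ds.labels).mean() == 1.0

    def test_huge_penalty_shrinks_evidence_to_base_rate(self):
        ds = toy_dataset(snr=3.0, seed=4)
        clf = mvpa.train_ovr_classifiers(ds.X, ds.labels, penalty=1e8)
        ev = clf.evidence(ds.X)
        for c in CLASSES:
            base_rate = (ds.labels == c).mean()
            assert ev[c].to_numpy() == pytest.approx(base_rate, abs=0.01)

    def test_agrees_with_lightly_regularised_reference(self):
        from sklearn.linear_model import LogisticRegression
        ds = toy_dataset(n_per_class=160, snr=1.0, seed=5, n_features=8)
        clf = mvpa.train_ovr_classifiers(ds.X, ds.labels, penalty=1e-4,
                                         alpha=None)
        Z = (ds.X - clf.mean) / clf.sd
        for c in CLASSES:
            ref = LogisticRegression(C=1e6, max_iter=5000).fit(
                Z, (ds.labels == c).astype(int))
            ours = clf.models[c].coef_.ravel()
            assert np.corrcoef(ours, ref.coef_.ravel())[0, 1] > 0.999

    def test_missing_class_is_a_training_error(self):
        ds = toy_dataset(seed=6)
        keep = ds.labels != "rest"
        with pytest.raises(mvpa.TrainingError, match="rest"):
            mvpa.train_ovr_classifiers(ds.X[keep], ds.labels[keep])


class TestCrossvalidate:
    def test_high_snr_auc_above_95(self):
        res = mvpa.crossvalidate(toy_dataset(snr=4.0, seed=7))
        assert all(a > 0.95 for a in res.auc.values())

    def test_every_sample_scored_exactly_once(self):
        ds = toy_dataset(seed=8)
        res = mvpa.crossvalidate(ds)
        assert len(res.evidence) == len(ds.labels)

    def test_single_run_is_an_error(self):
        ds = toy_dataset(n_runs=1, n_per_class=16, seed=9)
        with pytest.raises(ValueError, match="run"):
            mvpa.crossvalidate(ds)

    def test_evidence_values_need_not_sum_to_one(self):
        res = mvpa.crossvalidate(toy_dataset(snr=2.0, seed=10))
        sums = res.evidence[list(CLASSES)].sum(axis=1)
        assert (np.abs(sums - 1.0) > 0.05).any()

    def test_final_probe_rows_scored_but_not_trained_on(self, small_cohort):
        probes, trials, _ = small_cohort
        ds = sc.simulate_neural(probes, trials, sc.NeuralSynthParams(),
                                seed=11, participants=[3])[3]
        res = mvpa.crossvalidate(ds)
        assert res.evidence["is_final_probe"].sum() > 0

    def test_full_dataset_screening_leaks(self):
        # regression guard: screening outside the folds on null data inflates
        # apparent accuracy relative to in-fold screening
        rng = np.random.default_rng(12)
        n, p = 160, 600
        labels = np.array([CLASSES[i % 4] for i in range(n)])
        run = np.array(["r0"] * (n // 2) + ["r1"] * (n // 2))
        X = rng.normal(size=(n, p))
        ds = NeuralDataset(X=X, labels=labels, run=run,
                           trial=np.full(n, -1),
                           is_localizer=np.zeros(n, bool),
                           is_final_probe=np.zeros(n, bool),
                           lag_trs=0, labels_aligned=True)
        honest = mvpa.crossvalidate(ds).accuracy
        leaky_idx = mvpa.screen_features(X, labels, alpha=0.01)
        ds_leaky = NeuralDataset(X=X[:, leaky_idx], labels=labels, run=run,
                                 trial=np.full(n, -1),
                                 is_localizer=np.zeros(n, bool),
                                 is_final_probe=np.zeros(n, bool),
                                 lag_trs=0, labels_aligned=True)
        leaky = mvpa.crossvalidate(ds_leaky, alpha=None).accuracy
        assert leaky > honest + 0.05


class TestScrambledBaseline:
    def test_mean_near_chance_with_preserved_counts(self):
        ds = toy_dataset(n_per_class=40, n_runs=4, snr=1.0, seed=13)
        out = mvpa.scrambled_baseline(ds, n_perm=30, rng_seed=1, max_folds=2)
        assert abs(out["mean"] - 0.25) < 0.05
        # class counts per run are preserved by the permutation
        rng = np.random.default_rng(0)
        labels = ds.labels.copy()
        for run in np.unique(ds.run):
            m = ds.run == run
            before = pd.Series(labels[m]).value_counts()
            perm = rng.permutation(labels[m])
            after = pd.Series(perm).value_counts()
            pd.testing.assert_series_equal(before.sort_index(),
                                           after.sort_index())

    def test_signal_accuracy_beats_permuted_95th_percentile(self):
        ds = toy_dataset(n_per_class=40, n_runs=4, snr=1.5, seed=14)
        observed = mvpa.crossvalidate(ds).accuracy
        out = mvpa.scrambled_baseline(ds, n_perm=30, rng_seed=2, max_folds=2)
        assert observed > np.percentile(out["accuracies"], 95)


class TestPmIntentionEvidence:
    @staticmethod
    def evidence_frame(rng, n_trials=6, n_probes=8):
        rows = []
        for t in range(n_trials):
            for i in range(n_probes):
                rows.append(dict(
                    face=rng.random(), scene=rng.random(), og=rng.random(),
                    rest=rng.random(), trial=t, run="task1",
                    is_final_probe=(i == n_probes - 1),
                    time_s=2.0 * (t * n_probes + i), label="face",
                    predicted="face"))
        return pd.DataFrame(rows)

    def test_symmetric_evidence_gives_zero_ev(self):
        rng = np.random.default_rng(15)
        ev = self.evidence_frame(rng)
        ev["scene"] = ev["face"]
        trials = pd.DataFrame({"trial": range(6), "pm_type": "face"})
        out = mvpa.pm_intention_evidence(ev, trials)
        assert np.allclose(out["trial_summary"]["mean_ev"], 0.0)

    def test_ev_antisymmetric_under_target_swap(self):
        rng = np.random.default_rng(16)
        ev = self.evidence_frame(rng)
        as_face = mvpa.pm_intention_evidence(
            ev, pd.DataFrame({"trial": range(6), "pm_type": "face"}))
        as_scene = mvpa.pm_intention_evidence(
            ev, pd.DataFrame({"trial": range(6), "pm_type": "scene"}))
        np.testing.assert_allclose(
            as_face["trial_summary"]["mean_ev"].to_numpy(),
            -as_scene["trial_summary"]["mean_ev"].to_numpy())

    def test_constant_evidence_gives_zero_slope(self):
        rng = np.random.default_rng(17)
        ev = self.evidence_frame(rng)
        ev["face"] = 0.9
        ev["scene"] = 0.2
        out = mvpa.pm_intention_evidence(
            ev, pd.DataFrame({"trial": range(6), "pm_type": "face"}))
        assert np.allclose(out["trial_summary"]["ev_slope"], 0.0, atol=1e-12)

    def test_final_probe_excluded_and_non_pm_ignored(self):
        rng = np.random.default_rng(18)
        ev = self.evidence_frame(rng, n_trials=4)
        trials = pd.DataFrame({"trial": range(4),
                               "pm_type": ["face", "scene", "non_pm", "face"]})
        out = mvpa.pm_intention_evidence(ev, trials)
        s = out["trial_summary"]
        assert set(s["trial"]) == {0, 1, 3}
        assert (s["n_samples"] == 7).all()
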