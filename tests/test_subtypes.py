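"""Subtype clustering, survival labeling and the transfer classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import metabosubtype as ms
from conftest import toy_clinical


def _blob_matrix(shift, n_per=30, n_genes=8, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_genes, n_per))
    b = rng.standard_normal((n_genes, n_per)) + shift
    vals = np.hstack([a, b])
    ids = [f"S{i}" for i in range(2 * n_per)]
    m = ms.ExpressionMatrix(
        pd.DataFrame(vals, index=[f"G{i}" for i in range(n_genes)],
                     columns=ids), mode="zscore")
    truth = np.array(["blobA"] * n_per + ["blobB"] * n_per)
    return m, truth


def _labeled_cohort(seed=1):
    """Full path to a survival-labeled assignment on default study conditions."""
    expr, clin, truth = ms.generate_cohort(ms.SyntheticConfig(seed=seed))
    z = ms.zscore_genes(ms.log_transform(ms.median_of_ratios_normalize(expr)[0]))
    z_sig = z.restrict_genes(truth.prognostic_gene_ids)
    a = ms.cluster_subtypes(z_sig, k=2, seed=seed)
    return ms.label_by_survival(a, clin), clin, truth, z_sig


class TestClusterSubtypes:
    def test_separated_blobs_perfectly_recovered(self):
        m, truth = _blob_matrix(shift=6.0)
        a = ms.cluster_subtypes(m, k=2, seed=0)
        assert adjusted_rand_score(truth, a.labels) == 1.0
        assert a.centroids.shape == (8, 2)

    def test_planted_subtypes_recovered(self):
        aris = []
        for seed in range(3):
            labeled, _, truth, _ = _labeled_cohort(seed=40 + seed)
            aris.append(adjusted_rand_score(
                truth.true_subtype.loc[labeled.sample_ids], labeled.labels))
        assert np.mean(aris) >= 0.9

    def test_identical_samples_degenerate(self):
        vals = pd.DataFrame(np.ones((4, 10)),
                            index=[f"G{i}" for i in range(4)],
                            columns=[f"S{i}" for i in range(10)])
        a = ms.cluster_subtypes(ms.ExpressionMatrix(vals, mode="zscore"), k=2)
        assert a.degenerate
        assert a.labels.nunique() == 1

    def test_too_few_distinct_profiles_error(self):
        base = np.array([[1.0], [0.0]])
        vals = pd.DataFrame(np.hstack([base] * 5 + [1 - base] * 5),
                            index=["G0", "G1"],
                            columns=[f"S{i}" for i in range(10)])
        with pytest.raises(ValueError, match="distinct"):
            ms.cluster_subtypes(ms.ExpressionMatrix(vals, mode="zscore"), k=3)

    def test_silhouette_reported_for_k_range(self):
        m, _ = _blob_matrix(shift=4.0)
        a = ms.cluster_subtypes(m, k=2, seed=1, silhouette_range=(2, 6))
        assert set(a.silhouette) == {2, 3, 4, 5, 6}
        assert max(a.silhouette, key=a.silhouette.get) == 2

    def test_fixed_seed_reproducible(self):
        m, _ = _blob_matrix(shift=2.0, seed=5)
        a = ms.cluster_subtypes(m, k=2, seed=9)
        b = ms.cluster_subtypes(m, k=2, seed=9)
        assert (a.labels == b.labels).all()
        assert a.inertia == b.inertia


class TestLabelBySurvival:
    def test_aggressive_cluster_labeled_high_risk(self):
        labeled, _, truth, _ = _labeled_cohort(seed=2)
        agg = truth.true_subtype.loc[labeled.sample_ids] == "aggressive"
        assert labeled.labels[agg].mode()[0] == "M2"
        assert labeled.labels[~agg].mode()[0] == "M1"
        assert labeled.logrank is not None and labeled.logrank.p < 0.05

    def test_idempotent(self):
        labeled, clin, _, _ = _labeled_cohort(seed=3)
        again = ms.label_by_survival(labeled, clin)
        assert (again.labels == labeled.labels).all()

    def test_survival_tie_smaller_cluster_is_high_risk(self):
        # identical survival in both clusters, cluster sizes 4 vs 6
        time = [5, 6, 7, 8] * 2 + [5, 6]
        event = [1] * 10
        clin = toy_clinical(time, event)
        labels = pd.Series(["C0"] * 4 + ["C1"] * 6, index=clin.sample_ids)
        a = ms.SubtypeAssignment(
            labels=labels, k=2,
            centroids=pd.DataFrame({"C0": [0.0], "C1": [1.0]}, index=["g"]),
            inertia=1.0, seed=0)
        with pytest.warns(UserWarning, match="smaller cluster"):
            out = ms.label_by_survival(a, clin)
        assert (out.labels[labels == "C0"] == "M2").all()


class TestClassifier:
    def test_separable_toy_skips_cv_with_training_accuracy(self):
        vals = pd.DataFrame([[-5.0, 5.0], [-4.0, 4.0]],
                            index=["G0", "G1"], columns=["s1", "s2"])
        z = ms.ExpressionMatrix(vals, mode="zscore")
        labels = pd.Series(["M1", "M2"], index=["s1", "s2"])
        model = ms.train_classifier(z, labels, seed=0)
        assert model.cv_skipped
        assert model.cv_accuracy_mean == 1.0

    def test_single_class_error(self):
        vals = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 20)),
                            index=["G0", "G1", "G2"],
                            columns=[f"s{i}" for i in range(20)])
        z = ms.ExpressionMatrix(vals, mode="zscore")
        labels = pd.Series(["M1"] * 20, index=z.sample_ids)
        with pytest.raises(ValueError, match="single class"):
            ms.train_classifier(z, labels)

    def test_cv_accuracy_high_on_shifted_subtypes(self):
        labeled, _, _, z_sig = _labeled_cohort(seed=4)
        model = ms.train_classifier(z_sig, labeled.labels, seed=0,
                                    cv_folds=10, cv_repeats=2)
        assert not model.cv_skipped
        assert model.cv_accuracy_mean >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        # balanced random labels: mean CV accuracy over permutations must sit
        # at the 0.5 chance level (a single labeling can drift ~1/sqrt(n) by
        # chance correlation with the cohort's real cluster axis)
        _, _, _, z_sig = _labeled_cohort(seed=5)
        rng = np.random.default_rng(0)
        n = len(z_sig.sample_ids)
        accs = []
        for _ in range(3):
            permuted = pd.Series(
                rng.permutation(["M1"] * (n // 2) + ["M2"] * (n - n // 2)),
                index=z_sig.sample_ids)
            model = ms.train_classifier(z_sig, permuted, seed=0,
                                        cv_folds=10, cv_repeats=1)
            accs.append(model.cv_accuracy_mean)
        assert abs(np.mean(accs) - 0.5) <= 0.05

    def test_model_json_round_trip_predicts_identically(self):
        labeled, _, _, z_sig = _labeled_cohort(seed=6)
        model = ms.train_classifier(z_sig, labeled.labels, seed=0,
                                    cv_folds=10, cv_repeats=1)
        back = ms.ClassifierModel.from_dict(model.to_dict())
        X = z_sig.values.T
        assert (back.predict(X) == model.predict(X)).all()


@pytest.fixture(scope="module")
def trained():
    labeled, clin, truth, z_sig = _labeled_cohort(seed=7)
    model = ms.train_classifier(z_sig, labeled.labels, seed=0,
                                cv_folds=10, cv_repeats=1)
    return model, labeled, z_sig


class TestClassifyExternal:

    def test_self_consistency(self, trained):
        model, labeled, z_sig = trained
        labels, _ = ms.classify_external(model, z_sig)
        acc = (labels == labeled.labels).mean()
        assert acc >= model.cv_accuracy_mean - 0.05

    def test_sample_permutation_equivariance(self, trained):
        model, _, z_sig = trained
        labels, _ = ms.classify_external(model, z_sig)
        rng = np.random.default_rng(1)
        perm = rng.permutation(z_sig.n_samples)
        z_perm = ms.ExpressionMatrix(z_sig.values.iloc[:, perm].copy(),
                                     mode="zscore")
        labels_perm, _ = ms.classify_external(model, z_perm)
        assert (labels_perm == labels.iloc[perm]).all()

    def test_proportions_sum_to_one(self, trained):
        model, _, z_sig = trained
        _, props = ms.classify_external(model, z_sig)
        assert props.sum() == pytest.approx(1.0)
        assert set(props.index) == set(model.classes)

    def test_missing_genes_listed(self, trained):
        model, _, z_sig = trained
        dropped = ms.ExpressionMatrix(z_sig.values.iloc[1:].copy(),
                                      mode="zscore")
        with pytest.raises(KeyError, match=model.genes[0]):
            ms.classify_external(model, dropped)

    def test_unscaled_input_warns(self, trained):
        model, _, z_sig = trained
        raw = ms.ExpressionMatrix(z_sig.values * 37.0 + 100.0, mode="log")
        with pytest.warns(UserWarning, match="z-scored"):
            ms.classify_external(model, raw)

    def test_transfers_to_replicate_cohort(self, trained):
        model, _, _ = trained
        expr2, _, truth2 = ms.generate_cohort(ms.SyntheticConfig(seed=207))
        z2 = ms.zscore_genes(ms.log_transform(
            ms.median_of_ratios_normalize(expr2)[0]))
        labels2, _ = ms.classify_external(model, z2)
        t2 = truth2.true_subtype.map({"aggressive": "M2", "indolent": "M1"})
        assert (labels2 == t2.loc[labels2.index]).mean() >= 0.9
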