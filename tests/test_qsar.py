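"""Descriptors, filtering, under-sampling, classifiers, and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from cytostab.descriptors import (
    QNA_POWERS,
    compute_descriptors,
    descriptor_matrix,
    qna_atom_values,
)
from cytostab.qsar import (
    DescriptorFilter,
    StabilityClassifier,
    chemspace_overlap,
    compute_metrics,
    cross_validate,
    diversity_undersample,
    evaluate_external,
    multiple_undersample,
    train,
)
from tests.conftest import record


class TestDescriptors:
    @pytest.mark.parametrize("set_tag", ["rdkit2d", "qna"])
    def test_atom_order_invariance(self, set_tag):
        a = compute_descriptors("CC(=O)Nc1ccc(O)cc1", set_tag)
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
        perm = list(reversed(range(mol.GetNumAtoms())))
        b = compute_descriptors(
            Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False), set_tag
        )
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    @pytest.mark.parametrize("set_tag", ["rdkit2d", "qna"])
    def test_benzene_phenol_differ(self, set_tag):
        a = compute_descriptors("c1ccccc1", set_tag)
        b = compute_descriptors("Oc1ccccc1", set_tag)
        assert any(a[k] != b[k] for k in a)

    def test_qna_vector_length_120(self):
        vec = compute_descriptors("CCO", "qna")
        assert len(vec) == 120
        assert len(QNA_POWERS) == 110

    def test_qna_atom_values_finite(self):
        P, Q = qna_atom_values(Chem.MolFromSmiles("O=Cc1ccc(Cl)cn1"))
        assert np.isfinite(P).all() and np.isfinite(Q).all()
        assert len(P) == 9  # one value per heavy atom

    def test_matrix_excludes_failures(self):
        recs = [record("CCO", 10, "A"), record("[SiH3]O[SiH3]", 10, "B")]
        matrix, failed = descriptor_matrix(recs, "qna")
        assert list(matrix.index) == ["A", "B"] or failed  # Si is tabulated; no failure
        matrix, failed = descriptor_matrix([record("CCO", 10, "A")], "rdkit2d")
        assert failed == [] and matrix.shape[0] == 1


class TestFilter:
    def test_duplicate_column_one_survives(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        filt = DescriptorFilter().fit(df)
        assert filt.columns_ == ["a", "c"]

    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        filt = DescriptorFilter().fit(df)
        assert filt.columns_ == ["b"]

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            DescriptorFilter().fit(pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)}))

    def test_independent_columns_survive_and_match_bruteforce(self):
        """Independent random columns are not pruned at r² > 0.9; the greedy
        filter agrees with a brute-force all-pairs r² computation."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.normal(size=(200, 12)), columns=[f"c{i:02d}" for i in range(12)]
        )
        filt = DescriptorFilter().fit(df)
        assert filt.columns_ == list(df.columns)
        # brute-force oracle on a frame with planted correlation
        df["c99"] = df["c00"] * 3.0 + 1e-6 * rng.normal(size=200)
        filt = DescriptorFilter().fit(df)
        cols = sorted(df.columns)
        dropped = []
        kept = []
        for j, cj in enumerate(cols):
            r2s = [np.corrcoef(df[ci], df[cj])[0, 1] ** 2 for ci in kept]
            if any(r > 0.9 for r in r2s):
                dropped.append(cj)
            else:
                kept.append(cj)
        assert filt.columns_ == kept and dropped == ["c99"]

    def test_normalization_toggle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(5, 2, 100), "b": rng.normal(0, 1, 100)})
        z = DescriptorFilter(normalize=True).fit_transform(df)
        assert z["a"].mean() == pytest.approx(0, abs=1e-9)
        assert z["a"].std(ddof=0) == pytest.approx(1, abs=1e-9)
        raw = DescriptorFilter(normalize=False).fit_transform(df)
        assert raw["a"].mean() == pytest.approx(5, abs=1.0)


class TestUndersampling:
    def test_diversity_full_pick_returns_all(self):
        smi = {"a": "CCO", "b": "CCCO", "c": "c1ccccc1"}
        assert diversity_undersample(smi, 3, seed=0) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_distant_compound_always_picked(self, seed):
        """MaxMin on two near-duplicates plus one distant compound, picking
        two, must always include the distant one (brute-force argument)."""
        smi = {
            "dup1": "CCCCCCCCO",
            "dup2": "CCCCCCCCCO",
            "far": "O=S(=O)(N)c1ccc2nsnc2c1",
        }
        picked = diversity_undersample(smi, 2, seed=seed)
        assert "far" in picked

    def test_diversity_deterministic(self):
        smi = {f"m{i}": "C" * (i + 1) + "O" for i in range(12)}
        assert diversity_undersample(smi, 5, seed=9) == diversity_undersample(
            smi, 5, seed=9
        )

    def test_multiple_exact_fit_single_subset(self):
        ids = list("abcdefgh")
        subsets = multiple_undersample(ids, 8, seed=0)
        assert subsets == [sorted(ids)]

    def test_multiple_coverage_small_case(self):
        subsets = multiple_undersample(list(range(10)), 4, seed=1)
        assert len(subsets) >= 3
        assert all(len(s) == 4 for s in subsets)
        assert set().union(*subsets) == set(range(10))

    @given(
        n_major=st.integers(2, 60),
        n_minor=st.integers(1, 30),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_multiple_coverage_property(self, n_major, n_minor, seed):
        ids = [f"id{i}" for i in range(n_major)]
        subsets = multiple_undersample(ids, n_minor, seed)
        assert set().union(*subsets) == set(ids)
        size = min(n_minor, n_major)
        assert all(len(s) == size and len(set(s)) == size for s in subsets)
        assert len(subsets) >= int(np.ceil(n_major / size))


def separable_data(n=120, seed=0, prevalence=0.5):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    x1 = y * 2.0 + rng.normal(0, 0.2, n)
    x2 = -y * 1.5 + rng.normal(0, 0.2, n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return X, y


class TestClassifier:
    @pytest.mark.parametrize("algorithm", ["random_forest", "svm", "naive_bayes_net"])
    def test_separable_training_accuracy(self, algorithm):
        X, y = separable_data()
        clf = StabilityClassifier(algorithm=algorithm, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.98

    def test_multiple_under_member_coverage(self):
        X, y = separable_data(n=140, prevalence=0.3, seed=3)
        clf = StabilityClassifier(
            algorithm="random_forest", sampling="multiple_under", random_state=0
        ).fit(X, y)
        majority = set(np.flatnonzero(y == 0))
        used = set()
        for idx in clf.member_indices_:
            used.update(int(i) for i in idx)
        assert majority <= used
        assert len(clf.members_) >= int(np.ceil((y == 0).sum() / (y == 1).sum()))

    def test_diversity_under_balances(self):
        X, y = separable_data(n=100, prevalence=0.25, seed=4)
        clf = StabilityClassifier(
            algorithm="random_forest", sampling="diversity_under", random_state=0
        ).fit(X, y)
        (idx,) = clf.member_indices_
        yy = y[idx]
        assert (yy == 1).sum() == (yy == 0).sum()

    def test_seed_reproducibility(self):
        X, y = separable_data(n=150, prevalence=0.3, seed=5)
        p1 = (
            StabilityClassifier("random_forest", "multiple_under", random_state=7)
            .fit(X, y)
            .predict_proba(X)
        )
        p2 = (
            StabilityClassifier("random_forest", "multiple_under", random_state=7)
            .fit(X, y)
            .predict_proba(X)
        )
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_errors(self):
        X, _ = separable_data(40)
        with pytest.raises(ValueError):
            StabilityClassifier().fit(X, np.zeros(40))

    def test_sklearn_params_roundtrip(self):
        clf = StabilityClassifier(algorithm="svm", sampling="diversity_under")
        params = clf.get_params()
        clone = StabilityClassifier(**params)
        assert clone.get_params() == params


class TestMetrics:
    def test_hand_confusion_counts(self):
        # TP=3, FN=1, TN=2, FP=2 with the positive class "unstable"
        y_true = ["unstable"] * 4 + ["stable"] * 4
        y_pred = ["unstable"] * 3 + ["stable"] + ["unstable"] * 2 + ["stable"] * 2
        score = [0.9, 0.8, 0.7, 0.4, 0.6, 0.55, 0.3, 0.2]
        m = compute_metrics(y_true, y_pred, score, positive="unstable")
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.50)
        assert m.bacc == pytest.approx(0.625)

    def test_bacc_is_mean_of_recalls(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 500)
        y_pred = rng.integers(0, 2, 500)
        score = rng.random(500)
        m = compute_metrics(y_true, y_pred, score, positive=1)
        assert m.bacc == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 1000)
        score = rng.random(1000)
        m = compute_metrics(y, (score > 0.5).astype(int), score, positive=1)
        assert 0.45 <= m.auc_roc <= 0.55

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        score = rng.random(300)
        base = compute_metrics(y, y, score, positive=1).auc_roc
        warped = compute_metrics(y, y, score**3, positive=1).auc_roc
        assert base == pytest.approx(warped, abs=1e-12)


class TestRecordWrappers:
    def test_cross_validate_near_perfect_on_threshold_rule(self, structural_library):
        """A label derived noiselessly from a single monotone descriptor rule
        (polar surface area above the median) is recovered almost perfectly."""
        from dataclasses import replace
        from rdkit.Chem import rdMolDescriptors

        records, _, _ = structural_library
        subset = records[:150]
        tpsa = [rdMolDescriptors.CalcTPSA(Chem.MolFromSmiles(r.smiles_std)) for r in subset]
        cut = float(np.median(tpsa))
        relabeled = [
            replace(r, stability_class="unstable" if t > cut else "stable")
            for r, t in zip(subset, tpsa)
        ]
        m = cross_validate(relabeled, "random_forest", "none", "rdkit2d", folds=3, seed=0)
        assert m.bacc >= 0.95 and m.auc_roc >= 0.99

    def test_external_leakage_guard(self, structural_library):
        records, _, _ = structural_library
        model = train(records[:200], "random_forest", "none", "rdkit2d", seed=0)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_external(model, records[:10])

    def test_external_on_disjoint_set(self, structural_library):
        records, _, _ = structural_library
        model = train(records[:400], "random_forest", "none", "rdkit2d", seed=0)
        m = evaluate_external(model, records[400:600])
        assert 0.0 <= m.bacc <= 1.0
        assert m.bacc == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)


class TestChemspace:
    def test_identical_sets_fully_overlap(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(4000, 6)))
        rep = chemspace_overlap(df, df)
        assert rep["fraction_in_bbox"] == 1.0
        assert rep["fraction_in_ellipse_95"] == pytest.approx(0.95, abs=0.015)

    def test_shifted_set_does_not_overlap(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(300, 4)))
        rep = chemspace_overlap(df, df + 10.0 * df.std())
        assert rep["fraction_in_bbox"] <= 0.02
        assert rep["fraction_in_ellipse_95"] <= 0.02

    def test_half_in_half_out(self):
        rng = np.random.default_rng(5)
        train_m = pd.DataFrame(rng.normal(size=(500, 3)))
        inside = rng.normal(size=(250, 3)) * 0.3
        outside = rng.normal(size=(250, 3)) + 25.0
        ext = pd.DataFrame(np.vstack([inside, outside]))
        rep = chemspace_overlap(train_m, ext)
        assert rep["fraction_in_bbox"] == pytest.approx(0.5, abs=0.05)

    def test_too_few_rows_errors(self):
        df = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            chemspace_overlap(df, df)
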