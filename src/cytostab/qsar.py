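"""Imbalanced-class QSAR classifiers of cytosolic stability.

The training sets are skewed toward the stable class (roughly 25% unstable in
the human-like setting, 10% in the mouse-like one), so the classifiers support
two majority-class under-sampling modes in addition to training on the raw
set:

* ``diversity_under`` — pick a minority-sized, maximally diverse majority
  subset (MaxMin on circular fingerprints when structures are available,
  Euclidean MaxMin in descriptor space otherwise) and train one model.
* ``multiple_under`` — repeatedly draw minority-sized random majority subsets
  until every majority instance has been used at least once, train one model
  per subset, and average the member probabilities.

`StabilityClassifier` is an sklearn-compatible estimator (fit/predict/
predict_proba, ``get_params``/``set_params``) over a numeric descriptor
matrix; `DescriptorFilter` is the companion transformer (z-normalization,
constant-column removal, r² > 0.9 correlation pruning). `train`,
`cross_validate` and `evaluate_external` are record-level wrappers that
compose the two. Sensitivity is the recall of the unstable class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker
from scipy.stats import chi2
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import recall_score, roc_auc_score
from sklearn.naive_bayes import CategoricalNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from cytostab.descriptors import descriptor_matrix

ALGORITHMS = ("random_forest", "svm", "naive_bayes_net")
SAMPLINGS = ("none", "diversity_under", "multiple_under")

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class EvalMetrics:
    """AUC-ROC, balanced accuracy, sensitivity (unstable recall), specificity."""

    auc_roc: float
    bacc: float
    sensitivity: float
    specificity: float


def compute_metrics(y_true, y_pred, y_score, positive) -> EvalMetrics:
    """Metrics with the unstable class as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_mask = y_true == positive
    sens = recall_score(pos_mask, np.asarray(y_pred) == positive)
    spec = recall_score(~pos_mask, np.asarray(y_pred) != positive)
    auc = roc_auc_score(pos_mask, y_score)
    return EvalMetrics(
        auc_roc=float(auc),
        bacc=float((sens + spec) / 2),
        sensitivity=float(sens),
        specificity=float(spec),
    )


# ---------------------------------------------------------------------------
# Descriptor filtering


class DescriptorFilter(TransformerMixin, BaseEstimator):
    """Z-normalize, drop constant columns, prune correlated pairs (r² > 0.9).

    Columns are examined in stable (alphabetical for DataFrames, positional
    otherwise) order; of a correlated pair the later column is removed, so
    the result is deterministic. ``normalize=False`` reproduces the handling
    of descriptor sets that are left unnormalized by design (the QNA panel).
    """

    def __init__(self, normalize: bool = True, r2_threshold: float = 0.9):
        self.normalize = normalize
        self.r2_threshold = r2_threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to filter descriptors")
        cols = sorted(X.columns, key=str)
        values = X[cols].to_numpy(dtype=float)
        std = values.std(axis=0, ddof=0)
        nonconstant = std > 0
        if not nonconstant.any():
            raise ValueError("all descriptor columns are constant")
        cols = [c for c, keep in zip(cols, nonconstant) if keep]
        values = values[:, nonconstant]
        corr = np.corrcoef(values, rowvar=False)
        if corr.ndim == 0:
            corr = np.array([[1.0]])
        r2 = corr**2
        kept: list[int] = []
        for j in range(len(cols)):
            if any(r2[i, j] > self.r2_threshold for i in kept):
                continue
            kept.append(j)
        self.columns_ = [cols[j] for j in kept]
        sub = values[:, kept]
        self.mean_ = sub.mean(axis=0)
        self.scale_ = sub.std(axis=0, ddof=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        out = X[self.columns_].astype(float)
        if self.normalize:
            out = (out - self.mean_) / self.scale_
        return out


def filter_descriptors(matrix: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """One-shot functional form of :class:`DescriptorFilter`."""
    return DescriptorFilter(normalize=normalize).fit_transform(matrix)


# ---------------------------------------------------------------------------
# Under-sampling


def diversity_undersample(
    smiles_by_id: Mapping[str, str], n_pick: int, seed: int
) -> list[str]:
    """MaxMin-diverse subset of the majority class, on Morgan fingerprints.

    Deterministic per seed. Raises if more picks are requested than
    compounds are available.
    """
    ids = sorted(smiles_by_id)
    if n_pick > len(ids):
        raise ValueError(f"cannot pick {n_pick} from {len(ids)} compounds")
    if n_pick == len(ids):
        return ids
    fps = [_MORGAN.GetFingerprint(Chem.MolFromSmiles(smiles_by_id[i])) for i in ids]
    picker = MaxMinPicker()
    picks = picker.LazyBitVectorPick(fps, len(fps), n_pick, seed=seed)
    return [ids[i] for i in sorted(picks)]


def _maxmin_euclidean(X: np.ndarray, n_pick: int, seed: int) -> list[int]:
    """Brute-force MaxMin picking in descriptor space (estimator fallback)."""
    n = X.shape[0]
    if n_pick >= n:
        return list(range(n))
    rng = np.random.default_rng(seed)
    picked = [int(rng.integers(n))]
    d = np.linalg.norm(X - X[picked[0]], axis=1)
    while len(picked) < n_pick:
        nxt = int(np.argmax(d))
        picked.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    return sorted(picked)


def multiple_undersample(
    majority_ids: Sequence, n_minority: int, seed: int
) -> list[list]:
    """Minority-sized random majority subsets covering every majority id.

    Subsets are sampled without replacement within a subset; their union is
    the whole majority class; the number of subsets is
    ceil(|majority| / n_minority). Deterministic per seed.
    """
    if n_minority < 1:
        raise ValueError("n_minority must be >= 1")
    ids = sorted(majority_ids, key=str)
    if n_minority >= len(ids):
        return [list(ids)]
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    subsets = []
    for start in range(0, len(perm), n_minority):
        chunk = perm[start : start + n_minority]
        if len(chunk) < n_minority:
            pool = [i for i in ids if i not in chunk]
            extra = rng.choice(len(pool), size=n_minority - len(chunk), replace=False)
            chunk = chunk + [pool[j] for j in sorted(extra)]
        subsets.append(sorted(chunk, key=str))
    return subsets


# ---------------------------------------------------------------------------
# Estimator


def _base_estimator(algorithm: str, random_state, n_bins: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=random_state)
    if algorithm == "svm":
        # RBF SVC with sigmoid-calibrated probabilities (Platt scaling).
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    CalibratedClassifierCV(
                        SVC(kernel="rbf", C=1.0, gamma="scale"),
                        method="sigmoid",
                        cv=5,
                        ensemble=False,
                    ),
                ),
            ]
        )
    if algorithm == "naive_bayes_net":
        # Discrete Bayes-network family: quantile-binned descriptors feeding
        # a categorical naive Bayes.
        return Pipeline(
            [
                (
                    "bins",
                    KBinsDiscretizer(
                        n_bins=n_bins,
                        encode="ordinal",
                        strategy="quantile",
                        quantile_method="averaged_inverted_cdf",
                    ),
                ),
                ("nb", CategoricalNB(min_categories=n_bins)),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class StabilityClassifier(ClassifierMixin, BaseEstimator):
    """Binary stability classifier with majority-class under-sampling built in.

    Parameters
    ----------
    algorithm:
        ``random_forest``, ``svm`` (RBF kernel, Platt-scaled probabilities)
        or ``naive_bayes_net`` (quantile-discretized categorical naive Bayes).
    sampling:
        ``none``, ``diversity_under`` or ``multiple_under``. Under-sampling
        happens inside :meth:`fit`, so wrapping this estimator in sklearn
        cross-validation automatically confines it to training folds.
    random_state:
        Seeds the sampler and every member model.

    The positive class is the lexicographically larger label (``1`` for 0/1
    labels, ``"unstable"`` for stable/unstable), matching the convention that
    sensitivity is the unstable-class recall.

    Fitted attributes: ``classes_``, ``members_`` (list of fitted base
    estimators), ``member_indices_`` (training row indices per member).
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        sampling: str = "none",
        random_state: int | None = None,
        n_bins: int = 10,
    ):
        self.algorithm = algorithm
        self.sampling = sampling
        self.random_state = random_state
        self.n_bins = n_bins

    def fit(self, X, y, smiles: Sequence[str] | None = None):
        X = np.asarray(pd.DataFrame(X), dtype=float)
        y = np.asarray(y)
        if self.sampling not in SAMPLINGS:
            raise ValueError(f"unknown sampling {self.sampling!r}")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("StabilityClassifier requires exactly 2 classes")
        self.n_features_in_ = X.shape[1]
        counts = {c: int((y == c).sum()) for c in self.classes_}
        minority = min(self.classes_, key=lambda c: (counts[c], str(c)))
        majority = [c for c in self.classes_ if c != minority][0]
        maj_idx = np.flatnonzero(y == majority)
        min_idx = np.flatnonzero(y == minority)
        seed = 0 if self.random_state is None else int(self.random_state)

        if self.sampling == "none":
            member_indices = [np.arange(len(y))]
        elif self.sampling == "diversity_under":
            if smiles is not None:
                smi_by_id = {str(i): smiles[i] for i in maj_idx}
                picked = [int(i) for i in diversity_undersample(
                    smi_by_id, len(min_idx), seed
                )]
            else:
                local = _maxmin_euclidean(X[maj_idx], len(min_idx), seed)
                picked = [int(maj_idx[j]) for j in local]
            member_indices = [np.sort(np.concatenate([min_idx, picked]).astype(int))]
        else:  # multiple_under
            subsets = multiple_undersample(
                [int(i) for i in maj_idx], len(min_idx), seed
            )
            member_indices = [
                np.sort(np.concatenate([min_idx, np.asarray(s, dtype=int)]))
                for s in subsets
            ]

        self.members_ = []
        self.member_indices_ = member_indices
        for m, idx in enumerate(member_indices):
            base = _base_estimator(self.algorithm, seed + m, self.n_bins)
            base.fit(X[idx], y[idx])
            self.members_.append(base)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "members_")
        X = np.asarray(pd.DataFrame(X), dtype=float)
        acc = np.zeros((X.shape[0], 2))
        for member in self.members_:
            proba = member.predict_proba(X)
            # align member class order with self.classes_
            order = [list(member.classes_).index(c) for c in self.classes_]
            acc += proba[:, order]
        return acc / len(self.members_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Mean positive-class (unstable) probability across members."""
        return self.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Record-level wrappers


@dataclass
class QsarModel:
    """A fitted classifier bundled with its descriptor pipeline and metadata."""

    algorithm: str
    sampling: str
    descriptor_set: str
    seed: int
    filter: DescriptorFilter
    classifier: StabilityClassifier
    train_ids: tuple[str, ...]

    def is_fitted(self) -> bool:
        return hasattr(self.classifier, "members_")

    def _features(self, records: Sequence) -> pd.DataFrame:
        matrix, failed = descriptor_matrix(records, self.descriptor_set)
        if failed:
            raise ValueError(f"descriptor failure for {len(failed)} records")
        return self.filter.transform(matrix)

    def predict_proba_records(self, records: Sequence) -> np.ndarray:
        """Positive-class (unstable) probability per record."""
        return self.classifier.decision_scores(self._features(records))

    def predict_records(self, records: Sequence) -> list[str]:
        return list(self.classifier.predict(self._features(records)))


def _labels(records: Sequence) -> np.ndarray:
    return np.asarray([r.stability_class for r in records])


def train(
    records: Sequence,
    algorithm: str = "random_forest",
    sampling: str = "none",
    set_tag: str = "rdkit2d",
    seed: int = 0,
) -> QsarModel:
    """Fit a stability classifier on deduplicated records."""
    y = _labels(records)
    if len(np.unique(y)) < 2:
        raise ValueError("training records must contain both classes")
    matrix, failed = descriptor_matrix(records, set_tag)
    keep = [r for r in records if r.inchikey not in set(failed)]
    y = _labels(keep)
    filt = DescriptorFilter(normalize=(set_tag != "qna")).fit(matrix)
    X = filt.transform(matrix)
    clf = StabilityClassifier(algorithm=algorithm, sampling=sampling, random_state=seed)
    clf.fit(X, y, smiles=[r.smiles_std for r in keep])
    return QsarModel(
        algorithm=algorithm,
        sampling=sampling,
        descriptor_set=set_tag,
        seed=seed,
        filter=filt,
        classifier=clf,
        train_ids=tuple(r.inchikey for r in keep),
    )


def cross_validate(
    records: Sequence,
    algorithm: str = "random_forest",
    sampling: str = "none",
    set_tag: str = "rdkit2d",
    folds: int = 5,
    seed: int = 0,
) -> EvalMetrics:
    """Stratified k-fold cross-validation with fold-internal under-sampling.

    The descriptor filter and any under-sampling are fit inside each
    training fold only; predictions are pooled over folds before computing
    metrics, with sensitivity the unstable-class recall.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    matrix, failed = descriptor_matrix(records, set_tag)
    keep = [r for r in records if r.inchikey not in set(failed)]
    y = _labels(keep)
    smiles = np.asarray([r.smiles_std for r in keep])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(keep), dtype=object)
    y_score = np.zeros(len(keep))
    for train_idx, test_idx in skf.split(matrix, y):
        filt = DescriptorFilter(normalize=(set_tag != "qna")).fit(
            matrix.iloc[train_idx]
        )
        X_tr = filt.transform(matrix.iloc[train_idx])
        X_te = filt.transform(matrix.iloc[test_idx])
        clf = StabilityClassifier(
            algorithm=algorithm, sampling=sampling, random_state=seed
        )
        clf.fit(X_tr, y[train_idx], smiles=list(smiles[train_idx]))
        y_pred[test_idx] = clf.predict(X_te)
        y_score[test_idx] = clf.decision_scores(X_te)
    return compute_metrics(y, y_pred, y_score, positive="unstable")


def evaluate_external(model: QsarModel, records: Sequence) -> EvalMetrics:
    """Evaluate a fitted model on an untouched external set.

    Raises if any external record shares an identity key with the training
    set (leakage guard).
    """
    overlap = set(model.train_ids) & {r.inchikey for r in records}
    if overlap:
        raise ValueError(
            f"{len(overlap)} external records overlap the training set"
        )
    y = _labels(records)
    X = model._features(records)
    y_pred = model.classifier.predict(X)
    y_score = model.classifier.decision_scores(X)
    return compute_metrics(y, y_pred, y_score, positive="unstable")


def chemspace_overlap(
    train_matrix: pd.DataFrame, external_matrix: pd.DataFrame
) -> dict[str, float]:
    """Chemical-space overlap of an external set with the training set.

    Projects both filtered descriptor matrices onto the training set's first
    two principal axes and reports the fraction of external points inside
    the training points' axis-aligned bounding box and inside the 95%
    Mahalanobis ellipse of the training scores.
    """
    if train_matrix.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    cols = list(train_matrix.columns)
    ext = pd.DataFrame(external_matrix)[cols]
    pca = PCA(n_components=2, random_state=0)
    train_scores = pca.fit_transform(train_matrix.to_numpy(dtype=float))
    ext_scores = pca.transform(ext.to_numpy(dtype=float))
    lo = train_scores.min(axis=0)
    hi = train_scores.max(axis=0)
    in_box = np.all((ext_scores >= lo) & (ext_scores <= hi), axis=1)
    mean = train_scores.mean(axis=0)
    cov = np.cov(train_scores, rowvar=False)
    inv = np.linalg.pinv(cov)
    d2 = np.einsum("ij,jk,ik->i", ext_scores - mean, inv, ext_scores - mean)
    in_ellipse = d2 <= chi2.ppf(0.95, df=2)
    return {
        "fraction_in_bbox": float(np.mean(in_box)),
        "fraction_in_ellipse_95": float(np.mean(in_ellipse)),
        "explained_variance_ratio": float(pca.explained_variance_ratio_.sum()),
    }
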