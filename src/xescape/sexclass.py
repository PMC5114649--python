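"""Random-Forest sex classification from X-linked TSS expression.

Female samples carry an inactive X whose escapee loci remain transcribed
(≈2x female signal) and an XIST-like TSS expressed only from the Xi, so
expression at X-non-PAR TSSs separates the sexes. The classifier exposes
out-of-bag (OOB) error, balanced accuracy, OOB class votes (used to flag
mislabeled/outlier samples) and the tree-proximity matrix, embedded with
classical multidimensional scaling for inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

try:  # bootstrap reconstruction for OOB-restricted proximities
    from sklearn.ensemble._forest import (
        _generate_sample_indices,
        _get_n_samples_bootstrap,
    )
except ImportError:  # pragma: no cover - older/newer sklearn layout
    _generate_sample_indices = None


def balanced_accuracy(confusion) -> float:
    """Mean of per-class recalls from a square confusion-count table.

    Rows are true classes, columns predictions. Raises ``ValueError`` if a
    true class has no observations.
    """
    table = np.asarray(confusion, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(table < 0):
        raise ValueError("confusion counts must be non-negative")
    row_sums = table.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("balanced accuracy undefined: a true class has zero count")
    return float(np.mean(np.diag(table) / row_sums))


class SexClassifier(BaseEstimator, ClassifierMixin):
    """Random-Forest sex classifier over X-non-PAR TSS features.

    Parameters
    ----------
    n_trees : int, default 500
        Forest size; splits consider sqrt(p) features (forest defaults).
    random_state : int or None
        Seed for the bootstrap and split sampling.
    oob_proximity : bool, default True
        Restrict the proximity estimate of a sample pair to trees where
        both samples are out of bag; falls back to all trees for pairs
        never jointly OOB (or when bootstrap bookkeeping is unavailable).

    Attributes (after ``fit``)
    --------------------------
    classes_ : array of class labels.
    oob_votes_ : (n_samples, n_classes) OOB class-vote fractions.
    oob_error_ : OOB misclassification rate.
    balanced_accuracy_ : mean per-class recall of the OOB predictions.
    proximity_ : (n, n) symmetric matrix, unit diagonal; the fraction of
        trees in which two samples share a terminal node.
    feature_ids_ : feature (tss_id) names seen during fit.
    """

    def __init__(self, n_trees: int = 500, random_state=None, oob_proximity: bool = True):
        self.n_trees = n_trees
        self.random_state = random_state
        self.oob_proximity = oob_proximity

    def fit(self, X, y):
        """Fit on a sample x feature matrix (DataFrame keeps feature ids)."""
        if isinstance(X, pd.DataFrame):
            self.feature_ids_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_ids_ = list(range(X.shape[1]))
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training requires at least two classes")
        if counts.min() < 2:
            raise ValueError("training requires >=2 samples per class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        votes = self.forest_.oob_decision_function_
        # samples never OOB (tiny forests) get a uniform vote placeholder
        nan_rows = ~np.isfinite(votes).all(axis=1)
        votes = votes.copy()
        votes[nan_rows] = 1.0 / len(self.classes_)
        self.oob_votes_ = votes
        oob_pred = self.classes_[np.argmax(votes, axis=1)]
        valid = ~nan_rows
        self.oob_error_ = float(np.mean(oob_pred[valid] != y[valid]))
        confusion = np.zeros((len(self.classes_),) * 2)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for yt, yp in zip(y[valid], oob_pred[valid]):
            confusion[class_index[yt], class_index[yp]] += 1
        self.balanced_accuracy_ = balanced_accuracy(confusion)
        self.y_ = y
        self.proximity_ = self._proximity(X)
        return self

    def _proximity(self, X) -> np.ndarray:
        n = X.shape[0]
        leaves = self.forest_.apply(X)  # (n, n_trees)
        same_all = np.zeros((n, n))
        same_oob = np.zeros((n, n))
        both_oob = np.zeros((n, n))
        use_oob = self.oob_proximity and _generate_sample_indices is not None
        if use_oob:
            try:  # signature grew a sample_weight argument in newer sklearn
                n_boot = _get_n_samples_bootstrap(n, self.forest_.max_samples, None)
                sample_idx = lambda rs: _generate_sample_indices(rs, n, n_boot, None)
            except TypeError:
                n_boot = _get_n_samples_bootstrap(n, self.forest_.max_samples)
                sample_idx = lambda rs: _generate_sample_indices(rs, n, n_boot)
        for t, tree in enumerate(self.forest_.estimators_):
            same = leaves[:, t][:, None] == leaves[:, t][None, :]
            same_all += same
            if use_oob:
                inbag = np.bincount(sample_idx(tree.random_state), minlength=n)
                oob = inbag == 0
                pair_oob = oob[:, None] & oob[None, :]
                both_oob += pair_oob
                same_oob += same & pair_oob
        all_frac = same_all / len(self.forest_.estimators_)
        if not use_oob:
            prox = all_frac
        else:
            with np.errstate(invalid="ignore"):
                prox = np.where(both_oob > 0, same_oob / np.maximum(both_oob, 1), all_frac)
        np.fill_diagonal(prox, 1.0)
        return (prox + prox.T) / 2

    def predict(self, X):
        """Majority-vote sex per sample; DataFrame columns are checked
        against the training feature ids."""
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_ids_:
                raise ValueError("feature ids do not match the training features")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([], dtype=self.classes_.dtype)
        if X.shape[1] != len(self.feature_ids_):
            raise ValueError("feature count does not match the training features")
        return self.forest_.predict(X)


def train_sex_classifier(expr, tss_records, samples, n_trees: int = 500, seed=None,
                         x_chrom: str = "chrX", feature_subset=None) -> SexClassifier:
    """Train on X-non-PAR TSS features of sex-labelled samples.

    ``feature_subset`` restricts features further (e.g. XIST-only TSSs).
    Samples labelled ``unknown`` are excluded from training.
    """
    x_ids = [r.tss_id for r in tss_records if r.is_x_nonpar(x_chrom)]
    if feature_subset is not None:
        keep = set(feature_subset)
        x_ids = [t for t in x_ids if t in keep]
    labelled = [s for s in samples if s.sex_label in ("male", "female")]
    sub = expr.subset_tss(x_ids).subset_samples([s.sample_id for s in labelled])
    X = sub.to_frame().T  # samples x features
    y = np.array([s.sex_label for s in labelled])
    clf = SexClassifier(n_trees=n_trees, random_state=seed).fit(X, y)
    clf.sample_ids_ = [s.sample_id for s in labelled]
    return clf


def detect_outliers(clf: SexClassifier, sample_ids=None) -> list:
    """Samples whose strict OOB majority vote disagrees with the label.

    Returns ``(sample_id, labeled_sex, predicted_sex, vote_margin)`` tuples
    sorted by decreasing margin (majority fraction − label-class fraction).
    Exact vote ties are not outliers.
    """
    check_is_fitted(clf, "forest_")
    if sample_ids is None:
        sample_ids = getattr(clf, "sample_ids_", list(range(len(clf.y_))))
    class_index = {c: i for i, c in enumerate(clf.classes_)}
    out = []
    for i, sid in enumerate(sample_ids):
        votes = clf.oob_votes_[i]
        top = int(np.argmax(votes))
        label_i = class_index[clf.y_[i]]
        if top == label_i or np.isclose(votes[top], votes[label_i]):
            continue
        out.append((sid, clf.y_[i], clf.classes_[top],
                    float(votes[top] - votes[label_i])))
    return sorted(out, key=lambda rec: -rec[3])


def embed_proximity(proximity, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of the dissimilarity 1 − proximity.

    Double-centers the squared dissimilarities and returns the leading
    ``dims`` principal coordinates (centered at the origin; dimensions
    with non-positive eigenvalues come back as zeros).
    """
    P = np.asarray(proximity, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("proximity must be square")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("proximity must be symmetric")
    D2 = (1.0 - P) ** 2
    n = P.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
    return coords
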