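"""Single-trial hit-vs-miss classification on the SPD manifold.

Trials are summarized by regularized spatial covariance matrices
(Schaefer-Strimmer shrinkage toward the diagonal), which live on the
manifold of symmetric positive-definite matrices equipped with the
affine-invariant metric

    delta(A, B) = || Log(A^{-1/2} B A^{-1/2}) ||_F .

Two classifiers are provided: minimum distance to the mean (MDM), which
assigns each trial to the class of the nearest Frechet centroid, and a
tangent-space classifier (TSC) that maps covariances to tangent vectors at
the Riemannian mean of the training set and feeds them to an L2-regularized
logistic regression. The majority class is undersampled with Tomek links
before fitting; performance is estimated by stratified 5-fold
cross-validation with balanced accuracy (the mean of the class recalls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.linalg import eigh as gen_eigh
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .preprocess import EpochSet


@dataclass
class SPDSet:
    """Per-trial SPD covariance matrices with labels and shrinkage weights."""

    mats: np.ndarray            # trials x n x n
    labels: np.ndarray
    lambdas: np.ndarray         # shrinkage intensity per trial

    def __post_init__(self):
        self.mats = np.asarray(self.mats, float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.lambdas = np.asarray(self.lambdas, float)
        if self.mats.ndim != 3 or self.mats.shape[1] != self.mats.shape[2]:
            raise ValueError("mats must be trials x n x n")

    def __len__(self):
        return self.mats.shape[0]

    def select(self, idx) -> "SPDSet":
        return SPDSet(self.mats[idx], self.labels[idx], self.lambdas[idx])


@dataclass
class CVResult:
    """Per-fold accuracies of one subject's cross-validation."""

    classes: list
    fold_class_recall: np.ndarray   # folds x classes
    fold_balanced: np.ndarray       # folds
    n_folds: int = 5

    @property
    def balanced_accuracy(self) -> float:
        return float(self.fold_balanced.mean())

    @property
    def balanced_sem(self) -> float:
        f = self.fold_balanced
        return float(f.std(ddof=1) / np.sqrt(len(f))) if len(f) > 1 else 0.0


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def shrinkage_covariance(epoch: np.ndarray) -> tuple:
    """Schaefer-Strimmer shrinkage covariance of one epoch.

    ``epoch`` is channels x samples. Returns ``(C, lam)`` with
    ``C = (1 - lam) S + lam diag(S)``, where ``S`` is the unbiased sample
    covariance over time and ``lam`` the analytic optimum

        lam* = sum_{i != j} Var(s_ij) / sum_{i != j} s_ij^2 ,

    clipped to [0, 1]. Var(s_ij) is the usual n / (n-1)^3 estimate of the
    sampling variance of the covariance entries.
    """
    x = np.asarray(epoch, float)
    n_ch, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    s = xc @ xc.T / (n - 1)
    # w_kij = xc_ik xc_jk ; Var(s_ij) = n/(n-1)^3 * sum_k (w_kij - wbar_ij)^2
    w = np.einsum("ik,jk->ijk", xc, xc)
    wbar = w.mean(axis=2)
    var_s = n / (n - 1) ** 3 * ((w - wbar[:, :, None]) ** 2).sum(axis=2)
    off = ~np.eye(n_ch, dtype=bool)
    denom = (s[off] ** 2).sum()
    lam = 1.0 if denom <= 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    c = (1.0 - lam) * s + lam * np.diag(np.diag(s))
    if np.linalg.eigvalsh(c).min() <= 0:
        raise ValueError("shrunk covariance is not positive definite "
                         "(constant channel with lam = 0?)")
    return c, lam


def covariances_from_epochs(epochs: EpochSet,
                            channels: Optional[Sequence[str]] = None,
                            prototype_augment: bool = False) -> SPDSet:
    """Shrinkage covariance per trial, optionally on a channel subset.

    With ``prototype_augment``, each class's mean waveform is stacked as
    extra rows before the covariance (super-trial descriptor); disabled by
    default.
    """
    eps = epochs if channels is None else epochs.pick_channels(list(channels))
    data = eps.data
    if prototype_augment:
        proto = class_prototypes(data, eps.labels)
        data = np.stack([np.vstack([tr, proto]) for tr in data])
    mats, lams = [], []
    for tr in data:
        c, lam = shrinkage_covariance(tr)
        mats.append(c)
        lams.append(lam)
    return SPDSet(np.stack(mats), eps.labels.copy(), np.array(lams))


def class_prototypes(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Stacked per-class mean waveforms (classes in sorted label order)."""
    return np.concatenate([data[labels == c].mean(axis=0)
                           for c in sorted(set(labels.tolist()))], axis=0)


def _augmented_spd(data: np.ndarray, labels: np.ndarray, proto: np.ndarray
                   ) -> SPDSet:
    mats, lams = [], []
    for tr in data:
        c, lam = shrinkage_covariance(np.vstack([tr, proto]))
        mats.append(c)
        lams.append(lam)
    return SPDSet(np.stack(mats), labels.copy(), np.array(lams))


def _augmented_spd_loo(data: np.ndarray, labels: np.ndarray) -> SPDSet:
    """Training-side augmentation with leave-one-out prototypes.

    A trial must not contribute to its own class prototype: the shared noise
    would give training trials a spurious trial-prototype correlation that
    test trials cannot have, biasing the fitted model below chance on null
    data.
    """
    classes = sorted(set(labels.tolist()))
    sums = {c: data[labels == c].sum(axis=0) for c in classes}
    counts = {c: int((labels == c).sum()) for c in classes}
    mats, lams = [], []
    for tr, lab in zip(data, labels):
        rows = []
        for c in classes:
            if c == lab and counts[c] > 1:
                rows.append((sums[c] - tr) / (counts[c] - 1))
            else:
                rows.append(sums[c] / counts[c])
        c_, lam = shrinkage_covariance(np.vstack([tr, *rows]))
        mats.append(c_)
        lams.append(lam)
    return SPDSet(np.stack(mats), labels.copy(), np.array(lams))


# ---------------------------------------------------------------------------
# affine-invariant geometry
# ---------------------------------------------------------------------------

def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def spd_logm(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(_sym(a))
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return v @ np.diag(np.log(w)) @ v.T


def spd_expm(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(_sym(a))
    return v @ np.diag(np.exp(w)) @ v.T


def spd_power(a: np.ndarray, p: float) -> np.ndarray:
    w, v = np.linalg.eigh(_sym(a))
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return v @ np.diag(w ** p) @ v.T


def riemann_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant geodesic distance: sqrt(sum log^2 eig(A^{-1} B))."""
    w = gen_eigh(b, a, eigvals_only=True)
    if w.min() <= 0:
        raise ValueError("matrices must be positive definite")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def riemann_mean(mats: np.ndarray, tol: float = 1e-10, max_iter: int = 100
                 ) -> np.ndarray:
    """Frechet mean under the affine-invariant metric.

    Fixed-point iteration: project the set to the tangent space at the
    current estimate, average, and map back; stops when the Frobenius norm
    of the tangent-space update falls below ``tol``.
    """
    mats = np.asarray(mats, float)
    if mats.ndim != 3 or len(mats) == 0:
        raise ValueError("need a non-empty stack of SPD matrices")
    if len(mats) == 1:
        return mats[0].copy()
    m = mats.mean(axis=0)
    for _ in range(max_iter):
        m_isqrt = spd_power(m, -0.5)
        m_sqrt = spd_power(m, 0.5)
        logs = np.mean([spd_logm(m_isqrt @ c @ m_isqrt.T) for c in mats], axis=0)
        m = m_sqrt @ spd_expm(logs) @ m_sqrt.T
        m = _sym(m)
        if np.linalg.norm(logs, "fro") < tol:
            return m
    raise RuntimeError(
        f"Riemannian mean did not converge in {max_iter} iterations "
        f"(last update norm {np.linalg.norm(logs, 'fro'):.2e})")


_SQRT2 = np.sqrt(2.0)


def tangent_project(mats: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Tangent vectors at ``reference``: vec_upper(Log(R^-1/2 C R^-1/2)).

    Off-diagonal entries are weighted by sqrt(2) so that the Euclidean norm
    of a vector equals the Riemannian distance of its matrix to the
    reference. Vectors have length n(n+1)/2.
    """
    mats = np.asarray(mats, float)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    r_isqrt = spd_power(reference, -0.5)
    n = mats.shape[1]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, _SQRT2)
    out = np.empty((len(mats), n * (n + 1) // 2))
    for k, c in enumerate(mats):
        l = spd_logm(r_isqrt @ c @ r_isqrt.T)
        out[k] = l[iu] * weights
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Tomek-link undersampling
# ---------------------------------------------------------------------------

def tomek_links(vectors: np.ndarray, labels: np.ndarray,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Balance two classes by removing Tomek links, then random undersampling.

    A Tomek link is a mutual-nearest-neighbour pair with opposite labels;
    the majority-class member of each link is removed. Link removal repeats
    until the classes balance or no links remain; any residual imbalance is
    resolved by seeded random undersampling of the majority class. Returns
    the retained indices (sorted).
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("Tomek balancing needs exactly two classes")
    alive = np.arange(len(labels))
    while True:
        counts = {c: int((labels[alive] == c).sum()) for c in classes}
        if min(counts.values()) == 0:
            raise ValueError("a class became empty during balancing")
        if counts[classes[0]] == counts[classes[1]]:
            return np.sort(alive)
        maj = max(classes, key=lambda c: counts[c])
        v = vectors[alive]
        d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argmin(d2, axis=1)
        links = set()
        for i in range(len(alive)):
            j = nn[i]
            if nn[j] == i and labels[alive[i]] != labels[alive[j]]:
                links.add(tuple(sorted((i, j))))
        if not links:
            break
        drop_local = {i if labels[alive[i]] == maj else j for i, j in links}
        excess = counts[maj] - min(counts.values())
        if len(drop_local) > excess:  # do not overshoot balance
            drop_local = set(sorted(drop_local)[:excess])
        alive = np.delete(alive, sorted(drop_local))
    counts = {c: int((labels[alive] == c).sum()) for c in classes}
    maj = max(classes, key=lambda c: counts[c])
    excess = counts[maj] - min(counts.values())
    if excess > 0:
        maj_local = np.flatnonzero(labels[alive] == maj)
        drop = rng.choice(maj_local, size=excess, replace=False)
        alive = np.delete(alive, np.sort(drop))
    return np.sort(alive)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def mdm_fit(train: SPDSet) -> Dict[str, np.ndarray]:
    """One Riemannian centroid per class."""
    classes = sorted(set(train.labels.tolist()))
    if any((train.labels == c).sum() < 1 for c in classes):
        raise ValueError("every class needs at least one training matrix")
    return {c: riemann_mean(train.mats[train.labels == c]) for c in classes}


def mdm_predict(centroids: Dict[str, np.ndarray], test: SPDSet) -> np.ndarray:
    classes = sorted(centroids)
    dists = np.array([[riemann_distance(c, centroids[k]) for k in classes]
                      for c in test.mats])
    return np.array(classes, dtype=object)[np.argmin(dists, axis=1)]


def mdm_fit_predict(train: SPDSet, test: SPDSet) -> np.ndarray:
    """Minimum-distance-to-mean classification (ties -> lower class index)."""
    return mdm_predict(mdm_fit(train), test)


@dataclass
class TSCModel:
    reference: np.ndarray
    scaler: StandardScaler
    clf: LogisticRegression
    classes: list


def tsc_fit(train: SPDSet, c_inv: float = 1.0, max_iter: int = 1000) -> TSCModel:
    """Tangent-space classifier: reference and scaler from training data only."""
    classes = sorted(set(train.labels.tolist()))
    if len(classes) < 2:
        raise ValueError("tangent-space classifier needs two classes")
    reference = riemann_mean(train.mats)
    vecs = tangent_project(train.mats, reference)
    scaler = StandardScaler().fit(vecs)
    clf = LogisticRegression(C=c_inv, max_iter=max_iter)
    clf.fit(scaler.transform(vecs), train.labels.astype(str))
    return TSCModel(reference, scaler, clf, classes)


def tsc_predict(model: TSCModel, test: SPDSet) -> tuple:
    vecs = model.scaler.transform(tangent_project(test.mats, model.reference))
    pred = model.clf.predict(vecs).astype(object)
    proba = model.clf.predict_proba(vecs)
    return pred, proba


def tsc_fit_predict(train: SPDSet, test: SPDSet) -> tuple:
    """Tangent-space logistic regression -> (labels, class probabilities)."""
    model = tsc_fit(train)
    return tsc_predict(model, test)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _class_recalls(y_true: np.ndarray, y_pred: np.ndarray, classes: list
                   ) -> np.ndarray:
    rec = []
    for c in classes:
        sel = y_true == c
        rec.append(float((y_pred[sel] == c).mean()) if sel.any() else np.nan)
    return np.array(rec)


def crossvalidate(spd: SPDSet, classifier: str = "tsc", folds: int = 5,
                  seed: Optional[int] = None, balance: str = "tomek"
                  ) -> CVResult:
    """Stratified k-fold CV with within-fold Tomek balancing.

    All training-fold-derived quantities (tangent reference, scaler, Tomek
    removals, centroids) are computed on the training trials only.
    ``balance='pre'`` instead applies Tomek balancing once, before the
    split; ``balance='none'`` disables it.
    """
    if classifier not in ("mdm", "tsc"):
        raise ValueError("classifier must be 'mdm' or 'tsc'")
    classes = sorted(set(spd.labels.tolist()))
    counts = {c: int((spd.labels == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(f"need >= {folds} trials per class, got {counts}")
    rng = np.random.default_rng(seed)
    if balance == "pre":
        ref = riemann_mean(spd.mats)
        keep = tomek_links(tangent_project(spd.mats, ref), spd.labels, rng)
        spd = spd.select(keep)

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    y = spd.labels.astype(str)
    fold_recall, fold_bal = [], []
    for tr_idx, te_idx in skf.split(np.zeros(len(spd)), y):
        train, test = spd.select(tr_idx), spd.select(te_idx)
        if balance == "tomek":
            ref = riemann_mean(train.mats)
            keep = tomek_links(tangent_project(train.mats, ref),
                               train.labels, rng)
            train = train.select(keep)
        if classifier == "mdm":
            pred = mdm_fit_predict(train, test)
        else:
            pred, _ = tsc_fit_predict(train, test)
        rec = _class_recalls(test.labels, pred, classes)
        fold_recall.append(rec)
        fold_bal.append(np.nanmean(rec))
    return CVResult(classes, np.array(fold_recall), np.array(fold_bal), folds)


def crossvalidate_epochs(epochs: EpochSet, classifier: str = "tsc",
                         channels: Optional[Sequence[str]] = None,
                         folds: int = 5, seed: Optional[int] = None,
                         balance: str = "tomek",
                         prototype_augment: bool = False) -> CVResult:
    """Covariance estimation + cross-validation from an epoch set.

    With ``prototype_augment``, the class-mean waveforms stacked under each
    trial are recomputed inside every training fold and applied unchanged to
    that fold's test trials, so no test-label information leaks into the
    descriptors.
    """
    if not prototype_augment:
        spd = covariances_from_epochs(epochs, channels)
        return crossvalidate(spd, classifier, folds, seed, balance)

    eps = epochs if channels is None else epochs.pick_channels(list(channels))
    if classifier not in ("mdm", "tsc"):
        raise ValueError("classifier must be 'mdm' or 'tsc'")
    classes = sorted(set(eps.labels.tolist()))
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    y = eps.labels.astype(str)
    fold_recall, fold_bal = [], []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        proto = class_prototypes(eps.data[tr_idx], eps.labels[tr_idx])
        train = _augmented_spd_loo(eps.data[tr_idx], eps.labels[tr_idx])
        test = _augmented_spd(eps.data[te_idx], eps.labels[te_idx], proto)
        if balance == "tomek":
            ref = riemann_mean(train.mats)
            keep = tomek_links(tangent_project(train.mats, ref),
                               train.labels, rng)
            train = train.select(keep)
        if classifier == "mdm":
            pred = mdm_fit_predict(train, test)
        else:
            pred, _ = tsc_fit_predict(train, test)
        rec = _class_recalls(test.labels, pred, classes)
        fold_recall.append(rec)
        fold_bal.append(np.nanmean(rec))
    return CVResult(classes, np.array(fold_recall), np.array(fold_bal), folds)
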