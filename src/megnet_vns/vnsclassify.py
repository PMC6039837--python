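"""Three-group classification of VNS outcome from network topology.

A Gaussian naive Bayes classifier (class-conditionally independent Gaussian
features) separates non-responders (NR), responders (R) and healthy controls
(C) using modularity and transitivity — CPL is excluded because it does not
differ between the patient groups.  Four feature menus are supported: the
two measures in theta, alpha or beta, or all six.

Validation is stratified 10-fold cross-validation.  Because controls
outnumber each patient group, every repetition draws a balanced control
subsample (14 of the available controls) before cross-validating; the
confusion matrix and all metrics are averaged over (by default) 1000 such
repetitions.  Per-class metrics are one-vs-rest: sensitivity TP/actual,
specificity TN/actual-negatives, PPV TP/predicted-positive, accuracy
(TP+TN)/total, and the Mann–Whitney AUC of the class posterior; weighted
averages weight classes by their size (9, 14, 14 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "CLASSES",
    "GaussianNBModel",
    "ClassifierReport",
    "fit_gnb",
    "predict_gnb",
    "stratified_kfold_predict",
    "balanced_repeated_cv",
    "metrics_from_confusion",
    "auc_one_vs_rest",
    "select_features",
]

#: Reporting order of the three classes.
CLASSES = ("NR", "R", "C")

METRICS = ("sensitivity", "specificity", "ppv", "accuracy", "auc")


@dataclass
class GaussianNBModel:
    """Per-class priors and per-feature Gaussian parameters.

    ``classes`` are kept in lexicographic order; posterior ties resolve to
    the lexicographically first class.
    """

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # n_classes x n_features
    variances: np.ndarray  # n_classes x n_features, floored

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive after flooring")


def fit_gnb(features: np.ndarray, labels: np.ndarray) -> GaussianNBModel:
    """Fit class priors and Gaussian parameters; variances are floored at
    ``1e-9 * max feature variance`` to keep densities finite."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes = np.unique(y)  # sorted lexicographically
    if classes.size < 2:
        raise ValueError("need at least 2 classes in training data")
    floor = 1e-9 * float(np.max(x.var(axis=0), initial=0.0))
    floor = max(floor, 1e-12)
    priors, means, variances = [], [], []
    for c in classes:
        xc = x[y == c]
        priors.append(xc.shape[0] / x.shape[0])
        means.append(xc.mean(axis=0))
        variances.append(np.maximum(xc.var(axis=0), floor))
    return GaussianNBModel(
        classes=classes,
        priors=np.asarray(priors),
        means=np.asarray(means),
        variances=np.asarray(variances),
    )


def predict_gnb(
    model: GaussianNBModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities and argmax labels for new samples.

    Returns ``(posteriors, labels)``; posterior rows sum to 1 and ties pick
    the lexicographically first class.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    # log p(x|c) + log prior, feature-independent Gaussians
    log_post = np.log(model.priors)[None, :] - 0.5 * np.sum(
        np.log(2.0 * np.pi * model.variances)[None, :, :]
        + (x[:, None, :] - model.means[None, :, :]) ** 2
        / model.variances[None, :, :],
        axis=2,
    )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(post, axis=1)]
    return post, labels


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; class proportions preserved up to integer counts.

    Classes smaller than ``k`` simply miss some test folds (every sample is
    still tested exactly once, and every training set keeps all classes for
    k >= 3 and class sizes >= 2).
    """
    n = labels.size
    if k > n:
        raise ValueError("k exceeds the number of samples")
    folds = np.empty(n, dtype=int)
    start = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        folds[idx] = (start + np.arange(idx.size)) % k
        start = (start + idx.size) % k
    return folds


def stratified_kfold_predict(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-fold posteriors and predicted labels under stratified k-fold CV.

    Every sample is predicted exactly once by a model that never saw it.
    Returns ``(posteriors, predicted_labels, model_classes)`` with posterior
    columns in lexicographic class order.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    classes = np.unique(y)
    post = np.zeros((y.size, classes.size))
    pred = np.empty(y.size, dtype=y.dtype)
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        model = fit_gnb(x[~test], y[~test])
        if model.classes.size != classes.size:
            raise RuntimeError("a class vanished from a training fold")
        p, lab = predict_gnb(model, x[test])
        post[test] = p
        pred[test] = lab
    return post, pred, classes


def metrics_from_confusion(
    confusion: np.ndarray,
    classes: tuple[str, ...] = CLASSES,
) -> pd.DataFrame:
    """One-vs-rest metrics from an actual x predicted confusion matrix.

    Rows must be the actual classes in ``classes`` order.  PPV is NaN (not 0)
    for a class that was never predicted.  The last row is the class-size
    weighted average (NaNs excluded with weights renormalised).
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (len(classes), len(classes)) or np.any(c < 0):
        raise ValueError("confusion must be square, non-negative, matching classes")
    total = c.sum()
    rows = {}
    for i, name in enumerate(classes):
        tp = c[i, i]
        actual = c[i, :].sum()
        predicted = c[:, i].sum()
        tn = total - actual - predicted + tp
        rows[name] = {
            "sensitivity": tp / actual if actual else np.nan,
            "specificity": tn / (total - actual) if total - actual else np.nan,
            "ppv": tp / predicted if predicted else np.nan,
            "accuracy": (tp + tn) / total,
        }
    df = pd.DataFrame(rows).T
    weights = c.sum(axis=1)
    weighted = {}
    for col in df.columns:
        v = df[col].to_numpy()
        ok = np.isfinite(v)
        weighted[col] = float(np.average(v[ok], weights=weights[ok])) if ok.any() else np.nan
    df.loc["weighted"] = weighted
    return df


def auc_one_vs_rest(
    posteriors: np.ndarray,
    labels: np.ndarray,
    classes: np.ndarray,
) -> dict[str, float]:
    """Per-class AUC of the class posterior as a class-vs-rest score
    (Mann–Whitney formulation; ties count one half)."""
    post = np.asarray(posteriors, dtype=float)
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    y = np.asarray(labels)
    out = {}
    for i, c in enumerate(classes):
        pos = y == c
        if pos.sum() == 0 or pos.sum() == y.size:
            raise ValueError(f"class {c!r} has no members (or no negatives)")
        out[str(c)] = float(roc_auc_score(pos, post[:, i]))
    return out


@dataclass
class ClassifierReport:
    """Averaged confusion matrix and metrics over the subsampling repetitions."""

    classes: tuple[str, ...]
    class_sizes: np.ndarray
    confusion: np.ndarray  # real-valued average, rows = actual
    per_class: pd.DataFrame  # metrics incl. 'weighted' row
    overall_accuracy: float
    n_repetitions: int
    feature_names: list[str] = field(default_factory=list)


def balanced_repeated_cv(
    features: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 1000,
    n_controls_drawn: int = 14,
    k: int = 10,
    seed: int | None = None,
    permute_labels: bool = False,
    feature_names: list[str] | None = None,
) -> ClassifierReport:
    """Repeated balanced-control cross-validation.

    Per repetition: draw ``n_controls_drawn`` controls without replacement,
    pool them with all patients, run stratified k-fold CV, and accumulate the
    confusion matrix, one-vs-rest metrics and AUC.  Reported values are
    arithmetic means over repetitions.  ``permute_labels=True`` re-shuffles
    the subset's labels independently in every repetition — the chance-level
    null for the whole procedure.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    ctrl_idx = np.flatnonzero(y == "C")
    other_idx = np.flatnonzero(y != "C")
    if ctrl_idx.size < n_controls_drawn:
        raise ValueError(
            f"only {ctrl_idx.size} controls available; cannot draw {n_controls_drawn}"
        )
    rng = np.random.default_rng(seed)

    conf_sum = np.zeros((3, 3))
    metric_sums = {m: np.zeros(4) for m in ("sensitivity", "specificity", "ppv", "accuracy")}
    metric_counts = {m: np.zeros(4) for m in metric_sums}
    auc_sum = np.zeros(3)
    acc_sum = 0.0

    for _ in range(n_reps):
        chosen = rng.choice(ctrl_idx, size=n_controls_drawn, replace=False)
        idx = np.concatenate([other_idx, chosen])
        xs, ys = x[idx], y[idx]
        if permute_labels:
            ys = rng.permutation(ys)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        post, pred, model_classes = stratified_kfold_predict(xs, ys, k=k, seed=fold_seed)

        conf = np.zeros((3, 3))
        for i, actual in enumerate(CLASSES):
            for j, predicted in enumerate(CLASSES):
                conf[i, j] = np.sum((ys == actual) & (pred == predicted))
        conf_sum += conf
        acc_sum += np.trace(conf) / conf.sum()

        mdf = metrics_from_confusion(conf)  # rows: NR, R, C, weighted
        for m in metric_sums:
            v = mdf[m].to_numpy()
            ok = np.isfinite(v)
            metric_sums[m][ok] += v[ok]
            metric_counts[m][ok] += 1

        aucs = auc_one_vs_rest(post, ys, model_classes)
        auc_sum += np.array([aucs[c] for c in CLASSES])

    confusion = conf_sum / n_reps
    per_class = pd.DataFrame(index=list(CLASSES) + ["weighted"], columns=list(METRICS), dtype=float)
    for m in metric_sums:
        with np.errstate(invalid="ignore"):
            vals = metric_sums[m] / metric_counts[m]
        per_class[m] = vals
    auc_mean = auc_sum / n_reps
    per_class.loc[list(CLASSES), "auc"] = auc_mean
    sizes = confusion.sum(axis=1)
    per_class.loc["weighted", "auc"] = float(np.average(auc_mean, weights=sizes))

    return ClassifierReport(
        classes=CLASSES,
        class_sizes=sizes,
        confusion=confusion,
        per_class=per_class,
        overall_accuracy=acc_sum / n_reps,
        n_repetitions=n_reps,
        feature_names=feature_names or [],
    )


def select_features(
    features_wide: pd.DataFrame,
    bands: str = "all",
    measures: tuple[str, ...] = ("transitivity", "modularity"),
) -> tuple[np.ndarray, list[str]]:
    """Pick the classifier's feature columns from a wide per-subject table.

    ``features_wide`` has one row per subject and columns named
    ``<measure>_<band>``.  ``bands`` is one of theta/alpha/beta/all.
    """
    band_list = ["theta", "alpha", "beta"] if bands == "all" else [bands]
    cols = [f"{m}_{b}" for b in band_list for m in measures]
    missing = [c for c in cols if c not in features_wide.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    return features_wide[cols].to_numpy(dtype=float), cols
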