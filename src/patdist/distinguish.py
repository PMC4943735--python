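"""Pairwise distinguishability of labeled pattern classes.

Two pattern classes are called distinguishable when a linear
maximum-margin classifier, trained on visual signatures, predicts
held-out samples well above chance. The statistic is the leave-one-out
(LOO) success rate: each sample in turn is held out, the classifier is
retrained on the rest, and the held-out prediction is compared to the
true label. Significance comes from a label-permutation test: the full
LOO pipeline is recomputed under random relabelings, giving the null
distribution of the success rate when labels carry no visual
information. The P-value uses the add-one estimator
``(1 + #{null >= observed}) / (n_permutations + 1)`` so it is never zero
and is valid (conservative) at any permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .imaging import ValidationError


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear max-margin (hinge loss) classifier settings.

    C is the soft-margin constant (the study used a linear SVM with
    C = 1); ties at decision value exactly 0 go to the lexicographically
    first class name so predictions are deterministic.

    ``standardize`` z-scores every signature coordinate on the training
    fold before the margin is fit (the same transform is applied to the
    held-out sample). Gaussian max-similarity features concentrate near
    1 with a data-dependent spread, and a fixed-C soft margin is only
    meaningful relative to the feature scale; per-fold standardization
    pins that scale without leaking test information.
    """

    C: float = 1.0
    tol: float = 1e-6
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be positive")


@dataclass
class LOOResult:
    success_rate: float
    predictions: list[str]
    n: int
    n_support: int = 0


@dataclass
class PermutationResult:
    observed_rate: float
    null_rates: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    n: int = 0


@dataclass
class UnknownAssignment:
    predictions: list[str]
    fractions: dict[str, float]
    group_separability: dict[str, PermutationResult] = field(default_factory=dict)


def _as_matrix_labels(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if X.ndim != 2:
        raise ValidationError("signature matrix must be 2-D (n samples x T)")
    if len(labels) != X.shape[0]:
        raise ValidationError("label count does not match signature rows")
    if not np.isfinite(X).all():
        raise ValidationError("signature matrix has missing/non-finite values")
    return X, labels


def _check_two_class(labels) -> np.ndarray:
    classes = np.unique(labels.astype(str))
    if len(classes) != 2:
        raise ValidationError(
            f"exactly 2 classes required, got {len(classes)}; "
            "use pairwise_distinguishability for multi-class tables"
        )
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValidationError(
            "each class needs >= 2 samples (an LOO fold would otherwise "
            "train on a single class)"
        )
    return classes


def _fit_svm(X, y01, cfg: ClassifierConfig):
    """Fit the margin on (optionally per-fold-standardized) features.

    Standardization is done inline with numpy rather than a sklearn
    pipeline: the permutation test refits this classifier hundreds of
    thousands of times on tiny folds, where pipeline overhead dominates.
    """
    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        X = (X - mu) / sd
    else:
        mu = sd = None
    svc = SVC(kernel="linear", C=cfg.C, tol=cfg.tol)
    svc.fit(X, y01)
    return svc, mu, sd


def _predict(clf, classes: np.ndarray, X) -> np.ndarray:
    # decision > 0 -> second class; exactly 0 -> lexicographically first
    svc, mu, sd = clf
    if mu is not None:
        X = (X - mu) / sd
    d = svc.decision_function(X)
    return classes[(d > 0).astype(int)]


def loo_success_rate(X, labels, cfg: ClassifierConfig | None = None) -> LOOResult:
    """Leave-one-out success rate of the linear max-margin classifier.

    Deterministic given the data and config; the rate times n is exactly
    the number of correct held-out predictions.
    """
    cfg = cfg or ClassifierConfig()
    X, labels = _as_matrix_labels(X, labels)
    labels = labels.astype(str)
    n = X.shape[0]
    if n < 4:
        raise ValidationError("need n >= 4 for a two-class LOO analysis")
    classes = _check_two_class(labels)
    y01 = (labels == classes[1]).astype(int)
    preds = []
    n_support = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        clf = _fit_svm(X[mask], y01[mask], cfg)
        preds.append(_predict(clf, classes, X[i : i + 1])[0])
        n_support = max(n_support, int(clf[0].n_support_.sum()))
    correct = sum(p == t for p, t in zip(preds, labels))
    return LOOResult(success_rate=correct / n, predictions=preds, n=n,
                     n_support=n_support)


def permutation_p_value(
    X,
    labels,
    cfg: ClassifierConfig | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the LOO success rate.

    Every permutation shuffles the label vector uniformly and recomputes
    the entire LOO loop, the same pipeline that produced the observed
    statistic. Reproducible given the seed.
    """
    if n_permutations < 99:
        raise ValidationError("n_permutations < 99 gives too coarse a p-value grid")
    cfg = cfg or ClassifierConfig()
    X, labels = _as_matrix_labels(X, labels)
    labels = labels.astype(str)
    observed = loo_success_rate(X, labels, cfg).success_rate
    rng = np.random.default_rng(seed)
    null_rates = np.empty(n_permutations)
    for j in range(n_permutations):
        permuted = rng.permutation(labels)
        null_rates[j] = loo_success_rate(X, permuted, cfg).success_rate
    p = (1 + int((null_rates >= observed).sum())) / (n_permutations + 1)
    return PermutationResult(
        observed_rate=observed,
        null_rates=null_rates,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        n=X.shape[0],
    )


def holm_flags(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm's step-down (sequential Bonferroni) significance flags."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break  # once one fails, all larger p fail
    return flags.tolist()


@dataclass
class PairResult:
    pair: tuple[str, str]
    result: PermutationResult
    n_per_class: dict[str, int]
    holm_significant: bool | None = None


def pairwise_distinguishability(
    X,
    labels,
    pairs: list[tuple[str, str]] | None = None,
    cfg: ClassifierConfig | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    holm_alpha: float | None = None,
) -> list[PairResult]:
    """LOO rate + permutation P for every (or each requested) class pair.

    Mirrors a pairwise distinguishability table: one row per unordered
    pair, optionally annotated with Holm sequential-Bonferroni
    significance flags across the whole grid.
    """
    X, labels = _as_matrix_labels(X, labels)
    labels = labels.astype(str)
    classes = sorted(np.unique(labels))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if pairs is None:
        pairs = list(combinations(classes, 2))
    else:
        for a, b in pairs:
            if a not in classes or b not in classes:
                raise ValidationError(f"requested pair ({a}, {b}) has a missing class")
    results = []
    for k, (a, b) in enumerate(pairs):
        mask = (labels == a) | (labels == b)
        res = permutation_p_value(
            X[mask], labels[mask], cfg, n_permutations=n_permutations,
            seed=seed + k,
        )
        results.append(
            PairResult(
                pair=(a, b),
                result=res,
                n_per_class={a: int((labels == a).sum()), b: int((labels == b).sum())},
            )
        )
    if holm_alpha is not None:
        flags = holm_flags([r.result.p_value for r in results], alpha=holm_alpha)
        for r, f in zip(results, flags):
            r.holm_significant = f
    return results


def assign_unknowns(
    X_train,
    train_labels,
    X_unknown,
    cfg: ClassifierConfig | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> UnknownAssignment:
    """Assign unlabeled samples to one of two trained classes.

    The classifier is trained once on all training samples; each unknown
    is assigned, and per-class assignment fractions are reported. Group
    separability then asks whether the unknowns *as a group* can be told
    apart from each training class, by running the LOO permutation test
    on (unknowns vs that class).
    """
    cfg = cfg or ClassifierConfig()
    X_train, train_labels = _as_matrix_labels(X_train, train_labels)
    train_labels = train_labels.astype(str)
    classes = _check_two_class(train_labels)
    X_unknown = np.asarray(X_unknown, dtype=float)
    if X_unknown.ndim != 2 or X_unknown.shape[1] != X_train.shape[1]:
        raise ValidationError(
            "unknowns must share the training signature dimensionality "
            f"(got {X_unknown.shape} vs T={X_train.shape[1]})"
        )
    y01 = (train_labels == classes[1]).astype(int)
    clf = _fit_svm(X_train, y01, cfg)
    preds = _predict(clf, classes, X_unknown).tolist()
    m = len(preds)
    fractions = {c: preds.count(c) / m for c in classes}
    separability = {}
    for k, c in enumerate(classes):
        mask = train_labels == c
        Xg = np.vstack([X_unknown, X_train[mask]])
        yg = np.array(["_unknown"] * m + [c] * int(mask.sum()))
        separability[c] = permutation_p_value(
            Xg, yg, cfg, n_permutations=n_permutations, seed=seed + k
        )
    return UnknownAssignment(
        predictions=preds, fractions=fractions, group_separability=separability
    )
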