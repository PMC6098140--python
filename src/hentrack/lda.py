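"""Linear Discriminant Analysis with stepwise variable selection.

Equal-covariance Gaussian classifier over the six transition-count
variables, with hen identity as the class.  Posterior class probabilities
come from class-conditional Gaussian likelihoods sharing the pooled
within-class covariance, times class priors.  Variable selection follows
a backward-elimination / re-entry loop on a scalar discriminatory-power
criterion: the trace of (within-scatter)^-1 (between-scatter), expressed
as a proportion of the full six-variable model's value.  A variable is
dropped when removing it loses less than the threshold (default 5%) of
that proportion, and re-entered when adding it back gains at least the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import GroupingReport, HenScore
from .features import VARIABLES, SummaryFeatures, feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "LDAModel",
    "Posterior",
    "fit_lda",
    "predict",
    "predict_class",
    "stepwise_select",
    "evaluate_lda",
]


@dataclass
class LDAModel:
    """Fitted equal-covariance discriminant model on selected variables."""

    classes: list[str]
    priors: np.ndarray
    class_means: np.ndarray  # (n_classes, n_selected)
    pooled_cov: np.ndarray  # (n_selected, n_selected)
    pooled_cov_inv: np.ndarray
    eigvals: np.ndarray  # discriminant eigenvalues, descending
    eigvecs: np.ndarray  # columns = discriminant directions
    selected_vars: tuple[str, ...]
    ridge_used: float = 0.0

    @property
    def n_discriminants(self) -> int:
        return min(len(self.classes) - 1, len(self.selected_vars))


@dataclass
class Posterior:
    """Per-class posterior probabilities for one hen-day."""

    label: str
    classes: list[str]
    probabilities: np.ndarray

    @property
    def argmax_class(self) -> str:
        return self.classes[int(np.argmax(self.probabilities))]


def _as_matrix(features) -> np.ndarray:
    """Accept a list of SummaryFeatures or a ready (n, 6) matrix."""
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(VARIABLES):
            raise ValueError(f"feature matrix must be (n, {len(VARIABLES)})")
        return X
    return feature_matrix(features)[0]


def _var_indices(vars: tuple[str, ...] | list[str]) -> list[int]:
    idx = []
    for v in vars:
        if v not in VARIABLES:
            raise ValueError(f"unknown variable {v!r}; expected one of {VARIABLES}")
        idx.append(VARIABLES.index(v))
    return idx


def _scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Within- and between-class scatter plus class means and class list."""
    classes = sorted(set(y.tolist()))
    p = X.shape[1]
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = np.zeros((len(classes), p))
    for k, c in enumerate(classes):
        Xc = X[y == c]
        means[k] = Xc.mean(axis=0)
        d = Xc - means[k]
        W += d.T @ d
        m = means[k] - grand
        B += Xc.shape[0] * np.outer(m, m)
    return W, B, means, classes


def fit_lda(
    features: list[SummaryFeatures],
    labels: list[str],
    vars: tuple[str, ...] | list[str] = VARIABLES,
    ridge: float | None = None,
) -> LDAModel:
    """Fit the discriminant model on the selected variables.

    ``labels`` are hen identities, one per feature row.  The pooled
    within-class covariance uses n - n_classes degrees of freedom.  When
    it is near-singular a ridge eps*I (eps = 1e-8 x mean diagonal) is
    added and logged; pass ``ridge=0`` to forbid the fallback.
    """
    X_full = _as_matrix(features)
    y = np.asarray(labels)
    if X_full.shape[0] != y.size:
        raise ValueError("features and labels must align")
    idx = _var_indices(vars)
    X = X_full[:, idx]
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = np.array([(y == c).sum() for c in classes])
    if np.any(counts < 2):
        small = [c for c, n in zip(classes, counts) if n < 2]
        raise ValueError(f"classes with fewer than two observations: {small}")

    W, B, means, classes = _scatter(X, y)
    n, p = X.shape
    pooled = W / (n - len(classes))

    eps = 0.0
    cond_limit = 1e12
    if ridge is None:
        if np.linalg.cond(pooled) > cond_limit:
            eps = 1e-8 * float(np.mean(np.diag(pooled)))
            logger.warning("pooled covariance near-singular; ridge %.3g added", eps)
    elif ridge > 0:
        eps = ridge
    pooled_r = pooled + eps * np.eye(p)
    if np.linalg.cond(pooled_r) > 1e15:
        if ridge == 0:
            raise np.linalg.LinAlgError(
                "pooled covariance singular and ridge fallback disabled"
            )
        eps = max(eps, 1e-8 * float(np.mean(np.diag(pooled))) + 1e-12)
        pooled_r = pooled + eps * np.eye(p)
    pooled_inv = np.linalg.inv(pooled_r)

    # discriminant directions: eigenproblem of W^-1 B via the symmetric
    # whitened form for numerical stability
    L = np.linalg.cholesky(pooled_r * (n - len(classes)))
    Bw = np.linalg.solve(L, np.linalg.solve(L, B).T).T
    Bw = (Bw + Bw.T) / 2
    evals, evecs = np.linalg.eigh(Bw)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = np.linalg.solve(L.T, evecs[:, order])

    priors = counts / counts.sum()
    return LDAModel(
        classes=classes,
        priors=priors,
        class_means=means,
        pooled_cov=pooled_r,
        pooled_cov_inv=pooled_inv,
        eigvals=evals,
        eigvecs=evecs,
        selected_vars=tuple(VARIABLES[i] for i in idx),
        ridge_used=eps,
    )


def predict(model: LDAModel, feature: SummaryFeatures) -> Posterior:
    """Posterior class probabilities for one hen-day."""
    idx = _var_indices(model.selected_vars)
    x = (
        np.asarray(feature, dtype=float)[idx]
        if isinstance(feature, np.ndarray)
        else feature.as_vector()[idx]
    )
    d = model.class_means - x[None, :]
    mahal = np.einsum("ki,ij,kj->k", d, model.pooled_cov_inv, d)
    log_post = np.log(model.priors) - 0.5 * mahal
    log_post -= logsumexp(log_post)
    label = feature.label if hasattr(feature, "label") else ""
    return Posterior(label=label, classes=model.classes, probabilities=np.exp(log_post))


def predict_class(model: LDAModel, feature: SummaryFeatures) -> str:
    return predict(model, feature).argmax_class


# --------------------------------------------------------------------------
# stepwise selection


def _criterion(X: np.ndarray, y: np.ndarray, idx: list[int]) -> float:
    """Discriminatory power of a variable subset: tr(W^+ B)."""
    if not idx:
        return 0.0
    W, B, _, _ = _scatter(X[:, idx], y)
    return float(np.trace(np.linalg.pinv(W, rcond=1e-10) @ B))


def stepwise_select(
    features: list[SummaryFeatures],
    labels: list[str],
    threshold: float = 0.05,
) -> tuple[str, ...]:
    """Backward-elimination / re-entry selection over the six variables.

    The criterion is the subset's discriminatory power as a proportion of
    the full model's.  Each pass drops the variable whose removal loses
    the least, while that loss is below ``threshold``; dropped variables
    re-enter when adding one back gains at least ``threshold``.  Ties
    break toward the earlier variable in (z1..z5, total) order; at least
    one variable is always retained.  Deterministic.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    full = _criterion(X, y, list(range(len(VARIABLES))))
    if full <= 0:
        return VARIABLES
    current = list(range(len(VARIABLES)))
    dropped: list[int] = []

    def prop(idx: list[int]) -> float:
        return _criterion(X, y, sorted(idx)) / full

    changed = True
    while changed:
        changed = False
        # backward: drop the cheapest removable variable
        while len(current) > 1:
            cur_p = prop(current)
            losses = []
            for i in current:
                without = [j for j in current if j != i]
                losses.append((max(cur_p - prop(without), 0.0), i))
            loss, victim = min(losses)  # tie -> smaller variable index
            if loss < threshold and threshold > 0:
                current.remove(victim)
                dropped.append(victim)
                changed = True
            else:
                break
        # re-entry: add back the most valuable dropped variable
        while dropped:
            cur_p = prop(current)
            gains = [(prop(current + [i]) - cur_p, -i) for i in dropped]
            gain, neg_i = max(gains)  # tie -> smaller variable index
            i = -neg_i
            if gain >= threshold and threshold > 0:
                dropped.remove(i)
                current.append(i)
                changed = True
            else:
                break
    return tuple(VARIABLES[i] for i in sorted(current))


# --------------------------------------------------------------------------
# evaluation


def evaluate_lda(
    features: list[SummaryFeatures],
    labels: list[str] | None = None,
    vars: tuple[str, ...] | None = None,
    threshold: float = 0.05,
    leave_one_out: bool = False,
) -> tuple[LDAModel, GroupingReport]:
    """Fit (with stepwise selection unless ``vars`` given) and score.

    Default evaluation is resubstitution: the final model predicts the
    same hen-days it was fitted on.  ``leave_one_out=True`` refits without
    each hen-day before predicting it.
    """
    if labels is None:
        labels = [f.hen_id for f in features]
    if vars is None:
        vars = stepwise_select(features, labels, threshold=threshold)
    model = fit_lda(features, labels, vars=vars)

    correct: dict[str, int] = {c: 0 for c in model.classes}
    days: dict[str, int] = {c: 0 for c in model.classes}
    for i, (f, true) in enumerate(zip(features, labels)):
        if leave_one_out:
            rest_f = features[:i] + features[i + 1 :]
            rest_y = labels[:i] + labels[i + 1 :]
            m = fit_lda(rest_f, rest_y, vars=vars)
        else:
            m = model
        pred = predict_class(m, f)
        days[true] += 1
        if pred == true:
            correct[true] += 1
    scores = [HenScore(c, days[c], correct[c]) for c in model.classes]
    report = GroupingReport(
        scores=scores,
        method="lda" + ("-loo" if leave_one_out else ""),
    )
    return model, report
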