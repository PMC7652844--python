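"""Logistic models and the evaluation statistics of the biomarker study.

Conventions used throughout:

* the positive class is the minority class, men (label ``"male"``);
* ROC curves place one operating point per distinct score, so tied scores
  produce a single diagonal step;
* balanced evaluation draws ``per_class_n`` subjects per sex without
  replacement, repeats ``n_iterations`` times, and vertically averages the
  ROC curves (TPR interpolated on a fixed FPR grid);
* the "constrained" accuracy is the best pooled accuracy over thresholds
  whose TPR is strictly above 0.5 and FPR strictly below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateLabelsError
from .stats import wilcoxon_ranksum

POSITIVE_CLASS = "male"


def _binarize(labels, positive=POSITIVE_CLASS) -> np.ndarray:
    y = np.asarray([1 if lab == positive else 0 for lab in np.asarray(labels)])
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes must be present")
    return y


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive class); strictly inside (0, 1)."""
        p = 1.0 / (1.0 + np.exp(-np.clip(self.decision(X), -500, 500)))
        return np.clip(p, 1e-15, 1.0 - 1e-15)


def _irls(Xb: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, bool, int]:
    n, p = Xb.shape
    beta = np.zeros(p)
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0  # never penalize the intercept
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xb @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = Xb.T @ (y - mu) - pen @ beta
        hess = (Xb * w[:, None]).T @ Xb + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged, it


def fit_logistic(X: np.ndarray, y_or_labels, positive=POSITIVE_CLASS) -> LogisticModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    On detected separation (diverging coefficients or non-convergence) the
    model is refitted with a tiny ridge penalty (1e-8) and flagged.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y_or_labels)
    if y.dtype.kind not in "biu":
        y = _binarize(y, positive)
    else:
        y = y.astype(int)
        if y.min() == y.max():
            raise DegenerateLabelsError("both classes must be present")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    n = X.shape[0]
    Xb = np.hstack([np.ones((n, 1)), X])
    beta, converged, it = _irls(Xb, y, ridge=0.0)
    separated = (not converged) or (np.max(np.abs(beta)) > 1e3)
    if separated:
        beta, _, it = _irls(Xb, y, ridge=1e-8)
        converged = False
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        converged=converged,
        n_iter=it,
        separation=separated,
    )


# ---------------------------------------------------------------------------
# ROC machinery

@dataclass
class ROCCurve:
    """Ordered operating points from (0,0) to (1,1).

    ``thresholds`` holds the decision threshold of each point (``+inf`` for
    the origin) and is ``None`` for averaged curves, which have no single
    threshold per point.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray | None
    positive_class: str = POSITIVE_CLASS

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, float)
        self.tpr = np.asarray(self.tpr, float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, float)
            if np.any(np.diff(self.thresholds) >= 0):
                raise ValueError("thresholds must be strictly decreasing")


def roc_curve(scores, labels, positive=POSITIVE_CLASS) -> ROCCurve:
    """Operating points at every distinct score plus the (0,0) endpoint."""
    scores = np.asarray(scores, float)
    y = _binarize(labels, positive)
    order = np.argsort(-scores, kind="stable")
    s, ys = scores[order], y[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([distinct, [len(s) - 1]])  # last index of each tie group
    tp = np.cumsum(ys)[cut]
    fp = np.cumsum(1 - ys)[cut]
    n_pos, n_neg = y.sum(), (1 - y).sum()
    fpr = np.concatenate([[0.0], fp / n_neg])
    tpr = np.concatenate([[0.0], tp / n_pos])
    thresholds = np.concatenate([[np.inf], s[cut]])
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, positive_class=str(positive))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_from_scores(scores, labels, positive=POSITIVE_CLASS) -> float:
    return auc(roc_curve(scores, labels, positive))


@dataclass(frozen=True)
class ConstrainedAccuracy:
    """Best pooled accuracy under the TPR > 0.5 / FPR < 0.5 constraint."""

    feasible: bool
    accuracy_pct: float = float("nan")
    threshold: float = float("nan")
    tpr: float = float("nan")
    fpr: float = float("nan")


def constrained_max_accuracy(scores, labels, positive=POSITIVE_CLASS) -> ConstrainedAccuracy:
    """Maximum overall accuracy among thresholds with TPR > 0.5 and FPR < 0.5.

    Ties on accuracy are broken by maximal Youden J, then by the larger
    threshold. Returns an explicit infeasible result when no threshold
    satisfies both strict constraints.
    """
    y = _binarize(labels, positive)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    n = n_pos + n_neg
    curve = roc_curve(scores, labels, positive)
    best: ConstrainedAccuracy | None = None
    for fpr, tpr, thr in zip(curve.fpr, curve.tpr, curve.thresholds):
        if not (tpr > 0.5 and fpr < 0.5):
            continue
        acc = 100.0 * (tpr * n_pos + (1.0 - fpr) * n_neg) / n
        j = tpr - fpr
        if (
            best is None
            or acc > best.accuracy_pct + 1e-12
            or (abs(acc - best.accuracy_pct) <= 1e-12 and j > best.tpr - best.fpr + 1e-12)
            or (abs(acc - best.accuracy_pct) <= 1e-12
                and abs(j - (best.tpr - best.fpr)) <= 1e-12 and thr > best.threshold)
        ):
            best = ConstrainedAccuracy(True, acc, float(thr), float(tpr), float(fpr))
    return best if best is not None else ConstrainedAccuracy(False)


def mean_curve_constrained_accuracy(curve: ROCCurve) -> ConstrainedAccuracy:
    """Constrained accuracy of an averaged (balanced-priors) curve.

    Averaged curves come from class-balanced subsamples, so the pooled
    accuracy at an operating point is ``(TPR + 1 - FPR) / 2``.
    """
    best = None
    for fpr, tpr in zip(curve.fpr, curve.tpr):
        if not (tpr > 0.5 and fpr < 0.5):
            continue
        acc = 100.0 * (tpr + 1.0 - fpr) / 2.0
        if best is None or acc > best.accuracy_pct:
            best = ConstrainedAccuracy(True, acc, float("nan"), float(tpr), float(fpr))
    return best if best is not None else ConstrainedAccuracy(False)


# ---------------------------------------------------------------------------
# model specifications and validation schemes

@dataclass(frozen=True)
class ModelSpec:
    """Which feature columns enter the logistic model.

    ``select_k`` enables rank-sum channel selection (computed on training
    data only, inside each fold / iteration).
    """

    name: str
    features: tuple[str, ...]
    select_k: int | None = None

    def __post_init__(self) -> None:
        if self.select_k is not None and not 1 <= self.select_k <= len(self.features):
            raise ConfigurationError("select_k must be between 1 and the feature count")


@dataclass(frozen=True)
class ResampleConfig:
    n_iterations: int = 100
    per_class_n: int = 40
    seed: int = 0
    grid_size: int = 101

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.per_class_n < 1:
            raise ConfigurationError("per_class_n must be >= 1")


def rank_select_channels(X: np.ndarray, y_or_labels, k: int,
                         positive=POSITIVE_CLASS) -> list[int]:
    """Indices of the ``k`` columns with the smallest rank-sum p-values.

    Deterministic: ties broken by column order; result returned in column
    order. Must only ever see training data.
    """
    X = np.asarray(X, float)
    if not 1 <= k <= X.shape[1]:
        raise ConfigurationError(f"k must be in [1, {X.shape[1]}]")
    y = np.asarray(y_or_labels)
    if y.dtype.kind not in "biu":
        y = _binarize(y, positive)
    pvals = np.array([
        wilcoxon_ranksum(X[y == 1, j], X[y == 0, j]).p_value for j in range(X.shape[1])
    ])
    chosen = np.argsort(pvals, kind="stable")[:k]
    return sorted(int(c) for c in chosen)


def _fit_and_score(X_train, y_train, X_eval) -> np.ndarray:
    model = fit_logistic(X_train, y_train)
    return model.predict_proba(X_eval)


def loocv_scores(X: np.ndarray, y_or_labels, select_k: int | None = None,
                 positive=POSITIVE_CLASS) -> np.ndarray:
    """Out-of-sample probability for each subject under leave-one-out."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y_or_labels)
    if y.dtype.kind not in "biu":
        y = _binarize(y, positive)
    n = len(y)
    if min(y.sum(), n - y.sum()) < 3:
        raise DegenerateLabelsError("need at least 3 subjects per class for LOOCV")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if ytr.min() == ytr.max():
            raise DegenerateLabelsError(f"fold {i} has a single-class training set")
        cols = slice(None)
        if select_k is not None:
            cols = rank_select_channels(X[mask], ytr, select_k)
        model = fit_logistic(X[mask][:, cols], ytr)
        scores[i] = model.predict_proba(X[i : i + 1, cols])[0]
    return scores


def balanced_subsample_mean_roc(
    X: np.ndarray,
    y_or_labels,
    config: ResampleConfig | None = None,
    loocv: bool = False,
    select_k: int | None = None,
    positive=POSITIVE_CLASS,
) -> tuple[ROCCurve, np.ndarray]:
    """Mean ROC over repeated sex-balanced subsamples.

    Iteration ``i`` uses ``default_rng(seed + i)`` and draws ``per_class_n``
    subjects per class without replacement; the model is fitted on the
    subsample and scored either in-sample or by leave-one-out within the
    subsample. Curves are vertically averaged on a fixed FPR grid.

    Returns the mean curve and the vector of per-iteration (trapezoid) AUCs.
    """
    config = config or ResampleConfig()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y_or_labels)
    if y.dtype.kind not in "biu":
        y = _binarize(y, positive)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if min(len(pos_idx), len(neg_idx)) < config.per_class_n:
        raise ConfigurationError(
            f"per_class_n={config.per_class_n} exceeds a class size "
            f"({len(pos_idx)} pos / {len(neg_idx)} neg)"
        )
    grid = np.linspace(0.0, 1.0, config.grid_size)
    tprs = np.empty((config.n_iterations, config.grid_size))
    aucs = np.empty(config.n_iterations)
    for i in range(config.n_iterations):
        rng = np.random.default_rng(config.seed + i)
        sub = np.concatenate([
            rng.choice(pos_idx, size=config.per_class_n, replace=False),
            rng.choice(neg_idx, size=config.per_class_n, replace=False),
        ])
        Xs, ys = X[sub], y[sub]
        if loocv:
            scores = loocv_scores(Xs, ys, select_k=select_k)
        else:
            cols = slice(None)
            if select_k is not None:
                cols = rank_select_channels(Xs, ys, select_k)
            scores = _fit_and_score(Xs[:, cols], ys, Xs[:, cols])
        curve = roc_curve(scores, ys, positive=1)
        tprs[i] = np.interp(grid, curve.fpr, curve.tpr)
        aucs[i] = auc(curve)
    mean_curve = ROCCurve(fpr=grid, tpr=tprs.mean(axis=0), thresholds=None,
                          positive_class=str(positive))
    return mean_curve, aucs


# ---------------------------------------------------------------------------
# the six-model evaluation grid

@dataclass
class EvalResult:
    model: str
    session: str
    scheme: str  # in-sample | balanced-mean | leave-one-out | balanced-loocv
    auc: float
    accuracy_pct: float
    threshold: float
    feasible: bool
    n_iterations: int | None = None
    auc_iteration_mean: float | None = None  # mean of per-iteration areas

    def to_dict(self) -> dict:
        return {
            "model": self.model, "session": self.session, "scheme": self.scheme,
            "auc": self.auc, "accuracy_pct": self.accuracy_pct,
            "threshold": self.threshold, "feasible": self.feasible,
            "n_iterations": self.n_iterations,
            "auc_iteration_mean": self.auc_iteration_mean,
        }


def mean_feature_spec() -> ModelSpec:
    return ModelSpec("mean_rel_beta", ("mean_rel_beta",))


def all_channel_spec(table: pd.DataFrame) -> ModelSpec:
    cols = tuple(c for c in table.columns if c.startswith("rb_"))
    if not cols:
        raise ConfigurationError("no per-channel feature columns (rb_*) in table")
    return ModelSpec("all_channels", cols)


def evaluate_models(
    table: pd.DataFrame,
    resample: ResampleConfig | None = None,
    sessions: tuple[str, ...] = ("pre", "post"),
) -> list[EvalResult]:
    """Reproduce the six-model x session evaluation grid on a feature table.

    Rows: {mean feature, all channels} x {full fit, balanced mean} plus
    leave-one-out and balanced leave-one-out for the all-channel model.
    Sessions absent from the table yield explicit gaps (no rows).
    """
    resample = resample or ResampleConfig()
    results: list[EvalResult] = []
    for session in sessions:
        sub = table[table["session"] == session].dropna(subset=["mean_rel_beta"])
        if sub.empty:
            continue
        labels = sub["sex"].to_numpy()
        mean_spec = mean_feature_spec()
        full_spec = all_channel_spec(sub)

        for spec in (mean_spec, full_spec):
            X = sub[list(spec.features)].to_numpy()
            scores = _fit_and_score(X, labels, X)
            ca = constrained_max_accuracy(scores, labels)
            results.append(EvalResult(
                model=spec.name, session=session, scheme="in-sample",
                auc=auc_from_scores(scores, labels), accuracy_pct=ca.accuracy_pct,
                threshold=ca.threshold, feasible=ca.feasible,
            ))
            curve, aucs = balanced_subsample_mean_roc(X, labels, resample)
            ca = mean_curve_constrained_accuracy(curve)
            results.append(EvalResult(
                model=spec.name, session=session, scheme="balanced-mean",
                auc=auc(curve), accuracy_pct=ca.accuracy_pct,
                threshold=ca.threshold, feasible=ca.feasible,
                n_iterations=resample.n_iterations,
                auc_iteration_mean=float(aucs.mean()),
            ))

        X = sub[list(full_spec.features)].to_numpy()
        scores = loocv_scores(X, labels)
        ca = constrained_max_accuracy(scores, labels)
        results.append(EvalResult(
            model=full_spec.name, session=session, scheme="leave-one-out",
            auc=auc_from_scores(scores, labels), accuracy_pct=ca.accuracy_pct,
            threshold=ca.threshold, feasible=ca.feasible,
        ))
        curve, aucs = balanced_subsample_mean_roc(X, labels, resample, loocv=True)
        ca = mean_curve_constrained_accuracy(curve)
        results.append(EvalResult(
            model=full_spec.name, session=session, scheme="balanced-loocv",
            auc=auc(curve), accuracy_pct=ca.accuracy_pct,
            threshold=ca.threshold, feasible=ca.feasible,
            n_iterations=resample.n_iterations,
            auc_iteration_mean=float(aucs.mean()),
        ))
    return results


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
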