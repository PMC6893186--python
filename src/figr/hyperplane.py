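"""Regulatory-parameter inference by linear binary classification.

Given per-observation ON/OFF labels for one target gene, its row of the
genetic interconnectivity matrix and its threshold define a separating
hyperplane: y_p = sgn(T . x_p + h).  Recovering (T, h) is therefore a
linear binary classification problem and is solved by minimizing

    chi(T, h, lambda) = lambda * ||T||^2 + sum_p L(y_p, x_p)

with either the binomial-deviance loss (logistic regression, the default)
or the hinge loss (a linear SVM).  Both are convex, so the fitted
hyperplane is deterministic given the data.  The hyperplane is only
identified up to a positive scale; the fit is reported both raw and
normalized to ||(T, h)|| = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

__all__ = ["HyperplaneFit", "DegenerateLabelsError", "infer_regulatory",
           "predict_state"]


class DegenerateLabelsError(ValueError):
    """All observations carry the same label, so no hyperplane is identified."""


@dataclass(frozen=True)
class HyperplaneFit:
    """A fitted switching hyperplane for one gene.

    ``T_row`` and ``h`` are normalized so that ``||(T_row, h)|| = 1``;
    ``raw_T`` and ``raw_h`` keep the solver's scale (useful when the logit
    scale itself matters).  ``training_accuracy`` is the fraction of
    training labels reproduced by ``sgn(T . x + h)``.
    """

    T_row: np.ndarray
    h: float
    method: str
    reg_lambda: float
    training_accuracy: float
    raw_T: np.ndarray | None = None
    raw_h: float | None = None

    def __post_init__(self):
        T_row = np.asarray(self.T_row, dtype=float)
        norm = float(np.sqrt(T_row @ T_row + self.h * self.h))
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("hyperplane coefficients must be finite and nonzero")
        object.__setattr__(self, "T_row", T_row / norm)
        object.__setattr__(self, "h", float(self.h) / norm)
        if not 0.0 <= self.training_accuracy <= 1.0:
            raise ValueError("training_accuracy must lie in [0, 1]")

    @property
    def unit_normal(self) -> np.ndarray:
        """T_row normalized to a unit vector (ignoring the intercept)."""
        return self.T_row / np.linalg.norm(self.T_row)


def infer_regulatory(points, labels, method: str = "logistic",
                     reg_lambda: float | None = None,
                     class_weight=None) -> HyperplaneFit:
    """Fit the switching hyperplane of one gene from labeled states.

    Parameters
    ----------
    points : (P, G) array
        Observed state vectors.
    labels : (P,) array of +1/-1
        ON/OFF calls for the target gene at each observation.
    method : {"logistic", "svm"}
        Loss: binomial deviance or hinge.
    reg_lambda : float, optional
        Weight of the ||T||^2 penalty in the cost; defaults to 1/P.
    class_weight : None or "balanced"
        Optional inverse-frequency reweighting of the two classes.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a (P, G) matrix")
    y = np.asarray(labels).ravel().astype(int)
    if y.size != X.shape[0]:
        raise ValueError("labels must match points in length")
    P = X.shape[0]
    if P < 2:
        raise ValueError("need at least 2 observations")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1, 1))):
        raise ValueError("labels must be +1 or -1")
    if classes.size < 2:
        raise DegenerateLabelsError(
            "all observations are in one class; the switching hyperplane is "
            "unidentifiable -- consider adjusting the velocity/expression "
            "thresholds of the ON/OFF caller")
    if reg_lambda is None:
        reg_lambda = 1.0 / P
    if reg_lambda <= 0:
        raise ValueError("reg_lambda must be positive")
    C = 1.0 / (2.0 * reg_lambda)
    if method == "logistic":
        clf = LogisticRegression(C=C, solver="newton-cholesky", max_iter=200,
                                 tol=1e-8, class_weight=class_weight)
    elif method == "svm":
        clf = LinearSVC(C=C, loss="hinge", max_iter=20000, tol=1e-8,
                        class_weight=class_weight, random_state=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    clf.fit(X, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    # orient toward the classifier's own +1 (ON) class
    if clf.classes_[1] != 1:
        w, b = -w, -b
    pred = np.where(X @ w + b >= 0.0, 1, -1)
    acc = float(np.mean(pred == y))
    return HyperplaneFit(T_row=w, h=b, method=method, reg_lambda=float(reg_lambda),
                         training_accuracy=acc, raw_T=w.copy(), raw_h=b)


def predict_state(fit: HyperplaneFit, x):
    """Predict the ON/OFF label sgn(T . x + h) at state(s) ``x``.

    Accepts a single length-G state or a (P, G) stack; points exactly on
    the hyperplane are assigned +1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != fit.T_row.size:
        raise ValueError("state length does not match the fitted hyperplane")
    u = x @ fit.T_row + fit.h
    out = np.where(u >= 0.0, 1, -1)
    return out if out.ndim else int(out)
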