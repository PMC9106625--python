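"""PLS-DA: NIPALS partial least squares for two-class discrimination.

The two diet arms are coded y = -1 (control, "C") and y = +1 (experimental,
"Ex").  Fitting is NIPALS PLS1 on mean-centered (by default also
unit-variance scaled) X against centered y; for a single response the NIPALS
weight step is non-iterative, so the fit is exact and deterministic.
Variable importance in projection (VIP), cross-validated latent-variable
selection, and held-out ER/AUC evaluation complete the kernel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ComplexityError, CVError, EstimationError, SchemaError

log = logging.getLogger(__name__)

NEG_CLASS, POS_CLASS = -1, 1  # C-diet, Ex-diet


@dataclass
class PLSModel:
    """Fitted PLS-DA state.

    ``W`` (p x A) are the X weights, ``P`` the X loadings, ``T`` (n x A) the
    orthogonal X scores, ``q`` the y loadings and ``tt`` the per-component
    score norms t_a' t_a.  ``SSY_a = q_a^2 * tt_a`` is the y-variance
    captured by component a (used by VIP).  Coefficients for any leading
    subset of components derive from (W, P, q) without refitting.
    """

    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    tt: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    n_lv: int
    class_means_: dict = field(default_factory=dict)  # label -> mean training score
    thresholds_: np.ndarray | None = None  # midpoint threshold per component count

    @property
    def n_variables(self) -> int:
        return self.W.shape[0]

    def coef(self, k: int | None = None) -> np.ndarray:
        """Regression vector (scaled space) using the leading k components."""
        k = self.n_lv if k is None else k
        Wk, Pk, qk = self.W[:, :k], self.P[:, :k], self.q[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    def decision_scores(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_variables:
            raise SchemaError(
                f"model has {self.n_variables} variables, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coef(k) + self.y_mean

    def threshold(self, k: int | None = None) -> float:
        k = self.n_lv if k is None else k
        return float(self.thresholds_[k - 1])

    # ---- structured-text serialization for audit ------------------------
    def save_text(self, path: str) -> None:
        """Write the fitted state (weights, loadings, scores norms, scaling)
        as JSON so a model can be inspected or reloaded without refitting."""
        state = {
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "T": self.T.tolist(),
            "q": self.q.tolist(),
            "tt": self.tt.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "n_lv": self.n_lv,
            "class_means": {str(k): v for k, v in self.class_means_.items()},
            "thresholds": self.thresholds_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(state, fh, indent=1)

    @classmethod
    def load_text(cls, path: str) -> "PLSModel":
        with open(path) as fh:
            s = json.load(fh)
        return cls(
            W=np.asarray(s["W"]),
            P=np.asarray(s["P"]),
            T=np.asarray(s["T"]),
            q=np.asarray(s["q"]),
            tt=np.asarray(s["tt"]),
            x_mean=np.asarray(s["x_mean"]),
            x_scale=np.asarray(s["x_scale"]),
            y_mean=float(s["y_mean"]),
            n_lv=int(s["n_lv"]),
            class_means_={int(k): v for k, v in s["class_means"].items()},
            thresholds_=np.asarray(s["thresholds"]),
        )


def fit_pls(X, y, n_lv: int, scale: bool = True) -> PLSModel:
    """Fit a PLS1 discriminant model by NIPALS.

    X is centered and (if ``scale``) autoscaled column-wise; constant
    variables are retained at unit scale, which gives them exactly zero
    weight (equivalent to dropping them while keeping variable indices
    stable) and a warning.  y must contain both -1 and +1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if set(np.unique(y)) != {NEG_CLASS, POS_CLASS}:
        raise EstimationError("y must contain both classes coded -1/+1")
    max_rank = min(n - 1, p)
    if not 1 <= n_lv <= max_rank:
        raise ComplexityError(f"n_lv must be in [1, {max_rank}], got {n_lv}")

    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        n_const = int((x_scale == 0).sum())
        if n_const:
            log.warning("%d constant variables get zero weight", n_const)
        x_scale = np.where(x_scale == 0, 1.0, x_scale)
    else:
        x_scale = np.ones(p)
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    tt = np.zeros(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    a_fit = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # no covariance left; stop early
            break
        w /= nw
        t = Xd @ w
        tta = float(t @ t)
        if tta < 1e-12:
            break
        pa = Xd.T @ t / tta
        qa = float(yd @ t / tta)
        W[:, a], P[:, a], T[:, a], q[a], tt[a] = w, pa, t, qa, tta
        Xd -= np.outer(t, pa)
        yd -= qa * t
        a_fit = a + 1
    if a_fit == 0:
        raise EstimationError("no usable PLS component (X uncorrelated with y)")
    model = PLSModel(
        W=W[:, :a_fit],
        P=P[:, :a_fit],
        T=T[:, :a_fit],
        q=q[:a_fit],
        tt=tt[:a_fit],
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        n_lv=a_fit,
    )
    # training-score class means and midpoint thresholds for every k
    thresholds = np.zeros(a_fit)
    for k in range(1, a_fit + 1):
        s = Xc @ model.coef(k) + y_mean
        m_pos = s[y == POS_CLASS].mean()
        m_neg = s[y == NEG_CLASS].mean()
        thresholds[k - 1] = 0.5 * (m_pos + m_neg)
        if k == a_fit:
            model.class_means_ = {POS_CLASS: float(m_pos), NEG_CLASS: float(m_neg)}
    model.thresholds_ = thresholds
    return model


def predict_classify(model: PLSModel, X_new, k: int | None = None):
    """Continuous decision scores and hard labels for new samples.

    The label is the sign of the score relative to the midpoint of the
    training class-mean scores; a score exactly at the threshold goes to the
    positive class.
    """
    scores = model.decision_scores(X_new, k)
    labels = np.where(scores >= model.threshold(k), POS_CLASS, NEG_CLASS)
    return scores, labels


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ), with
    SSY_a = q_a^2 t_a't_a the y-variance explained by component a.  By
    construction mean(VIP^2) = 1.
    """
    p = model.n_variables
    ssy = model.q**2 * model.tt
    wnorm2 = (model.W**2) / (model.W**2).sum(axis=0, keepdims=True)
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


@dataclass
class EvalMetrics:
    """Held-out performance: misclassification rate and ROC AUC."""

    er: float
    auc: float
    scores: np.ndarray

    @property
    def accuracy(self) -> float:
        return 1.0 - self.er


def auc_mann_whitney(scores, labels_true) -> float:
    """AUC as the Mann-Whitney probability that a random positive outscores a
    random negative, ties counted 0.5."""
    scores = np.asarray(scores, float)
    labels_true = np.asarray(labels_true)
    pos = labels_true == POS_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EstimationError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(scores, labels_true, labels_pred) -> EvalMetrics:
    """ER (fraction of label mismatches) and tie-aware AUC of the scores."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    er = float(np.mean(labels_pred != labels_true))
    return EvalMetrics(er=er, auc=auc_mann_whitney(scores, labels_true), scores=np.asarray(scores))


def cv_error_profile(
    X, y, max_lv: int, cv_folds: int = 10, seed: int = 0, scale: bool = True
) -> np.ndarray:
    """Stratified k-fold CV misclassification rate for 1..max_lv components.

    Each fold is fitted once at the largest feasible component count; error
    at smaller counts reuses the leading components of the same fit.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if cv_folds > n:
        raise CVError(f"{cv_folds} folds but only {n} samples")
    if max_lv < 1:
        raise CVError("max_lv must be >= 1")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = np.zeros(max_lv)
    counts = np.zeros(max_lv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in skf.split(X, y):
            lv_cap = min(max_lv, len(tr) - 1, X.shape[1])
            model = fit_pls(X[tr], y[tr], lv_cap, scale=scale)
            for k in range(1, model.n_lv + 1):
                _, pred = predict_classify(model, X[te], k)
                errors[k - 1] += np.sum(pred != y[te])
                counts[k - 1] += len(te)
            # folds where fewer components were estimable reuse the last one
            for k in range(model.n_lv + 1, max_lv + 1):
                _, pred = predict_classify(model, X[te], model.n_lv)
                errors[k - 1] += np.sum(pred != y[te])
                counts[k - 1] += len(te)
    return errors / counts


def select_n_lv(
    X,
    y,
    max_lv: int,
    cv_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
    return_profile: bool = False,
):
    """Smallest latent-variable count achieving the minimal CV error
    (ties broken toward fewer components)."""
    profile = cv_error_profile(X, y, max_lv, cv_folds, seed, scale)
    n_lv = int(np.argmin(profile)) + 1  # argmin returns the first minimum
    if return_profile:
        return n_lv, profile
    return n_lv
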