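"""Repeated double cross-validation with VIP-driven variable elimination.

The discrimination analysis: for each of ``n_repeats`` random outer splits
(stratified by arm, default 80/20 train/test), backward elimination of
low-VIP variables reduces the training matrix to the panel-size candidate
achieving the best inner cross-validated classification error; the
surviving variable set is refitted on the full training set and scored once
on the untouched test subjects (ER and AUC).  Variables present in more
than ``stability_threshold`` of the repeats form the stability-selected
panel.

The inner error-versus-size curve is estimated *nested*: each inner fold
runs its own elimination path and every size on the path is scored on the
fold's held-out samples.  Scoring sizes with the same samples that ranked
the variables would systematically favour large variable sets (chance
correlates look useful in-sample), which inflates the stability panel with
false discoveries.  The returned set is the largest one whose debiased
inner-CV error stays within ``size_z`` standard errors of the curve minimum
(contiguously from the minimum): for biomarker-panel recovery, dropping a
true marker costs more than carrying a spurious one, and the stability
threshold across repeats removes the spurious ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, StratificationError
from .plsda import (
    evaluate,
    fit_pls,
    predict_classify,
    select_n_lv,
    vip_scores,
)

log = logging.getLogger(__name__)


@dataclass
class DCVConfig:
    """Tuning knobs of the repeated double cross-validation.

    ``elimination_fraction`` is the share of lowest-VIP variables dropped
    per elimination round; ``size_folds``/``size_cv_reps`` control the
    nested error-versus-size estimate (``size_cv_reps`` replicate
    ``size_folds``-fold splits); ``size_z`` is the sensitivity-protecting
    margin (in standard errors above the minimal inner error) used when
    choosing the panel-size candidate; ``path_n_lv`` is the component count
    used for VIP ranking along the elimination path.
    """

    n_repeats: int = 100
    test_fraction: float = 0.20
    stability_threshold: float = 0.70
    elimination_fraction: float = 0.20
    max_lv: int = 5
    inner_folds: int = 10
    size_folds: int = 5
    size_cv_reps: int = 3
    size_z: float = 3.0
    path_n_lv: int = 2
    scale: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if not 0 < self.stability_threshold <= 1:
            raise ConfigurationError("stability_threshold must be in (0, 1]")
        if not 0 < self.elimination_fraction < 1:
            raise ConfigurationError("elimination_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.max_lv < 1:
            raise ConfigurationError("max_lv must be >= 1")
        if self.inner_folds < 2:
            raise ConfigurationError("inner_folds must be >= 2")
        if self.size_folds < 2:
            raise ConfigurationError("size_folds must be >= 2")
        if self.size_cv_reps < 1:
            raise ConfigurationError("size_cv_reps must be >= 1")
        if self.size_z < 0:
            raise ConfigurationError("size_z must be >= 0")
        if self.path_n_lv < 1:
            raise ConfigurationError("path_n_lv must be >= 1")


@dataclass
class RepeatRecord:
    """Outcome of one outer train/test repeat."""

    repeat: int
    train_ids: list
    test_ids: list
    selected: list
    n_lv: int
    test_er: float
    test_auc: float
    ok: bool = True
    note: str = ""


@dataclass
class DCVResult:
    """Aggregated repeated-double-CV outcome."""

    repeats: list
    variable_ids: list
    selection_frequency: pd.Series
    mean_er: float
    mean_auc: float
    config: DCVConfig

    @property
    def n_successful(self) -> int:
        return sum(1 for r in self.repeats if r.ok)

    def per_repeat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [r.repeat for r in self.repeats],
                "ok": [r.ok for r in self.repeats],
                "test_er": [r.test_er for r in self.repeats],
                "test_auc": [r.test_auc for r in self.repeats],
                "n_lv": [r.n_lv for r in self.repeats],
                "n_selected": [len(r.selected) for r in self.repeats],
            }
        )


def outer_split(subject_ids, arms, test_fraction: float, seed) -> tuple[list, list]:
    """Stratified-by-arm random train/test split of subjects (disjoint and
    exhaustive), reproducible from ``seed``."""
    subject_ids = np.asarray(subject_ids)
    arms = np.asarray(arms)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for arm in sorted(set(arms.tolist())):
        members = subject_ids[arms == arm]
        if len(members) < 2:
            raise StratificationError(f"arm {arm!r} has fewer than 2 subjects")
        n_test = max(1, int(round(len(members) * test_fraction)))
        if n_test >= len(members):
            n_test = len(members) - 1
        order = rng.permutation(len(members))
        test.extend(members[order[:n_test]].tolist())
        train.extend(members[order[n_test:]].tolist())
    return sorted(train), sorted(test)


def vip_path(X, y, elimination_fraction: float = 0.2, n_lv: int = 2, scale: bool = True):
    """Backward VIP-elimination path.

    Repeatedly fits a PLS-DA model and drops the ``elimination_fraction``
    lowest-VIP variables (at least one) until a single variable remains.
    Returns the list of ``(size, variable_indices, model)`` triples along
    the path, largest set first.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    current = np.arange(X.shape[1])
    path = []
    while True:
        k = min(n_lv, len(current), X.shape[0] - 1)
        model = fit_pls(X[:, current], y, k, scale=scale)
        path.append((len(current), current, model))
        n_drop = max(1, int(np.floor(elimination_fraction * len(current))))
        if n_drop >= len(current):
            break
        vip = vip_scores(model)
        keep = np.argsort(vip, kind="stable")[n_drop:]
        current = current[np.sort(keep)]
    return path


def size_error_curve(X, y, config: DCVConfig, seed=0):
    """Debiased inner-CV classification error as a function of panel size.

    For each of ``size_cv_reps`` replicate stratified ``size_folds``-fold
    splits, every fold runs its own VIP-elimination path on the fold's
    training samples and scores each path size on the held-out samples, so
    the error estimate at a size never reuses the samples that ranked the
    variables.  Returns ``(curve, n_evaluations)`` where ``curve`` maps size
    to mean held-out error.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    err: dict[int, list] = {}
    n_eval = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(config.size_cv_reps):
            skf = StratifiedKFold(
                n_splits=min(config.size_folds, n),
                shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            for tr, te in skf.split(X, y):
                for size, sel, model in vip_path(
                    X[tr], y[tr], config.elimination_fraction,
                    config.path_n_lv, config.scale,
                ):
                    _, pred = predict_classify(model, X[te][:, sel])
                    err.setdefault(size, []).append(float(np.mean(pred != y[te])))
            n_eval += n
    curve = {s: float(np.mean(v)) for s, v in err.items()}
    return curve, n_eval


def eliminate_by_vip(X_train, y_train, config: DCVConfig, seed=0):
    """Backward elimination of low-VIP variables with nested size selection.

    The panel size is read off the debiased error-versus-size curve of
    :func:`size_error_curve`: starting from the size with the lowest
    held-out error, the choice walks toward larger sizes while the error
    stays within ``size_z`` standard errors of that minimum (contiguously),
    trading a few spurious variables for protection against dropping true
    markers.  The returned variable set is the elimination-path set on the
    full training data closest to the chosen size; the model complexity for
    that set is then chosen by standard inner CV.

    Returns ``(variable_indices, info)`` with ``info`` carrying the error
    curve (``trace``), the chosen ``size`` and ``n_lv``.
    """
    config.validate()
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    n, p = X_train.shape
    if p < 2:
        raise ConfigurationError("need at least 2 variables to eliminate")
    rng = np.random.default_rng(seed)

    curve, n_eval = size_error_curve(X_train, y_train, config, seed=int(rng.integers(2**31)))
    sizes = sorted(curve)
    er_min = min(curve.values())
    se = np.sqrt(er_min * (1.0 - er_min) / n_eval)
    s_min = min(s for s in sizes if curve[s] == er_min)
    s_star = s_min
    for s in sizes:
        if s <= s_min:
            continue
        if curve[s] <= er_min + config.size_z * se:
            s_star = s
        else:
            break

    path = vip_path(
        X_train, y_train, config.elimination_fraction, config.path_n_lv, config.scale
    )
    selected = min(path, key=lambda t: abs(t[0] - s_star))[1]
    n_lv = select_n_lv(
        X_train[:, selected],
        y_train,
        min(config.max_lv, len(selected), n - 1),
        cv_folds=min(config.inner_folds, n),
        seed=int(rng.integers(2**31)),
        scale=config.scale,
    )
    return np.asarray(selected), {"trace": curve, "size": int(s_star), "n_lv": n_lv}


def run_repeated_dcv(X, y, config: DCVConfig, subject_ids=None, variable_ids=None) -> DCVResult:
    """Repeated double cross-validation over random outer splits.

    ``X`` is the preprocessed baseline-corrected matrix (subjects x
    variables), ``y`` the arm labels coded -1/+1.  Per-repeat seeds derive
    from ``config.rng_seed`` via a SeedSequence, so the result is bit-for-bit
    reproducible and independent of execution order.  Degenerate repeats are
    excluded from the aggregates with a warning.
    """
    config.validate()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if subject_ids is None:
        subject_ids = [f"subj{i}" for i in range(n)]
    if variable_ids is None:
        variable_ids = [f"var{j}" for j in range(p)]
    subject_ids = list(subject_ids)
    variable_ids = list(variable_ids)
    pos = {s: i for i, s in enumerate(subject_ids)}

    children = np.random.SeedSequence(config.rng_seed).spawn(config.n_repeats)
    repeats = []
    counts = np.zeros(p)
    for r, child in enumerate(children):
        rep_rng = np.random.default_rng(child)
        split_seed = int(rep_rng.integers(2**31))
        elim_seed = int(rep_rng.integers(2**31))
        try:
            train_ids, test_ids = outer_split(
                subject_ids, y, config.test_fraction, split_seed
            )
            tr = np.array([pos[s] for s in train_ids])
            te = np.array([pos[s] for s in test_ids])
            sel, info = eliminate_by_vip(X[tr], y[tr], config, seed=elim_seed)
            model = fit_pls(X[tr][:, sel], y[tr], info["n_lv"], scale=config.scale)
            scores, pred = predict_classify(model, X[te][:, sel])
            metrics = evaluate(scores, y[te], pred)
            repeats.append(
                RepeatRecord(
                    repeat=r,
                    train_ids=train_ids,
                    test_ids=test_ids,
                    selected=[variable_ids[j] for j in sel],
                    n_lv=model.n_lv,
                    test_er=metrics.er,
                    test_auc=metrics.auc,
                )
            )
            counts[sel] += 1
        except Exception as exc:  # degenerate repeat: excluded, reported
            log.warning("repeat %d failed: %s", r, exc)
            repeats.append(
                RepeatRecord(
                    repeat=r,
                    train_ids=[],
                    test_ids=[],
                    selected=[],
                    n_lv=0,
                    test_er=np.nan,
                    test_auc=np.nan,
                    ok=False,
                    note=str(exc),
                )
            )
    ok = [r for r in repeats if r.ok]
    if not ok:
        raise StratificationError("every double-CV repeat failed")
    freq = pd.Series(counts / len(ok), index=variable_ids, name="selection_frequency")
    return DCVResult(
        repeats=repeats,
        variable_ids=variable_ids,
        selection_frequency=freq,
        mean_er=float(np.mean([r.test_er for r in ok])),
        mean_auc=float(np.mean([r.test_auc for r in ok])),
        config=config,
    )


def stability_select(result: DCVResult, threshold: float | None = None) -> list:
    """Variables selected in strictly more than ``threshold`` of the
    successful repeats (default: the config's stability threshold)."""
    if threshold is None:
        threshold = result.config.stability_threshold
    freq = result.selection_frequency
    return list(freq.index[freq > threshold])
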