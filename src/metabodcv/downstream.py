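"""From the stability-selected panel to clinical interpretation.

Subjects' baseline-corrected intensities of the selected metabolites are
summarized by the first two principal components ("metabolic profile
scores"); those scores are correlated with clinical changes (Pearson r with
Fisher-z confidence intervals), tested as mediators of the diet effect on
lipid outcomes (bootstrap product-of-coefficients mediation), and the panel
itself is organized by Spearman-correlation hierarchical clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegeneracyError, EstimationError, PreconditionError

log = logging.getLogger(__name__)


# -------------------------------------------------------------------------
# PCA profile scores
# -------------------------------------------------------------------------

@dataclass
class ProfileScores:
    """Per-subject principal-component scores on the selected panel."""

    scores: pd.DataFrame  # subjects x components (PC1, PC2, ...)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # variables x components


def pca_profile(X_panel: pd.DataFrame, n_components: int = 2, scale: bool = False) -> ProfileScores:
    """Centered (optionally autoscaled) PCA of the panel matrix via SVD.

    Sign convention: each component is flipped so that its largest-magnitude
    loading is positive, making the decomposition deterministic.
    """
    if X_panel.shape[0] < 3:
        raise DegeneracyError("PCA needs at least 3 subjects")
    if X_panel.shape[1] < 2:
        raise DegeneracyError("PCA needs at least 2 variables")
    X = X_panel.to_numpy(float)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = s**2 / (s**2).sum()
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    load = Vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    return ProfileScores(
        scores=pd.DataFrame(scores, index=X_panel.index, columns=names),
        explained_variance_ratio=evr[:k],
        loadings=pd.DataFrame(load, index=X_panel.columns, columns=names),
    )


# -------------------------------------------------------------------------
# score-outcome associations
# -------------------------------------------------------------------------

def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        raise PreconditionError("Fisher CI needs n >= 4")
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def associate_outcomes(
    scores: ProfileScores, clinical_changes: pd.DataFrame, outcomes=None
) -> pd.DataFrame:
    """Pearson correlation of each clinical change with each profile score.

    Returns one row per (outcome, component): r, Fisher-z 95% CI, two-sided
    p-value (unadjusted, as conventional for this exploratory table).
    """
    if outcomes is None:
        outcomes = [c for c in clinical_changes.columns if c != "arm"]
    common = scores.scores.index.intersection(clinical_changes.index)
    if len(common) < 4:
        raise PreconditionError("need >= 4 paired subjects for confidence intervals")
    rows = []
    for outcome in outcomes:
        yv = clinical_changes.loc[common, outcome].to_numpy(float)
        for comp in scores.scores.columns:
            xv = scores.scores.loc[common, comp].to_numpy(float)
            res = stats.pearsonr(xv, yv)
            lo, hi = fisher_ci(float(res.statistic), len(common))
            rows.append(
                {
                    "outcome": outcome,
                    "component": comp,
                    "n": len(common),
                    "r": float(res.statistic),
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------------
# causal mediation (bootstrap product of coefficients)
# -------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Linear-model mediation estimates with percentile bootstrap CIs.

    ACME = a*b (treatment -> mediator -> outcome), ADE = c' (direct path);
    for linear fits the point estimates satisfy total = ACME + ADE exactly.
    """

    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    prop_mediated: float
    n_boot: int
    ci_level: float


def _mediation_point(t, m, o):
    ones = np.ones_like(t)
    Xa = np.column_stack([ones, t])
    a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
    Xb = np.column_stack([ones, t, m])
    coef = np.linalg.lstsq(Xb, o, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    return a * b, c_prime


def mediate(
    treatment,
    mediator,
    outcome,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Does the metabolic-profile score mediate the diet effect on an outcome?

    Fits ``mediator ~ treatment`` and ``outcome ~ treatment + mediator`` by
    OLS; ACME is the product of coefficients a*b, ADE the direct coefficient
    c'.  CIs are case-resampling percentile bootstrap over ``n_boot``
    resamples, seeded.
    """
    t = np.asarray(treatment, float)
    m = np.asarray(mediator, float)
    o = np.asarray(outcome, float)
    if not (len(t) == len(m) == len(o)):
        raise PreconditionError("treatment, mediator, outcome lengths differ")
    if len(set(np.unique(t))) != 2:
        raise EstimationError("treatment must be binary")
    if np.std(t) == 0 or np.std(m) == 0:
        raise EstimationError("degenerate variance in treatment or mediator")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile CIs", stacklevel=2)

    acme, ade = _mediation_point(t, m, o)
    total = acme + ade
    rng = np.random.default_rng(seed)
    n = len(t)
    boots = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.std(t[idx]) == 0:  # resample until both arms present
            idx = rng.integers(0, n, n)
        boots[i] = _mediation_point(t[idx], m[idx], o[idx])
    alpha = (1 - ci_level) / 2
    qs = [100 * alpha, 100 * (1 - alpha)]
    acme_ci = tuple(np.percentile(boots[:, 0], qs))
    ade_ci = tuple(np.percentile(boots[:, 1], qs))
    total_ci = tuple(np.percentile(boots.sum(axis=1), qs))
    prop = acme / total if abs(total) > 1e-12 else np.nan
    return MediationResult(
        acme=float(acme),
        acme_ci=acme_ci,
        ade=float(ade),
        ade_ci=ade_ci,
        total=float(total),
        total_ci=total_ci,
        prop_mediated=float(prop),
        n_boot=n_boot,
        ci_level=ci_level,
    )


# -------------------------------------------------------------------------
# Spearman-correlation hierarchical clustering of the panel
# -------------------------------------------------------------------------

def cluster_metabolites(X_panel: pd.DataFrame, alpha: float = 0.05):
    """Spearman correlation structure of the selected metabolites.

    Returns the Spearman rho matrix over subjects, a significance mask
    (p < ``alpha``, unadjusted), the average-linkage tree on distance
    1 - rho, and the deterministic leaf order.  Constant metabolite columns
    (rho undefined) are dropped with a warning.
    """
    if X_panel.shape[1] < 3:
        raise PreconditionError("need >= 3 metabolites to cluster")
    const = X_panel.columns[X_panel.nunique() <= 1]
    if len(const):
        log.warning("dropping %d constant metabolites: %s", len(const), list(const))
        X_panel = X_panel.drop(columns=list(const))
    if X_panel.shape[1] < 3:
        raise PreconditionError("fewer than 3 non-constant metabolites")
    rho, pval = stats.spearmanr(X_panel.to_numpy(float), axis=0)
    cols = X_panel.columns
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    mask = p_df < alpha
    np.fill_diagonal(mask.values, False)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return rho_df, mask, Z, [cols[i] for i in leaves]
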