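"""Independent oracle implementations used only by the test suite.

These deliberately share no code with the package: the SIMPLS algorithm
(de Jong 1993) cross-checks the NIPALS fit, brute-force pair counting
cross-checks the rank-based AUC, and a literal transcription of the VIP
formula cross-checks the vectorized VIP computation.
"""

import numpy as np


def simpls_predict(X_train, y_train, X_test, n_lv):
    """SIMPLS regression predictions for a single centered response."""
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    X0 = X_train - x_mean
    y0 = y_train - y_mean

    n, p = X0.shape
    S = X0.T @ y0  # p-vector (univariate response)
    R = np.zeros((p, n_lv))
    V = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    for a in range(n_lv):
        r = S.copy()
        t = X0 @ r
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            R = R[:, :a]
            Q = Q[:a]
            break
        t /= normt
        r /= normt
        pvec = X0.T @ t
        Q[a] = float(y0 @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v /= np.linalg.norm(v)
        S = S - v * (v @ S)
        R[:, a] = r
        V[:, a] = v
    b = R @ Q
    return (np.asarray(X_test, float) - x_mean) @ b + y_mean


def auc_bruteforce(scores, labels):
    """AUC by exhaustive positive-negative pair counting, ties worth 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def vip_literal(W, q, tt):
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ),
    transcribed term by term with explicit loops."""
    p, A = W.shape
    ssy = [q[a] ** 2 * tt[a] for a in range(A)]
    denom = sum(ssy)
    out = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wnorm = np.sqrt(sum(W[k, a] ** 2 for k in range(p)))
            acc += ssy[a] * (W[j, a] / wnorm) ** 2
        out[j] = np.sqrt(p * acc / denom)
    return out
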