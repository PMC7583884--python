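"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive results through a different route than the
package (naive Gram-Schmidt, explicit normal equations, high-precision
arithmetic) so implementation and check never share code.
"""

import numpy as np
from sklearn.model_selection import KFold


def haugh_unit_highprec(h, w):
    """Haugh unit via mpmath 50-digit arithmetic."""
    import mpmath

    with mpmath.workdps(50):
        arg = mpmath.mpf(h) + mpmath.mpf("7.57") \
            - mpmath.mpf("1.7") * mpmath.mpf(w) ** mpmath.mpf("0.37")
        return float(100 * mpmath.log10(arg))


def ols_line(x, y):
    """Closed-form normal-equations OLS slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def pca_scores_eig(X, n_components):
    """PCA scores via eigendecomposition of the covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return Xc @ vecs[:, order[:n_components]], vals[order]


def fisher_ratio(X, y):
    """Between/within variance ratio summed over bands."""
    classes = np.unique(y)
    gm = X.mean(axis=0)
    nb = sum((X[y == c].shape[0]) * (X[y == c].mean(axis=0) - gm) ** 2
             for c in classes)
    nw = sum(((X[y == c] - X[y == c].mean(axis=0)) ** 2).sum(axis=0)
             for c in classes)
    return float((nb / np.maximum(nw, 1e-12)).sum())


def spa_bruteforce(X, y, m_min, m_max, seed):
    """Exhaustive SPA: naive Gram-Schmidt chain per start, explicit CV RMSE.

    Returns (best_rmse, sorted band list).
    """
    n, p = X.shape
    kf = KFold(5, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    scale = max(1.0, np.linalg.norm(X, axis=0).max())
    best = None
    for start in range(p):
        chain = [start]
        basis = []
        for _ in range(m_max - 1):
            v = X[:, chain[-1]].astype(float).copy()
            for b in basis:
                v -= (b @ v) * b
            nv = np.linalg.norm(v)
            if nv <= 1e-10 * scale:
                chain.pop()
                break
            basis.append(v / nv)
            B = np.array(basis)
            R = X - B.T @ (B @ X)
            norms = np.linalg.norm(R, axis=0)
            norms[chain] = -1
            nxt = int(np.argmax(norms))
            if norms[nxt] <= 1e-10 * scale:
                break
            chain.append(nxt)
        for m in range(m_min, m_max + 1):
            if len(chain) < m:
                continue
            sq, cnt = 0.0, 0
            for tr, va in folds:
                D = np.c_[np.ones(tr.size), X[np.ix_(tr, chain[:m])]]
                coef = np.linalg.lstsq(D, y[tr], rcond=None)[0]
                Dv = np.c_[np.ones(va.size), X[np.ix_(va, chain[:m])]]
                sq += np.sum((Dv @ coef - y[va]) ** 2)
                cnt += va.size
            rmse = np.sqrt(sq / cnt)
            if best is None or rmse < best[0] - 1e-12:
                best = (float(rmse), sorted(chain[:m]))
    return best


def planted_regression(seed, n=200, p=100, k=5, noise=0.5):
    """Random design with k planted informative bands."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    planted = np.sort(rng.choice(p, size=k, replace=False))
    beta = rng.uniform(0.7, 1.2, size=k) * rng.choice([-1.0, 1.0], size=k)
    y = X[:, planted] @ beta + rng.normal(scale=noise, size=n)
    return X, y, planted
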