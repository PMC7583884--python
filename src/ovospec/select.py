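"""Wavelength selection: PCA score reduction, SPA, CARS, and the PLS core.

* PCA: project onto the first principal components of the training spectra
  (scores become the classifier features); per-component contribution rates
  are the eigenvalue shares.
* SPA (successive projections algorithm): from every starting band grow a
  chain in which each new band has the largest residual norm after
  projecting out the span of the chain so far (minimally collinear sets);
  chains of length m_min..m_max are scored by cross-validated RMSE of a
  multiple linear regression on y, and the global minimum wins.
* CARS (competitive adaptive reweighted sampling): Monte-Carlo runs fit a
  PLS model on a random 80% sample of the training set, weight bands by
  |regression coefficient|, enforce an exponentially decaying retention
  schedule (all p bands at run 1 down to 2 at run N), resample the survivors
  adaptively in proportion to their weights, and record each survivor set's
  cross-validated RMSECV; the run with minimum RMSECV supplies the selected
  bands.

The regression target y is the numeric grade code 1..4 unless a different
vector is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold


@dataclass
class PlsModel:
    """PLS1 regression on centered data (coefficients on original bands)."""

    n_components: int
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.coefficients


def pls_fit(X, y, n_components: int) -> PlsModel:
    """Fit PLS1 with ``n_components`` latent variables.

    ``n_components`` may not exceed min(n_samples - 1, n_bands) nor the rank
    of the centered design.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("PLS requires at least 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    cap = min(n - 1, p)
    if n_components > cap:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_bands)={cap}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cross = Xc.T @ yc
    scale = max(np.linalg.norm(Xc), 1.0) * max(np.linalg.norm(yc), 1.0)
    if np.linalg.norm(cross) <= 1e-12 * scale:
        # y carries no covariance with any band: every PLS direction is
        # degenerate and the regression vector is exactly zero
        return PlsModel(n_components=n_components,
                        coefficients=np.zeros(p), x_mean=X.mean(axis=0),
                        y_mean=float(y.mean()))
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    return PlsModel(n_components=n_components,
                    coefficients=model.coef_.ravel().copy(),
                    x_mean=model._x_mean.copy(),
                    y_mean=float(np.asarray(model._y_mean).ravel()[0]))


@dataclass
class SelectionResult:
    """Outcome of one selector: indices (sorted, unique) plus diagnostics."""

    method: str
    selected_band_indices: np.ndarray
    projected_train: Optional[np.ndarray] = None
    projected_test: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.selected_band_indices, dtype=int)
        if idx.size and (np.unique(idx).size != idx.size):
            raise ValueError("selected band indices must be unique")
        self.selected_band_indices = np.sort(idx)

    def to_json_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v
        return {"method": self.method,
                "selected_band_indices": self.selected_band_indices.tolist(),
                "diagnostics": _clean(self.diagnostics)}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_reduce(X_train, X_test=None, n_components: int = 3) -> SelectionResult:
    """Scores of the first principal components (centered on training data).

    Diagnostics carry per-component contribution rates (eigenvalue share, %)
    over *all* components (summing to 100) and the cumulative contribution of
    the top 20.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    # economy SVD: eigenvalues of the covariance are s^2 / (n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    contributions = 100.0 * var / var.sum()
    scores_train = Xc @ Vt[:n_components].T
    scores_test = None
    if X_test is not None:
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        scores_test = (X_test - mean) @ Vt[:n_components].T
    top = min(20, contributions.size)
    return SelectionResult(
        method="pca",
        selected_band_indices=np.array([], dtype=int),
        projected_train=scores_train,
        projected_test=scores_test,
        diagnostics={
            "contribution_pct": contributions,
            "cumulative_top20_pct": np.cumsum(contributions[:top]),
            "n_components": n_components,
            "loadings": Vt[:n_components],
        })


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(X: np.ndarray, start: int, m_max: int,
               tol: float = 1e-10) -> list[int]:
    """Successive-projection chain from ``start``: each next band maximises
    the residual norm after projecting out the chain's span.  Stops early if
    every remaining residual is (numerically) zero."""
    n, p = X.shape
    R = X.copy()
    norms0 = np.linalg.norm(X, axis=0)
    scale = norms0.max() if norms0.max() > 0 else 1.0
    chain = [start]
    for _ in range(m_max - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= tol * scale:
            chain.pop()           # last pick was degenerate
            break
        v = v / nv
        R = R - np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol * scale:
            break
        chain.append(nxt)
    return chain


def _cv_mlr_rmse(X: np.ndarray, y: np.ndarray, chains: np.ndarray, m: int,
                 folds: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Batched k-fold RMSE of MLR on each chain's first m bands.

    Solves per-chain normal equations in one batched call per fold.
    """
    n_chains = chains.shape[0]
    sq = np.zeros(n_chains)
    count = 0
    for tr, va in folds:
        Xtr = X[tr]
        Xva = X[va]
        # design tensors: (chains, n_fold, m+1) with intercept column
        D_tr = np.concatenate(
            [np.ones((n_chains, tr.size, 1)),
             np.transpose(Xtr[:, chains[:, :m]], (1, 0, 2))], axis=2)
        D_va = np.concatenate(
            [np.ones((n_chains, va.size, 1)),
             np.transpose(Xva[:, chains[:, :m]], (1, 0, 2))], axis=2)
        G = np.einsum("cnm,cnk->cmk", D_tr, D_tr)
        G += 1e-10 * np.eye(m + 1)
        b = np.einsum("cnm,n->cm", D_tr, y[tr])
        coef = np.linalg.solve(G, b[..., None])[..., 0]
        pred = np.einsum("cnm,cm->cn", D_va, coef)
        sq += np.sum((pred - y[va]) ** 2, axis=1)
        count += va.size
    return np.sqrt(sq / count)


def spa_select(X_train, y, m_min: int = 5, m_max: int = 30,
               cv_folds: int = 5, seed: int = 0) -> SelectionResult:
    """SPA over all starting bands and chain lengths m_min..m_max.

    Returns the chain with minimum cross-validated MLR RMSE; diagnostics
    carry the RMSE-vs-m curve (minimum over starts at each m).
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if m_max >= p:
        raise ValueError(f"m_max={m_max} must be < n_bands={p}")
    if m_min < 1 or m_min > m_max:
        raise ValueError("need 1 <= m_min <= m_max")

    chains = [_spa_chain(X, start, m_max) for start in range(p)]
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr, va) for tr, va in kf.split(X)]

    best = None   # (rmse, m, start)
    rmse_curve: dict[int, float] = {}
    for m in range(m_min, m_max + 1):
        full = np.array([c[:m] for c in chains if len(c) >= m])
        starts = np.array([c[0] for c in chains if len(c) >= m])
        if full.size == 0:
            continue
        rmse = _cv_mlr_rmse(X, y, full, m, folds)
        i = int(np.argmin(rmse))
        rmse_curve[m] = float(rmse[i])
        if best is None or rmse[i] < best[0]:
            best = (float(rmse[i]), m, int(starts[i]),
                    np.array(full[i], dtype=int))
    if best is None:
        raise ValueError("no SPA chain reached the requested length; "
                         "data are too collinear")
    rmse_min, m_best, start_best, chain_best = best
    return SelectionResult(
        method="spa",
        selected_band_indices=chain_best,
        diagnostics={
            "rmse_by_m": rmse_curve,
            "best_m": m_best,
            "best_rmse": rmse_min,
            "best_start": start_best,
        })


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_schedule(p: int, n_runs: int) -> np.ndarray:
    """Enforced-retention counts per run: exponential decay from p to 2.

    ratio r_i = a·exp(−k·i) with a = (p/2)^(1/(N−1)) and
    k = ln(p/2)/(N−1), so r_1·p = p and r_N·p = 2 exactly.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if p < 2:
        raise ValueError("need at least 2 bands")
    i = np.arange(1, n_runs + 1)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    counts = np.rint(a * np.exp(-k * i) * p).astype(int)
    counts[0] = p          # guard float round-off at the exact endpoints
    counts[-1] = 2
    return counts


def _pick_components(X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int,
                     cap: int = 10) -> int:
    """Choose the PLS component count by k-fold RMSECV on the full data."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    max_a = max(1, min(cap, rank, n - 1 - (n // cv_folds)))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    best_a, best_rmse = 1, np.inf
    for a in range(1, max_a + 1):
        sq, cnt = 0.0, 0
        ok = True
        for tr, va in folds:
            try:
                m = pls_fit(X[tr], y[tr], a)
            except ValueError:
                ok = False
                break
            sq += float(np.sum((m.predict(X[va]) - y[va]) ** 2))
            cnt += va.size
        if not ok:
            break
        rmse = np.sqrt(sq / cnt)
        if rmse < best_rmse:
            best_a, best_rmse = a, rmse
    return best_a


def _rmsecv_pls(X: np.ndarray, y: np.ndarray, bands: np.ndarray,
                n_components: int, folds) -> float:
    sq, cnt = 0.0, 0
    for tr, va in folds:
        a = max(1, min(n_components, bands.size, tr.size - 1))
        sub = X[np.ix_(tr, bands)]
        rank = np.linalg.matrix_rank(sub - sub.mean(axis=0))
        a = max(1, min(a, rank))
        m = pls_fit(sub, y[tr], a)
        sq += float(np.sum((m.predict(X[np.ix_(va, bands)]) - y[va]) ** 2))
        cnt += va.size
    return float(np.sqrt(sq / cnt))


def cars_select(X_train, y, n_runs: int = 100, cv_folds: int = 5,
                mc_fraction: float = 0.8, seed: int = 0) -> SelectionResult:
    """Competitive adaptive reweighted sampling over ``n_runs`` MC runs.

    Diagnostics: per-run enforced schedule counts, post-resampling survivor
    counts, the RMSECV curve, and the winning run index.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    schedule = cars_schedule(p, n_runs)
    n_comp = _pick_components(X, y, cv_folds, seed)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    retained = np.arange(p)
    survivor_counts: list[int] = []
    rmsecv: list[float] = []
    subsets: list[np.ndarray] = []
    n_sub = max(3, int(round(mc_fraction * n)))
    for i in range(n_runs):
        if retained.size < 2:
            break
        sample = rng.choice(n, size=n_sub, replace=False)
        sub = X[np.ix_(sample, retained)]
        a = max(1, min(n_comp, retained.size, n_sub - 1))
        rank = np.linalg.matrix_rank(sub - sub.mean(axis=0))
        a = max(1, min(a, rank))
        model = pls_fit(sub, y[sample], a)
        w = np.abs(model.coefficients)
        if w.sum() == 0.0:
            w = np.ones_like(w)
        w = w / w.sum()

        # enforced retention: top bands of the exponential schedule
        k = min(int(schedule[i]), retained.size)
        top = np.argsort(w)[::-1][:k]
        retained = retained[np.sort(top)]
        w_top = w[np.sort(top)]

        # adaptive reweighted sampling: weighted resample, unique survivors
        draw = rng.choice(retained.size, size=retained.size, replace=True,
                          p=w_top / w_top.sum())
        retained = retained[np.unique(draw)]

        survivor_counts.append(int(retained.size))
        subsets.append(retained.copy())
        rmsecv.append(_rmsecv_pls(X, y, retained, n_comp, folds))

    if not rmsecv:
        raise ValueError("CARS performed no runs")
    winner = int(np.argmin(rmsecv))
    return SelectionResult(
        method="cars",
        selected_band_indices=subsets[winner],
        diagnostics={
            "schedule_counts": schedule[:len(rmsecv)],
            "survivor_counts": np.array(survivor_counts),
            "rmsecv": np.array(rmsecv),
            "winning_run": winner,
            "n_components": n_comp,
        })
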