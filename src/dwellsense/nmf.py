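"""Non-negative matrix factorisation of SFP data matrices and feature-space clustering.

The six-hour SFP matrix V (features x windows) is approximated by W @ H with
W, H >= 0, solved by alternating constrained least squares (ACLS): each block
update is a ridge-regularised least-squares solve followed by clipping
negatives to zero.  Multiple random restarts are run and the factorisation
with the smallest Frobenius residual is kept.  Windows are then clustered by
their coordinates in the r-dimensional feature space (columns of H), with the
number of clusters chosen by the silhouette coefficient — the number of
latent features r and the number of clusters k are deliberately decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class NMFModel:
    W: np.ndarray  # m x r, >= 0
    H: np.ndarray  # r x n, >= 0
    rank: int
    residual: float  # ||V - WH||_F
    converged: bool
    n_iter: int
    n_init: int
    seed: int | None
    objective_history: list[float] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray  # 1-based, length n
    centroids: np.ndarray  # k x r
    silhouette: float | None
    degenerate: bool = False


def _frobenius_sq(V, W, H) -> float:
    R = V - W @ H
    return float(np.sum(R * R))


def _acls_single(V, r, rng, max_iter, tol, ridge):
    m, n = V.shape
    scale = np.sqrt(V.mean() / max(r, 1)) if V.mean() > 0 else 1.0
    W = rng.uniform(0, 1, size=(m, r)) * scale + 1e-9
    H = rng.uniform(0, 1, size=(r, n)) * scale + 1e-9
    eye = ridge * np.eye(r)
    history = [_frobenius_sq(V, W, H)]
    best = (history[0], W, H)
    converged = False
    stall = 0
    for _ in range(max_iter):
        # H-block: min ||V - WH||^2 + ridge||H||^2, then clip.
        H = np.linalg.solve(W.T @ W + eye, W.T @ V)
        np.maximum(H, 0.0, out=H)
        # W-block.
        W = np.linalg.solve(H @ H.T + eye, H @ V.T).T
        np.maximum(W, 0.0, out=W)
        obj = _frobenius_sq(V, W, H)
        # Clipping can transiently raise the objective; keep iterating with a
        # short patience window and report only the accepted (improving)
        # iterates, so the recorded descent curve is monotone.
        if obj < best[0]:
            rel = (best[0] - obj) / max(best[0], 1e-300)
            best = (obj, W, H)
            history.append(obj)
            stall = 0
            if rel < tol:
                converged = True
                break
        else:
            stall += 1
            if stall >= 5:
                converged = True
                break
    _, W, H = best
    return W, H, history, converged


def acls_nmf(
    V: np.ndarray,
    rank: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_init: int = 10,
    seed: int | None = 0,
    ridge: float = 1e-4,
) -> NMFModel:
    """Factorise a non-negative matrix by ACLS with random restarts.

    Of ``n_init`` random initialisations the factorisation with the smallest
    Frobenius residual is returned.  The recorded objective history of the
    winning restart is non-increasing: any update step that would raise the
    objective (possible because non-negativity is enforced by clipping) is
    rejected and the solve stops at the previous iterate.

    Parameters
    ----------
    V : array (m, n), entrywise >= 0
    rank : target number of latent factors, ``1 <= rank < min(m, n)``
    ridge : Tikhonov term added to each block solve for numerical stability.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if (V < 0).any():
        raise ValueError("V must be entrywise non-negative")
    m, n = V.shape
    if not 1 <= rank < min(m, n):
        raise ValueError(f"rank must satisfy 1 <= r < min(m, n) = {min(m, n)}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        W, H, history, converged = _acls_single(V, rank, rng, max_iter, tol, ridge)
        obj = history[-1]
        if best is None or obj < best[2][-1]:
            best = (W, H, history, converged)
    W, H, history, converged = best
    return NMFModel(
        W=W,
        H=H,
        rank=rank,
        residual=float(np.sqrt(history[-1])),
        converged=converged,
        n_iter=len(history) - 1,
        n_init=n_init,
        seed=seed,
        objective_history=[float(x) for x in history],
    )


def select_rank(
    V: np.ndarray,
    r_range=range(1, 7),
    improvement_frac: float = 0.05,
    zero_tol: float = 1e-6,
    **nmf_kwargs,
) -> tuple[int, dict[int, float]]:
    """Choose the factorisation rank from the RMS residual curve.

    Fits every rank in ``r_range`` and returns the rank at the elbow of the
    root-mean-square residual curve: the smallest r after which adding a
    factor improves the relative residual by less than ``improvement_frac``.
    A rank whose residual is already numerically zero (relative to the RMS
    magnitude of V) is returned immediately.
    """
    ranks = sorted(r_range)
    if not ranks:
        raise ValueError("empty rank range")
    V = np.asarray(V, dtype=float)
    mn = V.size
    rms_v = float(np.sqrt((V * V).sum() / mn))
    curve: dict[int, float] = {}
    for r in ranks:
        model = acls_nmf(V, r, **nmf_kwargs)
        curve[r] = model.residual / np.sqrt(mn)
    chosen = ranks[-1]
    for i, r in enumerate(ranks):
        if curve[r] <= zero_tol * max(rms_v, 1e-300):
            chosen = r
            break
        if i > 0:
            prev = curve[ranks[i - 1]]
            improvement = (prev - curve[r]) / max(prev, 1e-300)
            if improvement < improvement_frac:
                chosen = ranks[i - 1]
                break
    return chosen, curve


def l1_normalise_columns(X: np.ndarray) -> np.ndarray:
    """Scale each column to unit L1 norm; all-zero columns stay zero."""
    X = np.asarray(X, dtype=float)
    norms = np.abs(X).sum(axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe


def cluster_feature_space(
    model: NMFModel,
    k_range=range(2, 11),
    seed: int | None = 0,
    normalise: bool = True,
    n_init: int = 10,
) -> ClusterAssignment:
    """Partition windows by their feature-space coordinates (columns of H).

    k-means is run for each candidate k and the k with the highest mean
    silhouette is kept.  Coordinates are L1-normalised first so that cluster
    geometry reflects the *shape* of a window's activity pattern rather than
    its overall intensity.  If every window has identical coordinates the
    assignment degenerates to a single cluster with an undefined silhouette.
    """
    X = model.H.T  # n x r
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 windows to cluster")
    if normalise:
        X = l1_normalise_columns(X.T).T
    if np.allclose(X, X[0], atol=1e-12):
        return ClusterAssignment(
            k=1,
            labels=np.ones(n, dtype=int),
            centroids=X[:1].copy(),
            silhouette=None,
            degenerate=True,
        )
    best = None
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("no feasible k in range")
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(X, labels))
        if best is None or sil > best[0]:
            best = (sil, k, labels, km.cluster_centers_)
    if best is None:  # every k collapsed; treat as degenerate
        return ClusterAssignment(
            k=1, labels=np.ones(n, dtype=int), centroids=X[:1].copy(),
            silhouette=None, degenerate=True,
        )
    sil, k, labels, centroids = best
    return ClusterAssignment(
        k=k, labels=labels + 1, centroids=centroids, silhouette=sil
    )
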