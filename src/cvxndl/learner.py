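"""Online convex network dictionary learning.

The learner consumes a stream of flattened k x k subnetwork patches
``x_t`` and maintains K dictionary elements.  Each step solves a
nonnegative sparse-coding problem

    Lambda_t = argmin_{L >= 0} ||x_t - D L||^2 + lam * ||L||_1,

updates the aggregated history

    A_t = (1 - w_t) A_{t-1} + w_t Lambda Lambda^T,
    B_t = (1 - w_t) B_{t-1} + w_t Lambda x^T,        w_t = 1/t,

and updates the dictionary by minimizing the quadratic surrogate

    Tr(D A_t D^T) - 2 Tr(D B_t)

under the convexity constraint: each element D[:, j] must be a convex
combination of its *representative set* — a capacity-bounded collection of
real sampled patches.  The newly observed patch is offered to the nearest
element's representative set; one member (possibly the newcomer itself) is
removed so the column-restricted surrogate objective is minimized.  The
output therefore has the interpretable form

    D[:, j] = sum_i w_{j,i} X_hat(j)[:, i],   w on the probability simplex,

so every element is itself a weighted overlay of subnetworks that actually
occur in the data.

A non-convex online NDL baseline (identical coding and history, classic
block-coordinate dictionary update with a [0, 1] box instead of the convex
hull constraint) is provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from numba import njit
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

__all__ = [
    "CodingConfig",
    "Dictionary",
    "TrainingState",
    "initialize",
    "sparse_code",
    "assign_nearest",
    "update_history",
    "solve_convex_weights",
    "update_representatives",
    "fit",
    "fit_online_ndl",
    "importance_scores",
    "density",
    "median_adjacent_distance",
    "project_simplex",
    "simplex_qp",
]


@dataclass
class CodingConfig:
    """Tunable parameters of the online learner.

    Parameters
    ----------
    lam : float
        L1 sparsity weight on the codes (>= 0).
    K : int
        Number of dictionary elements.
    k : int
        Path template length; sample dimension is d = k**2.
    n_max : int
        Representative-set capacity per element.
    min_reps : int
        Minimum representatives per element at initialization.
    max_iters : int
        Online iteration cap ("up to 1 million times").
    tol : float
        Relative change of the windowed surrogate loss below which the fit
        is declared converged.
    window : int
        Window length (steps) for the convergence check.
    """

    lam: float = 1.0
    K: int = 25
    k: int = 21
    n_max: int = 10
    min_reps: int = 10
    max_iters: int = 1_000_000
    tol: float = 1e-4
    window: int = 500

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @property
    def d(self) -> int:
        return self.k * self.k


# ---------------------------------------------------------------------------
# simplex machinery


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex."""
    v = np.asarray(v, dtype=np.float64)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@njit(cache=True)
def _project_simplex_nb(v):
    m = v.shape[0]
    u = np.sort(v)[::-1]
    css = 0.0
    theta = 0.0
    rho = -1
    run = 0.0
    for i in range(m):
        run += u[i]
        if u[i] * (i + 1) > run - 1.0:
            rho = i
            css = run
    theta = (css - 1.0) / (rho + 1.0)
    out = v - theta
    for i in range(m):
        if out[i] < 0.0:
            out[i] = 0.0
    return out


@njit(cache=True)
def _simplex_qp_nb(G, c, a, w0, max_iter, kkt_tol):
    # FISTA with gradient-based adaptive restart on the simplex
    m = c.shape[0]
    # power iteration for the largest eigenvalue of G (PSD)
    z = np.full(m, 1.0 / m)
    lmax = 1e-12
    for _ in range(60):
        z2 = G @ z
        nrm = np.sqrt((z2 * z2).sum())
        if nrm < 1e-300:
            break
        lmax = nrm / np.sqrt((z * z).sum())
        z = z2 / nrm
    L = 2.0 * a * max(lmax, 1e-12)
    scale = max(a * np.abs(G).max(), np.abs(c).max())
    scale = max(scale, 1.0)
    w = w0.copy()
    y = w0.copy()
    tt = 1.0
    for _ in range(max_iter):
        grad_w = 2.0 * (a * (G @ w) + c)
        gmin = grad_w[0]
        gact = -np.inf
        for i in range(m):
            if grad_w[i] < gmin:
                gmin = grad_w[i]
            if w[i] > 1e-12 and grad_w[i] > gact:
                gact = grad_w[i]
        if gact - gmin <= kkt_tol * scale:
            break
        grad_y = 2.0 * (a * (G @ y) + c)
        w_new = _project_simplex_nb(y - grad_y / L)
        # restart momentum when it points against the descent direction
        restart = 0.0
        for i in range(m):
            restart += (y[i] - w_new[i]) * (w_new[i] - w[i])
        if restart > 0.0:
            tt = 1.0
            y = w.copy()
            grad_y = grad_w
            w_new = _project_simplex_nb(y - grad_y / L)
        tt_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tt * tt))
        y = w_new + ((tt - 1.0) / tt_new) * (w_new - w)
        moved = np.abs(w_new - w).max()
        w = w_new
        tt = tt_new
        if moved < 1e-16:
            break
    return w


def simplex_qp(
    G: np.ndarray,
    c: np.ndarray,
    a: float,
    w0: np.ndarray | None = None,
    max_iter: int = 10_000,
    kkt_tol: float = 1e-6,
) -> np.ndarray:
    """Minimize a * w'Gw + 2 c'w over the probability simplex.

    Accelerated projected gradient (FISTA with adaptive restart) at the
    1/L step, L from the largest eigenvalue of 2aG.  When a == 0 the
    objective is linear and the optimum is the vertex with smallest c.
    Terminates on the KKT residual: max over active coordinates of
    grad_i - min_j grad_j, relative to the problem scale.
    """
    m = len(c)
    if m == 1:
        return np.ones(1)
    if a <= 0:
        w = np.zeros(m)
        w[int(np.argmin(c))] = 1.0
        return w
    w0 = np.full(m, 1.0 / m) if w0 is None else np.asarray(w0, dtype=np.float64)
    return _simplex_qp_nb(
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(c, dtype=np.float64),
        float(a),
        np.ascontiguousarray(w0),
        max_iter,
        kkt_tol,
    )


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrainingState:
    """Per-fit bookkeeping: step counter, losses and convergence flag."""

    t: int = 0
    f_t: float = 0.0
    f_hat_t: float = 0.0
    converged: bool = False
    assignments: list[int] = field(default_factory=list)
    loss_trace: list[tuple[int, float, float]] = field(default_factory=list)


class Dictionary:
    """K convex dictionary elements with their representative sets.

    Each element j holds a d x N_j matrix of real sampled patches
    (``reps[j]``), a simplex weight vector (``weights[j]``) and, when
    available, the sampled node tuples behind each representative.  The
    element itself is ``reps[j] @ weights[j]``.  ``A_hist`` (K x K) and
    ``B_hist`` (K x d) aggregate the code/data history.
    """

    def __init__(
        self,
        reps: list[np.ndarray],
        weights: list[np.ndarray],
        rep_tuples: list[np.ndarray] | None = None,
        config: CodingConfig | None = None,
    ):
        self.reps = [np.asarray(r, dtype=np.float64) for r in reps]
        self.weights = [np.asarray(w, dtype=np.float64) for w in weights]
        self.rep_tuples = rep_tuples
        self.config = config
        K = len(self.reps)
        d = self.reps[0].shape[0]
        self.A_hist = np.zeros((K, K))
        self.B_hist = np.zeros((K, d))
        self.t = 0
        self._D = np.column_stack(
            [self.reps[j] @ self.weights[j] for j in range(K)]
        )

    @property
    def K(self) -> int:
        return len(self.reps)

    @property
    def d(self) -> int:
        return self.reps[0].shape[0]

    @property
    def D(self) -> np.ndarray:
        """The d x K dictionary matrix (columns are elements)."""
        return self._D

    def n_reps(self) -> list[int]:
        return [r.shape[1] for r in self.reps]

    def set_element(self, j: int, reps: np.ndarray, w: np.ndarray,
                    tuples: np.ndarray | None = None) -> None:
        self.reps[j] = reps
        self.weights[j] = w
        if self.rep_tuples is not None and tuples is not None:
            self.rep_tuples[j] = tuples
        self._D[:, j] = reps @ w

    def validate(self, n_max: int | None = None) -> None:
        """Check the convex-interpretability invariants.

        Raises AssertionError if any element fails to reconstruct from its
        representatives and simplex weights, or entries leave [0, 1].
        """
        for j in range(self.K):
            w = self.weights[j]
            assert np.all(w >= -1e-12), f"element {j}: negative weight"
            assert abs(w.sum() - 1.0) <= 1e-10, f"element {j}: weights off simplex"
            resid = np.linalg.norm(self._D[:, j] - self.reps[j] @ w)
            assert resid <= 1e-8, f"element {j}: convexity residual {resid}"
            assert self._D[:, j].min() >= -1e-12 and self._D[:, j].max() <= 1 + 1e-12
            if n_max is not None:
                assert self.reps[j].shape[1] <= n_max

    def save(self, path, **extra) -> None:
        payload = {
            "D": self.D,
            "A_hist": self.A_hist,
            "B_hist": self.B_hist,
            "t": self.t,
            "K": self.K,
        }
        for j in range(self.K):
            payload[f"reps_{j}"] = self.reps[j]
            payload[f"weights_{j}"] = self.weights[j]
            if self.rep_tuples is not None:
                payload[f"tuples_{j}"] = self.rep_tuples[j]
        payload.update(extra)
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "Dictionary":
        with np.load(path) as z:
            K = int(z["K"])
            reps = [z[f"reps_{j}"] for j in range(K)]
            weights = [z[f"weights_{j}"] for j in range(K)]
            tuples = None
            if f"tuples_0" in z:
                tuples = [z[f"tuples_{j}"] for j in range(K)]
            dic = cls(reps, weights, rep_tuples=tuples)
            dic.A_hist = z["A_hist"]
            dic.B_hist = z["B_hist"]
            dic.t = int(z["t"])
        return dic


# ---------------------------------------------------------------------------
# operations


def initialize(
    pool: np.ndarray,
    K: int,
    min_reps: int = 10,
    rng: np.random.Generator | None = None,
    rep_tuples: np.ndarray | None = None,
    config: CodingConfig | None = None,
) -> Dictionary:
    """Initialize K elements from a pool of sampled patches.

    The pool (T x d, T >= K * min_reps) is partitioned into K groups by
    k-means on the flattened patches; groups below ``min_reps`` are topped
    up by moving the nearest members of surplus groups.  Weights start
    uniform, so each element is its group mean.
    """
    pool = np.asarray(pool, dtype=np.float64)
    T = pool.shape[0]
    if T < K * min_reps:
        raise ValueError(
            f"initialization pool of {T} patches is too small: "
            f"need at least K*min_reps = {K * min_reps}"
        )
    rng = np.random.default_rng() if rng is None else rng
    if K == 1:
        labels = np.zeros(T, dtype=int)
    else:
        km = KMeans(
            n_clusters=K,
            n_init=10,
            random_state=int(rng.integers(2**31)),
        ).fit(pool)
        labels = km.labels_.copy()
    # rebalance: every group must reach min_reps real members
    for _ in range(T):
        sizes = np.bincount(labels, minlength=K)
        deficient = np.flatnonzero(sizes < min_reps)
        if deficient.size == 0:
            break
        g = deficient[np.argmin(sizes[deficient])]
        centroid = (
            pool[labels == g].mean(axis=0) if sizes[g] > 0 else pool.mean(axis=0)
        )
        donors = np.flatnonzero(sizes > min_reps)
        cand = np.flatnonzero(np.isin(labels, donors))
        dist = np.linalg.norm(pool[cand] - centroid, axis=1)
        labels[cand[np.argmin(dist)]] = g
    reps, weights, tuples = [], [], []
    for j in range(K):
        idx = np.flatnonzero(labels == j)
        reps.append(pool[idx].T.copy())
        weights.append(np.full(len(idx), 1.0 / len(idx)))
        if rep_tuples is not None:
            tuples.append(rep_tuples[idx].copy())
    return Dictionary(
        reps,
        weights,
        rep_tuples=tuples if rep_tuples is not None else None,
        config=config,
    )


def sparse_code(x: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Nonnegative sparse coding of one sample against the dictionary.

    Solves ``argmin_{L >= 0} ||x - D L||^2 + lam ||L||_1``.  With lam = 0
    this is NNLS; otherwise a nonnegative lasso (coordinate descent).
    """
    x = np.asarray(x, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(D))):
        raise ValueError("non-finite inputs to sparse_code")
    d = D.shape[0]
    if x.shape[0] != d:
        raise ValueError("dimension mismatch between sample and dictionary")
    if lam == 0:
        code, _ = scipy.optimize.nnls(D, x)
        return code
    # sklearn lasso minimizes (1/2n)||y - Xw||^2 + alpha||w||_1
    model = Lasso(
        alpha=lam / (2.0 * d),
        positive=True,
        fit_intercept=False,
        max_iter=50_000,
        tol=1e-10,
    )
    model.fit(D, x)
    return model.coef_.astype(np.float64)


def assign_nearest(x: np.ndarray, D: np.ndarray) -> int:
    """Index of the dictionary element nearest to x (Euclidean, ties low)."""
    dist = np.linalg.norm(D - np.asarray(x, dtype=np.float64)[:, None], axis=0)
    return int(np.argmin(dist))


def update_history(
    A_hist: np.ndarray,
    B_hist: np.ndarray,
    code: np.ndarray,
    x: np.ndarray,
    t: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One exponential-forgetting history update with w_t = 1/t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    w = 1.0 / t
    code = np.asarray(code, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64).ravel()
    A_new = (1.0 - w) * A_hist + w * np.outer(code, code)
    B_new = (1.0 - w) * B_hist + w * np.outer(code, x)
    return A_new, B_new


def _column_residual(dic: Dictionary, j: int) -> np.ndarray:
    """r_j = sum_{i != j} A[i,j] D[:,i] - B[j,:]^T (independent of column j)."""
    r = dic.D @ dic.A_hist[:, j] - dic.A_hist[j, j] * dic.D[:, j]
    return r - dic.B_hist[j]


def column_objective(dic: Dictionary, j: int, col: np.ndarray) -> float:
    """Surrogate objective restricted to column j evaluated at ``col``."""
    r = _column_residual(dic, j)
    a = dic.A_hist[j, j]
    return float(a * col @ col + 2.0 * col @ r)


def solve_convex_weights(
    X_hat: np.ndarray,
    A_hist: np.ndarray,
    B_hist: np.ndarray,
    j: int,
    D: np.ndarray,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal simplex weights for element j given its representative set.

    Minimizes the column-j restriction of Tr(D A D^T) - 2 Tr(D B) over
    ``D[:, j] = X_hat @ w`` with w on the probability simplex; all other
    columns of D are held fixed.
    """
    m = X_hat.shape[1]
    if m == 0:
        raise ValueError("empty representative set")
    if m == 1:
        return np.ones(1)
    a = float(A_hist[j, j])
    r = D @ A_hist[:, j] - a * D[:, j] - B_hist[j]
    G = X_hat.T @ X_hat
    c = X_hat.T @ r
    if a <= 0:
        # no history for this element yet: fall back to the vertex rule
        # only when the linear term is informative, else keep uniform
        if np.abs(c).max() > 0:
            w = np.zeros(m)
            w[int(np.argmin(c))] = 1.0
            return w
        return np.full(m, 1.0 / m)
    return simplex_qp(G, c, a, w0=w0)


def update_representatives(
    dic: Dictionary,
    j: int,
    x: np.ndarray,
    x_tuple: np.ndarray | None = None,
    n_max: int | None = None,
) -> None:
    """Offer sample x to element j's representative set and update it.

    The sample is appended; while the set exceeds capacity, every removal
    candidate is scored by re-solving the simplex weights on the remaining
    set and evaluating the column-restricted surrogate objective, and the
    removal with the smallest objective is kept.  Removing the newcomer
    itself is always a candidate, so the update never increases the
    column-restricted objective relative to the incumbent set (with
    re-optimized weights).  Ties prefer removing the newcomer (leaving the
    representative set unchanged), then the lowest index.
    """
    n_max = n_max if n_max is not None else (
        dic.config.n_max if dic.config is not None else 10
    )
    x = np.asarray(x, dtype=np.float64)
    X = np.column_stack([dic.reps[j], x])
    tuples = None
    if dic.rep_tuples is not None and x_tuple is not None:
        tuples = np.vstack([dic.rep_tuples[j], np.asarray(x_tuple)[None, :]])
    w_prev = np.append(dic.weights[j], 0.0)

    a = float(dic.A_hist[j, j])
    r = _column_residual(dic, j)

    if X.shape[1] > n_max + 1:
        # over-capacity carryover (large initialization groups): one bulk
        # trim by optimal weight magnitude down to capacity + newcomer,
        # then the regular single-removal search below
        w_full = solve_convex_weights(X, dic.A_hist, dic.B_hist, j, dic.D, w0=w_prev)
        order = np.argsort(w_full[:-1])[::-1]
        keep = np.append(order[:n_max], X.shape[1] - 1)
        X = X[:, keep]
        w_prev = w_full[keep]
        s = w_prev.sum()
        w_prev = w_prev / s if s > 1e-12 else np.full(len(keep), 1.0 / len(keep))
        if tuples is not None:
            tuples = tuples[keep]

    while X.shape[1] > n_max:
        m = X.shape[1]
        newcomer = m - 1
        G = X.T @ X
        c = X.T @ r
        best = None
        for i in range(m):
            keep = np.delete(np.arange(m), i)
            Gs = G[np.ix_(keep, keep)]
            cs = c[keep]
            w0 = w_prev[keep]
            s = w0.sum()
            w0 = w0 / s if s > 1e-12 else np.full(len(keep), 1.0 / len(keep))
            if len(keep) == 1:
                w = np.ones(1)
            elif a <= 0:
                w = np.zeros(len(keep))
                w[int(np.argmin(cs))] = 1.0
            else:
                w = simplex_qp(Gs, cs, a, w0=w0)
            obj = a * w @ Gs @ w + 2.0 * c[keep] @ w
            # tie rule: strictly better wins; the newcomer-removal branch
            # (i == newcomer, evaluated last) wins ties against earlier
            # candidates only if it was not already beaten
            if best is None or obj < best[0] - 1e-12 or (
                i == newcomer and obj <= best[0] + 1e-12
            ):
                best = (obj, i, keep, w)
        _, i_rm, keep, w = best
        X = X[:, keep]
        w_prev = w
        if tuples is not None:
            tuples = tuples[keep]

    if X.shape[1] == dic.reps[j].shape[1] + 1:
        # capacity not reached: keep everything, re-solve weights
        w_prev = solve_convex_weights(
            X, dic.A_hist, dic.B_hist, j, dic.D, w0=w_prev
        )
    dic.set_element(j, X, w_prev, tuples)


def _surrogate_term(x: np.ndarray, D: np.ndarray, code: np.ndarray, lam: float) -> float:
    resid = x - D @ code
    return float(resid @ resid + lam * np.abs(code).sum())


def fit(
    stream,
    dic: Dictionary,
    config: CodingConfig,
    log_every: int = 100,
) -> tuple[Dictionary, TrainingState]:
    """Run the online convex dictionary learning loop over a patch stream.

    Per step: sparse-code the sample against the current dictionary,
    assign it to the nearest element, fold it into the history matrices,
    and update that element's representative set.  Stops when the relative
    change of the windowed surrogate loss falls below ``config.tol`` or at
    ``config.max_iters``; failure to converge is reported on the state and
    logged, never silently accepted.

    ``stream`` yields flattened patches, or (patch, node_tuple) pairs.
    """
    state = TrainingState(t=dic.t)
    window: list[float] = []
    prev_mean: float | None = None
    n_seen = 0
    for item in stream:
        if isinstance(item, tuple):
            x, x_tuple = item
        else:
            x, x_tuple = item, None
        n_seen += 1
        state.t += 1
        dic.t = state.t
        code = sparse_code(x, dic.D, config.lam)
        j = assign_nearest(x, dic.D)
        state.assignments.append(j)
        dic.A_hist, dic.B_hist = update_history(
            dic.A_hist, dic.B_hist, code, x, state.t
        )
        w_t = 1.0 / state.t
        loss = _surrogate_term(x, dic.D, code, config.lam)
        state.f_t = (1.0 - w_t) * state.f_t + w_t * loss
        update_representatives(dic, j, x, x_tuple, n_max=config.n_max)
        loss_post = _surrogate_term(x, dic.D, code, config.lam)
        state.f_hat_t = (1.0 - w_t) * state.f_hat_t + w_t * loss_post
        if state.t % log_every == 0:
            state.loss_trace.append((state.t, state.f_t, state.f_hat_t))
        window.append(state.f_hat_t)
        if len(window) == config.window:
            mean = float(np.mean(window))
            window.clear()
            if prev_mean is not None and abs(mean - prev_mean) <= config.tol * max(
                abs(prev_mean), 1e-12
            ):
                state.converged = True
                break
            prev_mean = mean
        if n_seen >= config.max_iters:
            break
    if n_seen == 0:
        raise ValueError("empty training stream")
    if not state.converged:
        logger.warning(
            "online cvxNDL did not converge within %d steps "
            "(windowed surrogate tol %.1e); declaring failure to converge",
            n_seen,
            config.tol,
        )
    return dic, state


def fit_online_ndl(
    stream,
    D0: np.ndarray,
    config: CodingConfig,
) -> tuple[np.ndarray, TrainingState]:
    """Non-convex online NDL baseline.

    Identical sampling, coding and history aggregation, but the dictionary
    update is the classic block-coordinate step on the surrogate,

        D[:, j] <- clip( D[:, j] + (B[j,:]^T - D A[:,j]) / A[j,j], 0, 1 ),

    with a [0, 1] box in place of the convex-hull constraint.  Returns the
    learned dictionary matrix and the training state.
    """
    D = np.asarray(D0, dtype=np.float64).copy()
    K = D.shape[1]
    A_hist = np.zeros((K, K))
    B_hist = np.zeros((K, D.shape[0]))
    state = TrainingState()
    window: list[float] = []
    prev_mean: float | None = None
    n_seen = 0
    for item in stream:
        x = item[0] if isinstance(item, tuple) else item
        n_seen += 1
        state.t += 1
        code = sparse_code(x, D, config.lam)
        state.assignments.append(assign_nearest(x, D))
        A_hist, B_hist = update_history(A_hist, B_hist, code, x, state.t)
        w_t = 1.0 / state.t
        loss = _surrogate_term(x, D, code, config.lam)
        state.f_t = (1.0 - w_t) * state.f_t + w_t * loss
        for j in range(K):
            if A_hist[j, j] > 1e-12:
                D[:, j] = np.clip(
                    D[:, j] + (B_hist[j] - D @ A_hist[:, j]) / A_hist[j, j],
                    0.0,
                    1.0,
                )
        state.f_hat_t = (1.0 - w_t) * state.f_hat_t + w_t * _surrogate_term(
            x, D, code, config.lam
        )
        window.append(state.f_hat_t)
        if len(window) == config.window:
            mean = float(np.mean(window))
            window.clear()
            if prev_mean is not None and abs(mean - prev_mean) <= config.tol * max(
                abs(prev_mean), 1e-12
            ):
                state.converged = True
                break
            prev_mean = mean
        if n_seen >= config.max_iters:
            break
    if n_seen == 0:
        raise ValueError("empty training stream")
    return D, state


# ---------------------------------------------------------------------------
# summaries


def importance_scores(A_hist: np.ndarray) -> np.ndarray:
    """Normalized squared diagonal of the aggregated code Gram matrix.

    gamma(i) = A[i,i]^2 / sum_j A[j,j]^2; sums to 1.
    """
    diag = np.diag(A_hist).astype(np.float64)
    denom = float((diag**2).sum())
    if denom == 0:
        raise ValueError("no usage recorded: A_hist diagonal is all zero")
    return diag**2 / denom


def density(element: np.ndarray, k: int) -> float:
    """Mean of the k**2 entries of one dictionary element."""
    element = np.asarray(element, dtype=np.float64)
    if element.size != k * k:
        raise ValueError("element size does not match k**2")
    return float(element.mean())


def median_adjacent_distance(rep_tuples: np.ndarray, bin_table) -> float:
    """Median genomic distance between consecutive nodes of representatives.

    For every representative tuple and every consecutive pair of its
    nodes, the absolute distance between bin midpoints is collected (pairs
    on different chromosomes are skipped); the median is returned in bases.
    """
    if rep_tuples is None:
        raise ValueError("node-tuple metadata missing from representatives")
    by_node = bin_table.set_index("node_id")
    mid = (by_node["start"] + by_node["size"] / 2.0).to_dict()
    chrom = by_node["chrom"].to_dict()
    dists = []
    for row in np.atleast_2d(rep_tuples):
        for a, b in zip(row[:-1], row[1:]):
            a, b = int(a), int(b)
            if chrom[a] != chrom[b]:
                continue
            dists.append(abs(mid[a] - mid[b]))
    if not dists:
        raise ValueError("no same-chromosome adjacent pairs found")
    return float(np.median(dists))
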