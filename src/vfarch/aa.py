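"""From-scratch archetypal analysis.

Minimizes ``|| X - A B X ||_F^2`` over row-stochastic A (n x k) and
B (k x n): archetypes ``Z = B X`` are convex combinations of data rows, and
every data row is reconstructed as a convex combination of archetypes.

Solver: alternating projected-gradient descent.  Each block update uses the
exact gradient-Lipschitz step ``1/L`` followed by a Euclidean projection of
every row onto the probability simplex, so the objective is non-increasing
at every inner step (and therefore at every outer iteration).  Restarts use
furthest-sum seeding of B's support; the best restart by final RSS wins.
Archetypes are relabeled AT1..ATk in descending relative weight after the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import nnls

from .grids import COMMON_42, GridMismatchError, build_grid

_EPS = 1e-12


@dataclass
class AAModel:
    k: int
    Z: np.ndarray          # k x p archetypes (TD dB per location)
    A: np.ndarray | None   # n x k weights, rows on the simplex
    B: np.ndarray | None   # k x n mixing, rows on the simplex
    rss: float
    seed: int
    grid_name: str = COMMON_42
    rw_percent: np.ndarray | None = None
    rss_history: list = dc_field(default_factory=list)
    config: dict = dc_field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [f"AT{j + 1}" for j in range(self.k)]

    def to_dict(self) -> dict:
        grid = build_grid(self.grid_name)
        return {
            "k": self.k,
            "grid_name": self.grid_name,
            "locations": [[l.x_deg, l.y_deg] for l in grid],
            "archetypes": self.Z.tolist(),
            "rw_percent": None if self.rw_percent is None else self.rw_percent.tolist(),
            "rss": self.rss,
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @staticmethod
    def from_dict(payload: dict) -> "AAModel":
        Z = np.asarray(payload["archetypes"], dtype=float)
        rw = payload.get("rw_percent")
        return AAModel(
            k=int(payload["k"]),
            Z=Z,
            A=None,
            B=None,
            rss=float(payload["rss"]),
            seed=int(payload["seed"]),
            grid_name=payload["grid_name"],
            rw_percent=None if rw is None else np.asarray(rw, dtype=float),
            config=payload.get("config", {}),
        )


@dataclass
class RSSCurve:
    k_values: list
    rss_values: list
    n: int
    p: int

    def __post_init__(self) -> None:
        if list(self.k_values) != sorted(set(self.k_values)):
            raise ValueError("k_values must be strictly increasing")
        if any(r < 0 for r in self.rss_values):
            raise ValueError("rss_values must be >= 0")

    def to_dict(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "rss_values": [float(r) for r in self.rss_values],
            "n": self.n,
            "p": self.p,
        }


# ---------------------------------------------------------------------------
# Simplex primitives
# ---------------------------------------------------------------------------

def project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of every row of V onto the probability simplex."""
    V = np.asarray(V, dtype=float)
    n, k = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    rho = np.count_nonzero(U - css / ind > 0, axis=1)
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(V - theta[:, None], 0.0)


def simplex_lstsq(M: np.ndarray, y: np.ndarray, polish_iters: int = 500) -> np.ndarray:
    """min ||M w - y||_2 over the probability simplex (M is p x k).

    A penalty-augmented NNLS supplies the active set; the renormalized
    solution is then polished with guarded projected-gradient steps.
    """
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    p, k = M.shape
    scale = max(1.0, float(np.abs(M).max()), float(np.abs(y).max()))
    lam = 1e5 * scale
    M_aug = np.vstack([M, lam * np.ones((1, k))])
    y_aug = np.concatenate([y, [lam]])
    w, _ = nnls(M_aug, y_aug)
    s = w.sum()
    w = np.full(k, 1.0 / k) if s <= _EPS else w / s
    # polish: monotone projected gradient with exact Lipschitz step
    H = M.T @ M
    L = 2.0 * float(np.linalg.eigvalsh(H).max())
    if L <= _EPS:
        return w
    obj = float(np.sum((M @ w - y) ** 2))
    for _ in range(polish_iters):
        g = 2.0 * (H @ w - M.T @ y)
        w_new = project_rows_to_simplex((w - g / L)[None, :])[0]
        obj_new = float(np.sum((M @ w_new - y) ** 2))
        if obj_new > obj:
            break
        if obj - obj_new <= 1e-15 * max(obj, 1.0):
            w, obj = w_new, obj_new
            break
        w, obj = w_new, obj_new
    return w


def furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum selection of k well-spread data row indices."""
    n = X.shape[0]
    if k >= n:
        return np.arange(n)
    start = int(rng.integers(n))
    chosen = [start]
    sumdist = np.linalg.norm(X - X[start], axis=1)
    for _ in range(k - 1):
        cand = sumdist.copy()
        cand[chosen] = -np.inf
        nxt = int(np.argmax(cand))
        chosen.append(nxt)
        sumdist += np.linalg.norm(X - X[nxt], axis=1)
    # classic refinement: drop the random start and re-pick it by the criterion
    if k > 1:
        sumdist -= np.linalg.norm(X - X[start], axis=1)
        cand = sumdist.copy()
        cand[chosen[1:]] = -np.inf
        chosen[0] = int(np.argmax(cand))
    return np.array(chosen)


# ---------------------------------------------------------------------------
# RSS and the solver
# ---------------------------------------------------------------------------

def rss(X: np.ndarray, A: np.ndarray, Z: np.ndarray) -> float:
    """Residual sum of squares || X - A Z ||_F^2."""
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if A.shape[0] != X.shape[0] or A.shape[1] != Z.shape[0] or Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, A {A.shape}, Z {Z.shape}"
        )
    return float(np.sum((X - A @ Z) ** 2))


def _mfista(W: np.ndarray, obj, grad, L: float, iters: int) -> np.ndarray:
    """Monotone accelerated projected gradient over row-simplices.

    Beck-Teboulle MFISTA: the accepted iterate never increases the objective,
    so each block update (and hence each outer sweep) is non-increasing.
    """
    t = 1.0
    Y = W
    f_cur = obj(W)
    for _ in range(iters):
        V = project_rows_to_simplex(Y - grad(Y) / L)
        f_v = obj(V)
        if f_v <= f_cur:
            W_new, f_new = V, f_v
        else:
            W_new, f_new = W, f_cur
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = W_new + (t / t_new) * (V - W_new) + ((t - 1.0) / t_new) * (W_new - W)
        W, f_cur, t = W_new, f_new, t_new
    return W


def _update_A(A: np.ndarray, X: np.ndarray, Z: np.ndarray, iters: int) -> np.ndarray:
    ZZt = Z @ Z.T
    L = 2.0 * float(np.linalg.eigvalsh(ZZt).max())
    if L <= _EPS:
        return A
    XZt = X @ Z.T

    def obj(W):
        return float(np.sum((W @ ZZt) * W) - 2.0 * np.sum(W * XZt))

    def grad(W):
        return 2.0 * (W @ ZZt - XZt)

    return _mfista(A, obj, grad, L, iters)


def _update_B(
    B: np.ndarray, X: np.ndarray, A: np.ndarray, iters: int, xxt_lmax: float
) -> np.ndarray:
    AtA = A.T @ A
    L = 2.0 * float(np.linalg.eigvalsh(AtA).max()) * xxt_lmax
    if L <= _EPS:
        return B
    AtX = A.T @ X

    def obj(W):
        P = W @ X
        return float(np.sum((AtA @ P) * P) - 2.0 * np.sum(AtX * P))

    def grad(W):
        return 2.0 * ((AtA @ (W @ X) - AtX) @ X.T)

    return _mfista(B, obj, grad, L, iters)


def _init_state(X: np.ndarray, k: int, rng: np.random.Generator):
    n = X.shape[0]
    idx = furthest_sum(X, k, rng)
    B = np.zeros((k, n))
    B[np.arange(k), idx] = 1.0
    A = np.full((n, k), 1.0 / k)
    return A, B


def _sweep(state, X, n_sweeps, tol, inner_iter, xxt_lmax, history):
    """Run up to ``n_sweeps`` alternating block updates; monotone in RSS."""
    A, B = state
    Z = B @ X
    total_ss = float(np.sum(X * X))
    prev = history[-1] if history else np.inf
    for _ in range(n_sweeps):
        A = _update_A(A, X, Z, inner_iter)
        B = _update_B(B, X, A, inner_iter, xxt_lmax)
        Z = B @ X
        cur = rss(X, A, Z)
        history.append(cur)
        if cur <= 1e-14 * max(total_ss, 1.0):
            break
        if np.isfinite(prev) and prev - cur <= tol * max(prev, _EPS):
            break
        prev = cur
    return (A, B), Z, history


def fit_aa(
    X: np.ndarray,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 150,
    inner_iter: int = 25,
    screen_iter: int = 15,
    grid_name: str = COMMON_42,
) -> AAModel:
    """Fit k archetypes to an n x p matrix; best of ``restarts`` runs.

    Every restart is screened for ``screen_iter`` alternating sweeps; only
    the best screened restart is refined up to ``max_iter`` total sweeps.
    Deterministic given ``(X, k, restarts, seed, tol, max_iter)``.  ``k = 1``
    has a closed form: the single archetype is the column mean (the
    unconstrained optimum, itself a convex combination of the rows).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n, p = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n rows; got k={k}, n={n}")
    config = {
        "restarts": restarts,
        "tol": tol,
        "max_iter": max_iter,
        "inner_iter": inner_iter,
        "screen_iter": screen_iter,
    }

    if k == 1:
        A = np.ones((n, 1))
        B = np.full((1, n), 1.0 / n)
        Z = B @ X
        r = rss(X, A, Z)
        return AAModel(1, Z, A, B, r, seed, grid_name, np.array([100.0]), [r], config)

    xxt_lmax = float(np.linalg.eigvalsh(X @ X.T if n <= p else X.T @ X).max())
    screen = min(screen_iter, max_iter)
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        state = _init_state(X, k, rng)
        state, Z, history = _sweep(state, X, screen, tol, inner_iter, xxt_lmax, [])
        if best is None or history[-1] < best[0]:
            best = (history[-1], state, Z, history)
    _, state, Z, history = best
    if len(history) >= screen:  # screening did not already converge
        state, Z, history = _sweep(
            state, X, max_iter - len(history), tol, inner_iter, xxt_lmax, history
        )
    (A, B), final = state, history[-1]

    rw = 100.0 * A.mean(axis=0)
    order = np.argsort(-rw, kind="stable")
    model = AAModel(
        k=k,
        Z=Z[order],
        A=A[:, order],
        B=B[order],
        rss=final,
        seed=seed,
        grid_name=grid_name,
        rw_percent=rw[order],
        rss_history=history,
        config=config,
    )
    return model


def rss_curve(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    restarts: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> RSSCurve:
    """Best-of-restarts RSS for each k in [k_min, k_max], per-k derived seeds."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of rows n={n}")
    ks = list(range(k_min, k_max + 1))
    values = []
    for k in ks:
        sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0])
        model = fit_aa(X, k, restarts=restarts, seed=sub_seed, **fit_kwargs)
        values.append(model.rss)
    return RSSCurve(ks, values, n, p)


def select_k_elbow(curve: RSSCurve, override_k: int | None = None) -> int:
    """Elbow pick: the k farthest (perpendicular) from the endpoint chord.

    Ties break toward the smallest k.  ``override_k`` short-circuits the
    heuristic for callers that fix the archetype count a priori.
    """
    if override_k is not None:
        return int(override_k)
    ks = np.asarray(curve.k_values, dtype=float)
    rs = np.asarray(curve.rss_values, dtype=float)
    if len(ks) == 0:
        raise ValueError("empty RSS curve")
    if len(ks) == 1:
        return int(ks[0])
    d = np.array([ks[-1] - ks[0], rs[-1] - rs[0]])
    norm = np.hypot(*d)
    rel = np.stack([ks - ks[0], rs - rs[0]], axis=1)
    dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / max(norm, _EPS)
    return int(ks[int(np.argmax(dist))])


# ---------------------------------------------------------------------------
# Decomposition and relative weights
# ---------------------------------------------------------------------------

def decompose(model: AAModel, field) -> np.ndarray:
    """Percentage weights of a TD field over the model's archetypes.

    Simplex-constrained least-squares projection onto the archetypes; the k
    percentages are nonnegative and sum to 100.
    """
    values = getattr(field, "values_db", None)
    if values is not None:
        if field.grid.name != model.grid_name:
            raise GridMismatchError(
                f"field grid {field.grid.name} != model grid {model.grid_name}"
            )
    else:
        values = np.asarray(field, dtype=float)
    if values.shape != (model.Z.shape[1],):
        raise GridMismatchError("field length does not match the model's location count")
    w = simplex_lstsq(model.Z.T, values)
    return 100.0 * w


def relative_weights(model: AAModel, X: np.ndarray | None = None) -> np.ndarray:
    """Dataset-level archetype prevalences, normalized to sum to 100.

    With ``X`` given, the weight matrix is recomputed by decomposing every
    row; otherwise the fitted A is used.  Fitted models are already labeled
    in descending relative weight.
    """
    if X is not None:
        W = np.vstack([decompose(model, row) / 100.0 for row in np.asarray(X, dtype=float)])
    elif model.A is not None:
        W = model.A
    else:
        raise ValueError("model carries no weights; supply X to recompute them")
    rw = 100.0 * W.mean(axis=0)
    return rw * (100.0 / rw.sum())
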