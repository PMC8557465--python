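"""Sparse-group-lasso logistic regression by accelerated proximal gradient.

The model minimizes

    L(β0, β) = l(β0, β) + λ1·‖β‖₁ + λ2·Σ_g w_g·‖β_g‖₂

where l is the weighted logistic loss over sequences (normalized by total
weight so λ values are comparable across data sizes), groups g are genes
(blocks of bit-columns), and w_g defaults to sqrt of the group's length in
positions. λ1 controls within-group (position-level) sparsity, λ2
group-level sparsity: at suitable values entire genes receive zero
coefficients. The intercept β0 is never penalized.

The solver is FISTA with backtracking line search and adaptive (function)
restart; a restart step falls back to a plain proximal-gradient step from
the previous iterate, so the recorded objective sequence is non-increasing.
Both nonsmooth terms enter through their exact proximal operator:
soft-thresholding followed by per-group Euclidean shrinkage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .encode import BitColumnMap, OneHotMatrix, map_groups_to_bits
from .msa_io import GroupMap
from .response import ResponseVector

logger = logging.getLogger(__name__)

PENALTIES = ("lasso", "sparse_group", "group", "ridge", "none")


class FitError(ValueError):
    pass


@dataclass
class FitOptions:
    """Hyperparameters and solver controls for one fit."""

    lam1: float = 0.1
    lam2: float = 0.2
    max_iterations: int = 10000
    tolerance: float = 1e-6
    step_rule: str = "backtracking"  # "backtracking" | "lipschitz"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise FitError("regularization strengths must be >= 0")
        if self.tolerance <= 0:
            raise FitError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise FitError("max_iterations must be >= 1")
        if self.step_rule not in ("backtracking", "lipschitz"):
            raise FitError(f"unknown step rule {self.step_rule!r}")


@dataclass
class BitGroups:
    """Group structure over bit-columns: names, index slices, weights."""

    names: list[str]
    slices: list[np.ndarray]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (len(self.names) == len(self.slices) == self.weights.size):
            raise FitError("inconsistent group structure")

    @classmethod
    def from_maps(cls, bitmap: BitColumnMap, groups: GroupMap) -> "BitGroups":
        slices = map_groups_to_bits(bitmap, groups)
        return cls(
            names=list(groups.names),
            slices=slices,
            weights=np.asarray(groups.weights, dtype=np.float64),
        )

    def check_partition(self, n_columns: int) -> None:
        counts = np.zeros(n_columns, dtype=np.int64)
        for sl in self.slices:
            counts[sl] += 1
        if np.any(counts > 1):
            raise FitError("group slices overlap")
        if np.any(counts == 0):
            raise FitError("group slices do not cover every bit-column")

    def subset(self, group_idx: list[int]) -> tuple["BitGroups", np.ndarray]:
        """Restrict to the given groups; returns (structure, column indices).

        The returned slices index into the concatenated column subset.
        """
        cols = []
        new_slices = []
        offset = 0
        for gi in group_idx:
            sl = self.slices[gi]
            cols.append(sl)
            new_slices.append(np.arange(offset, offset + sl.size))
            offset += sl.size
        col_idx = (
            np.concatenate(cols) if cols else np.array([], dtype=np.int64)
        )
        sub = BitGroups(
            names=[self.names[i] for i in group_idx],
            slices=new_slices,
            weights=self.weights[list(group_idx)],
        )
        return sub, col_idx


@dataclass
class ESLModel:
    """A fitted model: intercept, per-bit-column coefficients, diagnostics."""

    intercept: float
    beta: np.ndarray
    lam1: float
    lam2: float
    penalty: str
    group_names: list[str]
    group_weights: np.ndarray
    bitmap: BitColumnMap | None = None
    n_iterations: int = 0
    objective: float = np.nan
    converged: bool = False
    objective_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.bitmap is not None and self.beta.size != self.bitmap.n_columns:
            raise FitError("beta length does not match bit-column map")

    def nonzero_groups(self, groups: BitGroups) -> list[str]:
        return [
            name
            for name, sl in zip(groups.names, groups.slices)
            if sl.size and np.any(self.beta[sl] != 0.0)
        ]

    def to_json(self, groups: GroupMap | None = None) -> str:
        pos2group = groups.position_to_group() if groups is not None else {}
        records = []
        if self.bitmap is not None:
            for j in range(self.beta.size):
                pos = int(self.bitmap.positions[j])
                records.append(
                    {
                        "position": pos,
                        "state": str(self.bitmap.states[j]),
                        "group": pos2group.get(pos),
                        "beta": float(self.beta[j]),
                    }
                )
        return json.dumps(
            {
                "intercept": self.intercept,
                "lambda1": self.lam1,
                "lambda2": self.lam2,
                "penalty": self.penalty,
                "converged": self.converged,
                "iterations": self.n_iterations,
                "objective": self.objective,
                "coefficients": records,
            },
            indent=1,
        )


# ---------------------------------------------------------------- objective


def logistic_objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Weighted logistic loss and its exact gradient.

    l = Σ_j w_j·log(1 + exp(−y_j(β0 + x_jᵀβ))) / Σ_j w_j. Returns
    (loss, ∂l/∂β0, ∂l/∂β).
    """
    X = np.asarray(X, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if X.shape[1] != beta.size or X.shape[0] != y.size or y.size != weights.size:
        raise FitError("dimension mismatch in logistic objective")
    W = weights.sum()
    margin = -y * (beta0 + X @ beta)
    loss = float(np.dot(weights, np.logaddexp(0.0, margin)) / W)
    r = -(weights * y * expit(margin)) / W
    return loss, float(r.sum()), X.T @ r


def _intercept_only(y: np.ndarray, weights: np.ndarray) -> float:
    """Optimal β0 when β = 0: the weighted log-odds of the +1 class."""
    wpos = weights[y > 0].sum()
    wneg = weights[y < 0].sum()
    if wpos <= 0 or wneg <= 0:
        raise FitError("both classes need positive total weight")
    return float(np.log(wpos / wneg))


# ----------------------------------------------------------- proximal maps


def prox_l1(v: np.ndarray, t: float) -> np.ndarray:
    """Soft-thresholding: sign(v)·max(|v|−t, 0)."""
    if t < 0:
        raise FitError("threshold must be >= 0")
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def prox_sparse_group(
    v: np.ndarray,
    t1: float,
    t2: float,
    slices: list[np.ndarray],
    group_weights: np.ndarray,
) -> np.ndarray:
    """Exact prox of t1·‖·‖₁ + t2·Σ_g w_g·‖·_g‖₂.

    Soft-threshold at t1, then shrink each group block toward zero by its
    Euclidean norm: u_g·max(1 − t2·w_g/‖u_g‖₂, 0). The slices must
    partition the vector.
    """
    if t1 < 0 or t2 < 0:
        raise FitError("thresholds must be >= 0")
    counts = np.zeros(v.size, dtype=np.int64)
    for sl in slices:
        counts[sl] += 1
    if np.any(counts != 1):
        raise FitError("group slices must partition the coefficient vector")
    u = prox_l1(v, t1) if t1 > 0 else v.astype(np.float64, copy=True)
    if t2 > 0:
        for sl, wg in zip(slices, group_weights):
            if sl.size == 0:
                continue
            nrm = np.linalg.norm(u[sl])
            if nrm <= t2 * wg:
                u[sl] = 0.0
            else:
                u[sl] *= 1.0 - t2 * wg / nrm
    return u


def _penalty_value(
    beta: np.ndarray,
    lam1: float,
    lam2: float,
    slices: list[np.ndarray] | None,
    group_weights: np.ndarray | None,
) -> float:
    val = lam1 * float(np.abs(beta).sum()) if lam1 > 0 else 0.0
    if lam2 > 0 and slices is not None:
        val += lam2 * float(
            sum(
                wg * np.linalg.norm(beta[sl])
                for sl, wg in zip(slices, group_weights)
                if sl.size
            )
        )
    return val


# ------------------------------------------------------------------- solver


def _lipschitz_bound(X: np.ndarray, weights: np.ndarray, iters: int = 20) -> float:
    """Upper bound on the logistic-loss gradient Lipschitz constant.

    L ≤ σ_max(D·A)²/4 where A = [1, X] and D = diag(sqrt(w/W)); estimated
    by power iteration.
    """
    W = weights.sum()
    d = np.sqrt(weights / W)
    rng = np.random.default_rng(0)
    v = rng.standard_normal(X.shape[1] + 1)
    v /= np.linalg.norm(v)
    s = 1.0
    for _ in range(iters):
        u = d * (v[0] + X @ v[1:])
        v_new = np.concatenate(([u.sum()], X.T @ u))
        s = np.linalg.norm(v_new)
        if s == 0:
            break
        v = v_new / s
    return max(s / 4.0, 1e-12)


def fit(
    X: OneHotMatrix | np.ndarray,
    y: ResponseVector,
    groups: BitGroups | None,
    opts: FitOptions | None = None,
    penalty: str = "sparse_group",
    ridge_lam: float = 0.0,
    init: tuple[float, np.ndarray] | None = None,
) -> ESLModel:
    """Fit a penalized weighted logistic regression.

    ``penalty`` is one of ``lasso`` (λ1 only), ``group`` (λ2 only),
    ``sparse_group`` (both), ``ridge`` (smooth λ·‖β‖₂², via ``ridge_lam``)
    or ``none``. The fit itself is deterministic; initialization is β = 0
    with β0 at the weighted log-odds unless ``init`` is supplied.
    """
    opts = opts or FitOptions()
    if penalty not in PENALTIES:
        raise FitError(f"unknown penalty {penalty!r}")
    bitmap = None
    if isinstance(X, OneHotMatrix):
        bitmap = X.bitmap
        Xm = X.X
    else:
        Xm = np.asarray(X, dtype=np.float64)
    S, c = Xm.shape
    if c == 0:
        raise FitError("empty design: no retained bit-columns")
    if S != y.y.size:
        raise FitError("row count does not match response length")

    lam1 = opts.lam1 if penalty in ("lasso", "sparse_group") else 0.0
    lam2 = opts.lam2 if penalty in ("group", "sparse_group") else 0.0
    slices = groups.slices if groups is not None else None
    gw = groups.weights if groups is not None else None
    if lam2 > 0:
        if groups is None:
            raise FitError("group penalty requires a group structure")
        groups.check_partition(c)

    yv, wv = y.y, y.weights

    def smooth(theta: np.ndarray) -> tuple[float, np.ndarray]:
        loss, g0, g = logistic_objective(theta[0], theta[1:], Xm, yv, wv)
        if ridge_lam > 0:
            loss += ridge_lam * float(theta[1:] @ theta[1:])
            g = g + 2.0 * ridge_lam * theta[1:]
        return loss, np.concatenate(([g0], g))

    def pen(theta: np.ndarray) -> float:
        return _penalty_value(theta[1:], lam1, lam2, slices, gw)

    def prox(theta: np.ndarray, step: float) -> np.ndarray:
        out = theta.copy()
        if lam2 > 0:
            out[1:] = prox_sparse_group(
                theta[1:], step * lam1, step * lam2, slices, gw
            )
        elif lam1 > 0:
            out[1:] = prox_l1(theta[1:], step * lam1)
        return out

    if init is not None:
        theta = np.concatenate(([init[0]], np.asarray(init[1], dtype=np.float64)))
    else:
        theta = np.zeros(c + 1)
        theta[0] = _intercept_only(yv, wv)

    L = _lipschitz_bound(Xm, wv)
    backtrack = opts.step_rule == "backtracking"

    f_x, _ = smooth(theta)
    F_x = f_x + pen(theta)
    history = [F_x]
    x = theta
    z = theta.copy()
    t_k = 1.0
    converged = False
    n_iter = 0

    def _step_from(point: np.ndarray, L_cur: float) -> tuple[np.ndarray, float, float]:
        f_p, g_p = smooth(point)
        while True:
            cand = prox(point - g_p / L_cur, 1.0 / L_cur)
            diff = cand - point
            f_c, _ = smooth(cand)
            if not np.isfinite(f_c):
                if not backtrack:
                    raise FitError("objective diverged; use backtracking")
                L_cur *= 2.0
                continue
            quad = f_p + g_p @ diff + 0.5 * L_cur * (diff @ diff)
            if f_c <= quad + 1e-12 or not backtrack:
                return cand, f_c, L_cur
            L_cur *= 2.0

    for n_iter in range(1, opts.max_iterations + 1):
        x_new, f_new, L = _step_from(z, L)
        F_new = f_new + pen(x_new)
        if F_new > F_x + 1e-15:
            # adaptive restart: momentum overshot — plain proximal step
            # from the previous iterate, which cannot increase F
            t_k = 1.0
            x_new, f_new, L = _step_from(x, L)
            F_new = f_new + pen(x_new)
            if F_new > F_x + 1e-12:
                x_new, F_new = x, F_x  # numerically stalled
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z = x_new + ((t_k - 1.0) / t_next) * (x_new - x)
        rel = abs(F_x - F_new) / max(1.0, abs(F_x))
        x, F_x = x_new, min(F_new, F_x)
        history.append(F_x)
        t_k = t_next
        if rel < opts.tolerance:
            converged = True
            break
    if not np.isfinite(F_x):
        raise FitError("objective diverged")

    return ESLModel(
        intercept=float(x[0]),
        beta=x[1:],
        lam1=lam1,
        lam2=lam2,
        penalty=penalty,
        group_names=list(groups.names) if groups is not None else [],
        group_weights=(
            np.asarray(groups.weights) if groups is not None else np.array([])
        ),
        bitmap=bitmap,
        n_iterations=n_iter,
        objective=float(F_x),
        converged=converged,
        objective_history=history,
    )


def lambda_max(X: OneHotMatrix | np.ndarray, y: ResponseVector) -> float:
    """Smallest λ1 at which the l1-penalized optimum has β = 0.

    Equals the sup-norm of the loss gradient at the intercept-only optimum;
    a fit with λ1 at or above this value (any λ2 ≥ 0) returns the null
    model.
    """
    Xm = X.X if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=np.float64)
    b0 = _intercept_only(y.y, y.weights)
    _, _, g = logistic_objective(b0, np.zeros(Xm.shape[1]), Xm, y.y, y.weights)
    return float(np.max(np.abs(g))) if g.size else 0.0


def default_lambda_grid(lam_max: float, n_points: int = 20) -> np.ndarray:
    """Geometric grid from λ_max down to 1e-3·λ_max."""
    return lam_max * np.logspace(0.0, -3.0, n_points)


# --------------------------------------------------- model selection layers


def cross_validate(
    X: OneHotMatrix | np.ndarray,
    y: ResponseVector,
    groups: BitGroups | None,
    lam1_grid,
    lam2_grid,
    k: int = 5,
    seed: int = 0,
    opts: FitOptions | None = None,
    penalty: str = "sparse_group",
) -> tuple[float, float, pd.DataFrame]:
    """k-fold stratified CV over a (λ1, λ2) grid.

    Returns the grid pair with the lowest mean held-out logistic loss and
    the full CV table. Folds are stratified by class and deterministic
    given the seed.
    """
    if k < 2:
        raise FitError("need at least 2 folds")
    Xm = X.X if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=np.float64)
    opts = opts or FitOptions()
    lam1_grid = np.atleast_1d(np.asarray(lam1_grid, dtype=np.float64))
    lam2_grid = np.atleast_1d(np.asarray(lam2_grid, dtype=np.float64))
    if min(y.n_positive, y.n_negative) < k:
        raise FitError(
            f"cannot stratify {k} folds with class sizes "
            f"({y.n_positive}, {y.n_negative})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pairs = [(l1, l2) for l1 in lam1_grid for l2 in lam2_grid]
    losses = np.zeros((len(pairs), k))
    for fold, (tr, te) in enumerate(skf.split(Xm, y.y)):
        if len(set(y.y[tr])) < 2:
            raise FitError("a training fold lost a class")
        y_tr = ResponseVector(
            taxa=[y.taxa[i] for i in tr], y=y.y[tr], weights=y.weights[tr]
        )
        warm: tuple[float, np.ndarray] | None = None
        # iterate strongest-first so warm starts stay on the sparse path;
        # cache per (λ1, λ2) so duplicated grid points give identical losses
        cache: dict[tuple[float, float], float] = {}
        order = sorted(
            range(len(pairs)), key=lambda i: -(pairs[i][0] + pairs[i][1])
        )
        for i in order:
            l1, l2 = float(pairs[i][0]), float(pairs[i][1])
            if (l1, l2) not in cache:
                o = replace(opts, lam1=l1, lam2=l2)
                model = fit(Xm[tr], y_tr, groups, o, penalty=penalty, init=warm)
                warm = (model.intercept, model.beta)
                loss, _, _ = logistic_objective(
                    model.intercept, model.beta, Xm[te], y.y[te], y.weights[te]
                )
                cache[(l1, l2)] = loss
            losses[i, fold] = cache[(l1, l2)]
    table = pd.DataFrame(
        {
            "lam1": [p[0] for p in pairs],
            "lam2": [p[1] for p in pairs],
            "mean_cv_loss": losses.mean(axis=1),
            "sd_cv_loss": losses.std(axis=1, ddof=1) if k > 1 else 0.0,
        }
    )
    best = int(np.argmin(table["mean_cv_loss"].to_numpy()))
    return float(pairs[best][0]), float(pairs[best][1]), table


def stability_select(
    X: OneHotMatrix | np.ndarray,
    y: ResponseVector,
    groups: BitGroups,
    opts: FitOptions | None = None,
    subsample_fraction: float = 0.5,
    reps: int = 50,
    seed: int = 0,
    penalty: str = "sparse_group",
) -> pd.Series:
    """Per-group selection frequency over stratified subsample fits.

    Each replicate draws ``fraction`` of each class without replacement
    (at least one sequence per class, so no replicate can lose a class)
    and records which groups carry nonzero coefficients.
    """
    if not (0.0 < subsample_fraction < 1.0):
        raise FitError("subsample fraction must be in (0, 1)")
    if reps < 2:
        raise FitError("need at least 2 replicates")
    Xm = X.X if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=np.float64)
    opts = opts or FitOptions()
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y.y > 0)
    neg = np.flatnonzero(y.y < 0)
    counts = pd.Series(0.0, index=pd.Index(groups.names, name="group"))
    for _ in range(reps):
        idx = np.concatenate(
            [
                rng.choice(
                    pos, size=max(1, int(subsample_fraction * pos.size)),
                    replace=False,
                ),
                rng.choice(
                    neg, size=max(1, int(subsample_fraction * neg.size)),
                    replace=False,
                ),
            ]
        )
        y_sub = ResponseVector(
            taxa=[y.taxa[i] for i in idx], y=y.y[idx], weights=y.weights[idx]
        )
        model = fit(Xm[idx], y_sub, groups, opts, penalty=penalty)
        for name in model.nonzero_groups(groups):
            counts[name] += 1.0
    return counts / reps


def refit_selected(
    X: OneHotMatrix | np.ndarray,
    y: ResponseVector,
    groups: BitGroups,
    selected: list[str],
    lam_refit: float | None = None,
    mode: str = "group_lasso",
    opts: FitOptions | None = None,
) -> ESLModel:
    """Refit on the bit-columns of the selected groups only.

    ``group_lasso`` penalizes λ·Σ w_g·‖β_g‖₂ with no l1 term (robust
    coefficient estimation after selection); ``ridge`` penalizes λ·‖β‖₂².
    When ``lam_refit`` is None it defaults to 0.01·λ_max of the reduced
    problem. Unselected groups keep β = 0 in the returned full-size model.
    """
    if mode not in ("group_lasso", "ridge"):
        raise FitError(f"unknown refit mode {mode!r}")
    if not selected:
        raise FitError("empty group selection")
    unknown = set(selected) - set(groups.names)
    if unknown:
        raise FitError(f"unknown groups in selection: {sorted(unknown)}")
    bitmap = X.bitmap if isinstance(X, OneHotMatrix) else None
    Xm = X.X if isinstance(X, OneHotMatrix) else np.asarray(X, dtype=np.float64)
    opts = opts or FitOptions()
    g_idx = [groups.names.index(s) for s in selected]
    sub, col_idx = groups.subset(g_idx)
    if col_idx.size == 0:
        raise FitError("selected groups have no retained bit-columns")
    X_sub = Xm[:, col_idx]
    if lam_refit is None:
        lam_refit = 0.01 * lambda_max(X_sub, y)
    if mode == "group_lasso":
        o = replace(opts, lam1=0.0, lam2=float(lam_refit))
        sub_model = fit(X_sub, y, sub, o, penalty="group")
    else:
        o = replace(opts, lam1=0.0, lam2=0.0)
        sub_model = fit(
            X_sub, y, None, o, penalty="ridge", ridge_lam=float(lam_refit)
        )
    beta = np.zeros(Xm.shape[1])
    beta[col_idx] = sub_model.beta
    return ESLModel(
        intercept=sub_model.intercept,
        beta=beta,
        lam1=0.0,
        lam2=float(lam_refit) if mode == "group_lasso" else 0.0,
        penalty=f"refit_{mode}",
        group_names=list(groups.names),
        group_weights=np.asarray(groups.weights),
        bitmap=bitmap,
        n_iterations=sub_model.n_iterations,
        objective=sub_model.objective,
        converged=sub_model.converged,
        objective_history=sub_model.objective_history,
    )
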