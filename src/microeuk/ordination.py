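"""Redundancy analysis, collinearity pruning, forward selection and VPA.

RDA regresses a (Hellinger-transformed, column-centered) community matrix
on predictors and eigen-analyses the fitted values; explained variance is
summarized as the Ezekiel-adjusted R².  Two-set variation partitioning
splits adjusted R² into pure environmental (a), shared (b), pure spatial
(c) and residual (d) fractions, with reduced-model permutation tests for
the testable pure fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_matrix(x) -> pd.DataFrame:
    df = pd.DataFrame(x)
    return df.astype(float)


def _center(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=0, keepdims=True)


def _explained_ss(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of squares of fitted values of the multivariate OLS of y on [1, x]."""
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    return float((fitted**2).sum()), fitted


def vif_prune(predictors, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    Ties break deterministically toward the earlier column.  Raises if
    fewer than one predictor would survive (cannot happen: a single
    predictor has no VIF).
    """
    x = _as_matrix(predictors)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more samples than predictors")
    cols = list(x.columns)
    while len(cols) > 1:
        vifs = []
        xs = _center(x[cols].to_numpy())
        for j in range(len(cols)):
            yj = xs[:, j]
            others = np.delete(xs, j, axis=1)
            ss_tot = float(yj @ yj)
            if ss_tot == 0:
                vifs.append(1.0)
                continue
            ss_exp, _ = _explained_ss(yj[:, None], others)
            r2 = min(ss_exp / ss_tot, 1.0 - 1e-15)
            vifs.append(1.0 / (1.0 - r2))
        # ties drop the later column, keeping earlier predictors
        worst = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
        if vifs[worst] <= threshold:
            break
        cols.pop(worst)
    return cols


@dataclass
class RDAModel:
    """Canonical analysis of the fitted community variation."""

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    predictor_names: list[str]
    r2: float
    adj_r2: float
    n: int

    @property
    def proportion_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


def rda(y_hellinger, x) -> RDAModel:
    """Redundancy analysis of response matrix Y on predictors X.

    Y is column-centered internally; r2 is the trace of the fitted values
    over the total trace and adj_r2 the Ezekiel correction
    1 - (1 - r2)(n - 1)/(n - p - 1).
    """
    ydf = _as_matrix(y_hellinger)
    xdf = _as_matrix(x)
    n = xdf.shape[0]
    if n != ydf.shape[0]:
        raise ValueError("row mismatch between Y and X")
    # p = rank of the centered design, so redundant columns do not inflate
    # the Ezekiel penalty
    p = int(np.linalg.matrix_rank(_center(xdf.to_numpy()))) if xdf.shape[1] else 0
    if n <= p + 1:
        raise ValueError("need n > p + 1 samples")
    y = _center(ydf.to_numpy())
    ss_tot = float((y**2).sum())
    ss_exp, fitted = _explained_ss(y, xdf.to_numpy())
    r2 = ss_exp / ss_tot if ss_tot > 0 else 0.0
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > 1e-12 * max(eig.max(), 1.0) if eig.size else np.array([], dtype=bool)
    eig = eig[keep]
    scores = pd.DataFrame(
        (u[:, : len(eig)] * s[: len(eig)]),
        index=ydf.index,
        columns=[f"RDA{i + 1}" for i in range(len(eig))],
    )
    return RDAModel(eig, scores, list(xdf.columns), float(r2), float(adj), n)


def _partial_f_permutation(
    y: np.ndarray,
    x_full: np.ndarray,
    x_reduced: np.ndarray | None,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation test for the added predictors, reduced-model permutation.

    Rows of the reduced-model residuals are permuted, the reduced fitted
    values added back, and the partial pseudo-F recomputed.  Returns
    (F_observed, p).
    """
    n = len(y)
    p_full = x_full.shape[1]
    df_res = n - p_full - 1
    if df_res < 1:
        raise ValueError("residual degrees of freedom exhausted")

    def _basis(x: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(n), x])
        u, s, _ = np.linalg.svd(design, full_matrices=False)
        return u[:, s > s.max() * 1e-10]

    u_full = _basis(x_full)
    if x_reduced is None or x_reduced.shape[1] == 0:
        u_red = None
        fitted_reduced = np.zeros_like(y)
        p_added = p_full
    else:
        u_red = _basis(x_reduced)
        fitted_reduced = u_red @ (u_red.T @ y)
        p_added = p_full - x_reduced.shape[1]
    resid_reduced = y - fitted_reduced

    def f_stat(y_eff: np.ndarray) -> float:
        ss_full = float(((u_full.T @ y_eff) ** 2).sum())
        ss_red = float(((u_red.T @ y_eff) ** 2).sum()) if u_red is not None else 0.0
        denom = float((y_eff**2).sum()) - ss_full
        if denom <= 0:
            return np.inf
        return ((ss_full - ss_red) / p_added) / (denom / df_res)

    f_obs = f_stat(y)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_perm = _center(fitted_reduced + resid_reduced[perm])
        if f_stat(y_perm) >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return f_obs, p


def forward_select(
    y,
    x,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = None,
) -> list[str]:
    """Greedy forward selection of predictors for RDA.

    At each step the candidate with the largest adjusted-R² gain is tested
    by a reduced-model permutation test; selection stops when that
    candidate's p exceeds ``alpha`` or when the cumulative adjusted R²
    exceeds the global (all-predictor) model's adjusted R² — the double
    stopping rule.  May return an empty list.
    """
    ydf = _as_matrix(y)
    xdf = _as_matrix(x)
    yc = _center(ydf.to_numpy())
    rng = np.random.default_rng(seed)
    # the adjusted-R2 cap needs the global model; skip that rule when the
    # full predictor set is not estimable (p >= n - 1)
    if xdf.shape[0] > xdf.shape[1] + 1:
        global_adj = rda(ydf, xdf).adj_r2
    else:
        global_adj = np.inf
    selected: list[str] = []
    remaining = list(xdf.columns)
    while remaining:
        gains = []
        for c in remaining:
            model = rda(ydf, xdf[selected + [c]])
            gains.append(model.adj_r2)
        best_i = int(np.argmax(gains))
        best = remaining[best_i]
        best_adj = gains[best_i]
        x_reduced = xdf[selected].to_numpy() if selected else None
        _, p = _partial_f_permutation(
            yc, xdf[selected + [best]].to_numpy(), x_reduced, n_permutations, rng
        )
        if p > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        # second stopping rule: cumulative adjusted R2 reached the global cap
        if best_adj >= global_adj - 1e-12:
            break
    return selected


@dataclass
class VPAResult:
    """Adjusted-R² variation partitioning between two predictor sets.

    Fractions: ``a`` pure first set (environmental), ``c`` pure second set
    (spatial), ``b`` shared, ``d`` residual; a + b + c + d = 1.  Small
    negative adjusted fractions are diagnostic and reported unclipped.
    """

    a: float
    b: float
    c: float
    d: float
    p_a: float | None
    p_c: float | None
    env_names: list[str] = field(default_factory=list)
    spatial_names: list[str] = field(default_factory=list)

    def fractions(self) -> dict[str, float]:
        return {"pure_env": self.a, "shared": self.b, "pure_spatial": self.c, "residual": self.d}


def variation_partition(
    y,
    x_env,
    x_spatial,
    n_permutations: int = 999,
    seed: int | None = None,
) -> VPAResult:
    """Two-set variation partitioning by (partial) RDA.

    adjR2(Y|env) = a + b, adjR2(Y|spatial) = b + c, adjR2(Y|both) = a+b+c;
    pure fractions follow by subtraction and d = 1 - (a+b+c).  The pure
    fractions a and c are tested by permuting residuals of the partial
    (other-set) model.
    """
    ydf = _as_matrix(y)
    env = _as_matrix(x_env) if x_env is not None else pd.DataFrame(index=ydf.index)
    spa = _as_matrix(x_spatial) if x_spatial is not None else pd.DataFrame(index=ydf.index)
    rng = np.random.default_rng(seed)
    yc = _center(ydf.to_numpy())

    if env.shape[1] == 0 and spa.shape[1] == 0:
        raise ValueError("both predictor sets empty")
    if env.shape[1] == 0 or spa.shape[1] == 0:
        # degenerate single-set partition
        xdf = env if env.shape[1] else spa
        model = rda(ydf, xdf)
        _, p = _partial_f_permutation(yc, xdf.to_numpy(), None, n_permutations, rng)
        ab = model.adj_r2
        if env.shape[1]:
            return VPAResult(ab, 0.0, 0.0, 1 - ab, p, None, list(env.columns), [])
        return VPAResult(0.0, 0.0, ab, 1 - ab, None, p, [], list(spa.columns))

    both = pd.concat([env, spa], axis=1)
    ab = rda(ydf, env).adj_r2
    bc = rda(ydf, spa).adj_r2
    abc = rda(ydf, both).adj_r2
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    d = 1 - abc
    _, p_a = _partial_f_permutation(
        yc, both.to_numpy(), spa.to_numpy(), n_permutations, rng
    )
    _, p_c = _partial_f_permutation(
        yc, both.to_numpy(), env.to_numpy(), n_permutations, rng
    )
    return VPAResult(a, b, c, d, p_a, p_c, list(env.columns), list(spa.columns))


def sqrt_transform_env(env: pd.DataFrame, skip: tuple[str, ...] = ("pH",)) -> pd.DataFrame:
    """Square-root transform environment variables, leaving pH untouched."""
    out = env.copy().astype(float)
    for col in out.columns:
        if col in skip:
            continue
        if (out[col] < 0).any():
            raise ValueError(f"negative values in {col!r}; cannot square-root transform")
        out[col] = np.sqrt(out[col])
    return out
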