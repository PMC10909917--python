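"""Alpha diversity, community resemblance, PERMANOVA, NMDS and curve fits.

Resemblance measures are Bray-Curtis dissimilarity (abundance) and
Sørensen similarity (presence/absence).  Group structure is tested with
one-way PERMANOVA on a distance matrix; diversity-productivity responses
are fitted as quadratic (hump/U) or linear curves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from microeuk.io import CommunityTable, DistanceMatrix, TableError


def alpha_diversity(table: CommunityTable, shannon_base: float = math.e) -> pd.DataFrame:
    """Observed richness and Shannon index per sample.

    Shannon is computed over nonzero proportions in the requested log base
    (natural by default; base 2 gives values in bits).
    """
    counts = table.matrix.astype(float)
    if (counts.sum(axis=1) == 0).any():
        raise TableError("empty sample")
    rich = (counts > 0).sum(axis=1)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / math.log(shannon_base)
    return pd.DataFrame(
        {"richness": rich.astype(float), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(matrix: CommunityTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    df = matrix.counts if isinstance(matrix, CommunityTable) else pd.DataFrame(matrix)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances")
    if ((values.sum(axis=1) == 0).sum()) >= 2:
        raise TableError("two all-zero samples: Bray-Curtis undefined")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(list(df.index), d, kind="bray_curtis")


def sorensen_similarity(matrix: CommunityTable | pd.DataFrame) -> DistanceMatrix:
    """Sørensen similarity s = 2a / (2a + b + c) on presence/absence."""
    df = matrix.counts if isinstance(matrix, CommunityTable) else pd.DataFrame(matrix)
    pa = (df.to_numpy() > 0).astype(float)
    if (pa.sum(axis=1) == 0).any():
        raise TableError("sample with zero richness")
    shared = pa @ pa.T
    sizes = pa.sum(axis=1)
    sim = 2 * shared / (sizes[:, None] + sizes[None, :])
    np.fill_diagonal(sim, 1.0)
    return DistanceMatrix(list(df.index), sim, kind="sorensen_similarity")


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError("R2 outside [0, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p outside (0, 1]")


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F, R², permutation p) on a distance matrix.

    Sums of squares come from squared inter-point distances.  When the
    number of distinct label permutations is no larger than
    ``n_permutations`` the null is enumerated exhaustively (p = fraction of
    distinct permutations, observed included, with F >= observed);
    otherwise p uses Monte-Carlo sampling with the +1 correction.
    """
    if dist.is_similarity:
        raise ValueError("PERMANOVA needs a dissimilarity matrix")
    groups = pd.Series(list(groups))
    if len(groups) != dist.n:
        raise ValueError("group length does not match distance matrix")
    codes, uniq = pd.factorize(groups)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 members")

    d2 = dist.values**2
    f_obs, r2 = _permanova_stats(d2, codes, n_groups)

    n = len(codes)
    n_distinct = math.factorial(n)
    for s in sizes:
        n_distinct //= math.factorial(int(s))

    if n_distinct <= n_permutations:
        ge = 0
        seen = set()
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            f_p, _ = _permanova_stats(d2, np.array(perm), n_groups)
            if f_p >= f_obs - 1e-12:
                ge += 1
        p = ge / n_distinct
        return PermanovaResult(f_obs, r2, p, n_distinct, exhaustive=True)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_p, _ = _permanova_stats(d2, perm, n_groups)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, exhaustive=False)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS embedding minimizing Kruskal stress-1.

    Returns the best configuration over ``n_restarts`` random starts and
    its normalized stress.
    """
    if k >= dist.n - 1:
        raise ValueError("k must be < n - 1")
    values = dist.values
    if dist.is_similarity:
        values = 1.0 - values
        np.fill_diagonal(values, 0.0)
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(values)
    out = pd.DataFrame(
        coords,
        index=pd.Index(dist.labels, name="sample_id"),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return out, float(model.stress_)


@dataclass
class QuadraticFit:
    """OLS fit of y = b0 + b1 x + b2 x^2 with shape classification."""

    b0: float
    b1: float
    b2: float
    r2: float
    p_model: float
    p_b2: float
    shape: str  # hump | U | monotone

    @property
    def peak_x(self) -> float:
        if self.b2 == 0:
            return math.nan
        return -self.b1 / (2 * self.b2)


def quadratic_fit(x, y, alpha: float = 0.05) -> QuadraticFit:
    """Fit a quadratic response curve and classify its shape.

    The shape is ``hump`` (b2 significantly negative), ``U`` (significantly
    positive) or ``monotone`` (curvature not distinguishable from zero at
    the given alpha).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (all equal)")
    X = np.column_stack([np.ones_like(x), x, x**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    n, p = len(y), 3
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df_res = n - p
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        # perfect fit: curvature is significant only if b2 is non-negligible
        p_model = 0.0
        b2_scale = max(np.abs(beta).max(), 1.0)
        p_b2 = 0.0 if abs(beta[2]) > 1e-10 * b2_scale else 1.0
    else:
        f = (ss_tot - ss_res) / 2 / (ss_res / df_res)
        p_model = float(stats.f.sf(f, 2, df_res))
        sigma2 = ss_res / df_res
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t_b2 = beta[2] / math.sqrt(cov[2, 2])
        p_b2 = 2 * float(stats.t.sf(abs(t_b2), df_res))
    if p_b2 <= alpha and beta[2] < 0:
        shape = "hump"
    elif p_b2 <= alpha and beta[2] > 0:
        shape = "U"
    else:
        shape = "monotone"
    return QuadraticFit(float(beta[0]), float(beta[1]), float(beta[2]), r2, p_model, p_b2, shape)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float


def linear_fit(x, y) -> LinearFit:
    """Simple OLS line with slope t-test p-value and adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else math.nan
    return LinearFit(float(res.slope), float(res.intercept), float(r2), float(adj), float(res.pvalue))


def group_compare(values, groups, method: str = "t_test") -> dict:
    """Compare a variable across groups.

    ``t_test`` — classical pooled-variance two-sample t-test (two groups).
    ``anova_lsd`` — one-way ANOVA F-test plus Fisher's LSD pairwise
    p-values (pairwise t using the pooled ANOVA mean square error).
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    codes, uniq = pd.factorize(groups)
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 members")
    by_group = [values[codes == g] for g in range(len(uniq))]

    if method == "t_test":
        if len(uniq) != 2:
            raise ValueError("t_test needs exactly 2 groups")
        t, p = stats.ttest_ind(by_group[0], by_group[1], equal_var=True)
        return {"method": "t_test", "statistic": float(t), "p_value": float(p)}

    if method != "anova_lsd":
        raise ValueError(f"unknown method {method!r}")

    f, p = stats.f_oneway(*by_group)
    n = len(values)
    k = len(uniq)
    mse = sum(((g - g.mean()) ** 2).sum() for g in by_group) / (n - k)
    pairwise = {}
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1 / sizes[i] + 1 / sizes[j]))
        t = (by_group[i].mean() - by_group[j].mean()) / se
        pairwise[(str(uniq[i]), str(uniq[j]))] = 2 * float(stats.t.sf(abs(t), n - k))
    return {
        "method": "anova_lsd",
        "statistic": float(f),
        "p_value": float(p),
        "pairwise_p": pairwise,
    }


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def chla_level(chla_values, edges=(0.0, 2.0, 5.0, 11.0)) -> pd.Series:
    """Bin chlorophyll-a into productivity levels (low/mid/high).

    Half-open [low, high) bins with the last bin closed on the right.
    """
    labels = ["low", "mid", "high"]
    values = pd.Series(chla_values, dtype=float).clip(edges[0], edges[-1])
    out = pd.cut(values, bins=list(edges), labels=labels, right=False, include_lowest=True)
    # close the last bin on the right
    out[values == edges[-1]] = "high"
    return out
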