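"""Sloan neutral community model: fit, confidence envelope, partitioning.

The model predicts the occurrence frequency of a taxon across local
communities of size N from its metacommunity mean relative abundance p.
Under neutral drift with immigration probability m, the local relative
abundance of a taxon follows Beta(Nm*p, Nm*(1-p)), so the probability of
detecting it (at least one read, detection limit d = 1/N) is

    F(p) = 1 - BetaCDF(d; Nm*p, Nm*(1-p)).

Nm is estimated by nonlinear least squares of observed frequencies on
F(p); taxa outside a binomial confidence envelope around the fitted curve
are partitioned as over-represented ("above", e.g. actively selected or
broadly dispersed) or under-represented ("below", e.g. dispersal-limited).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from microeuk.io import CommunityTable, TableError

log = logging.getLogger(__name__)

_LOG_NM_BOUNDS = (-2.0, 7.0)  # log10(Nm) search interval


def freq_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-ASV mean relative abundance (p) and occurrence frequency (f).

    p_i is the mean over samples of within-sample relative abundance,
    f_i the fraction of samples where the ASV is present.  ASVs absent
    everywhere are dropped.  Intended for a rarefied table (equal row
    sums); a warning is emitted otherwise.
    """
    counts = table.matrix.astype(float)
    if counts.size == 0:
        raise TableError("empty table")
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        raise TableError("sample with zero reads")
    if len(set(sums)) > 1:
        warnings.warn("table is not rarefied (unequal sample sums)", stacklevel=2)
    rel = counts / sums[:, None]
    p = rel.mean(axis=0)
    f = (counts > 0).mean(axis=0)
    reads = counts.sum(axis=0)
    present = reads > 0
    out = pd.DataFrame(
        {"p": p[present], "f": f[present], "reads_total": reads[present].astype(int)},
        index=pd.Index(np.array(table.asv_ids)[present], name="asv_id"),
    )
    return out


def sloan_frequency(p, nm: float, detection_limit: float) -> np.ndarray:
    """Predicted occurrence frequency F(p) = 1 - BetaCDF(d; Nm p, Nm(1-p))."""
    p = np.asarray(p, dtype=float)
    alpha = nm * p
    beta = nm * (1.0 - p)
    return 1.0 - stats.beta.cdf(detection_limit, alpha, beta)


@dataclass
class NCMFit:
    """Fitted neutral-model parameters and per-ASV predictions."""

    n_reads: int
    nm: float
    r2: float
    converged: bool
    detection_limit: float
    predicted: pd.Series  # per-ASV F(p) at the fitted Nm

    @property
    def m(self) -> float:
        """Immigration probability m = Nm / N."""
        return self.nm / self.n_reads


def _sse(log10_nm: float, p: np.ndarray, f: np.ndarray, d: float) -> float:
    pred = sloan_frequency(p, 10.0**log10_nm, d)
    return float(((f - pred) ** 2).sum())


def fit_ncm(
    fa: pd.DataFrame,
    n_reads: int,
    n_grid: int = 200,
    bounds: tuple[float, float] = _LOG_NM_BOUNDS,
) -> NCMFit:
    """Estimate Nm by least squares of f on the Sloan curve.

    A coarse log10(Nm) grid locates the basin, then bounded scalar
    minimization refines it; the objective is flat for very large Nm, so
    the log-scale multi-start matters.  A solution at the search boundary
    is flagged non-convergent.
    """
    if len(fa) < 10:
        raise ValueError("need at least 10 ASVs to fit the neutral model")
    if n_reads < 2:
        raise ValueError("N must be >= 2")
    p = fa["p"].to_numpy(dtype=float)
    f = fa["f"].to_numpy(dtype=float)
    d = 1.0 / n_reads

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    sse_grid = np.array([_sse(g, p, f, d) for g in grid])
    i = int(np.argmin(sse_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(_sse, bounds=(lo, hi), args=(p, f, d), method="bounded")
    log_nm = float(res.x)
    converged = bounds[0] + 1e-3 < log_nm < bounds[1] - 1e-3
    if not converged:
        log.warning("NCM optimizer at search boundary (log10 Nm = %.3f)", log_nm)
    nm = 10.0**log_nm
    pred = sloan_frequency(p, nm, d)
    sse = float(((f - pred) ** 2).sum())
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else -np.inf
    return NCMFit(
        n_reads=int(n_reads),
        nm=nm,
        r2=r2,
        converged=converged,
        detection_limit=d,
        predicted=pd.Series(pred, index=fa.index, name="predicted"),
    )


def ncm_envelope(
    fit: NCMFit,
    fa: pd.DataFrame,
    ci_level: float = 0.95,
    n_communities: int | None = None,
) -> pd.DataFrame:
    """Wilson score confidence bounds around the fitted frequency curve.

    Treats each ASV's occurrence as a binomial proportion with success
    probability F(p_i) and n = number of communities; bounds are clipped
    to [0, 1] and degenerate one-sided at F = 0 or 1.
    """
    if n_communities is None:
        raise ValueError("n_communities (number of samples) is required")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    phat = fit.predicted.reindex(fa.index).to_numpy()
    n = n_communities
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    return pd.DataFrame({"lower": lower, "upper": upper}, index=fa.index)


@dataclass
class PartitionSummary:
    """Richness and read-abundance shares (%) of each neutrality partition."""

    richness_pct: dict[str, float]
    abundance_pct: dict[str, float]


def partition_asvs(fa: pd.DataFrame, envelope: pd.DataFrame) -> tuple[pd.Series, PartitionSummary]:
    """Label each ASV above/neutral/below the confidence envelope.

    Returns the per-ASV labels and the partition shares of ASV richness
    and of total reads (each summing to 100%).
    """
    f = fa["f"].to_numpy()
    lower = envelope.reindex(fa.index)["lower"].to_numpy()
    upper = envelope.reindex(fa.index)["upper"].to_numpy()
    labels = np.where(f > upper, "above", np.where(f < lower, "below", "neutral"))
    labels = pd.Series(labels, index=fa.index, name="partition")
    reads = fa["reads_total"].to_numpy(dtype=float)
    rich_pct = {}
    abund_pct = {}
    for part in ("above", "neutral", "below"):
        mask = labels.to_numpy() == part
        rich_pct[part] = 100.0 * mask.mean()
        abund_pct[part] = 100.0 * reads[mask].sum() / reads.sum()
    return labels, PartitionSummary(rich_pct, abund_pct)


def ncm_analysis(
    table: CommunityTable,
    n_reads: int | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Full neutral-model analysis of one community table.

    Convenience wrapper: frequency/abundance stats, Nm fit, envelope and
    partition summary, keyed for serialization.
    """
    fa = freq_abundance(table)
    if n_reads is None:
        n_reads = int(round(table.sample_sums().mean()))
    fit = fit_ncm(fa, n_reads)
    env = ncm_envelope(fit, fa, ci_level=ci_level, n_communities=table.shape[0])
    labels, summary = partition_asvs(fa, env)
    detail = fa.copy()
    detail["predicted"] = fit.predicted
    detail[["lower", "upper"]] = env
    detail["partition"] = labels
    return {
        "N": n_reads,
        "m": fit.m,
        "Nm": fit.nm,
        "r2": fit.r2,
        "converged": fit.converged,
        "ci_level": ci_level,
        "richness_pct": summary.richness_pct,
        "abundance_pct": summary.abundance_pct,
        "detail": detail,
    }
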