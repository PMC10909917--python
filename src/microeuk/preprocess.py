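"""Taxonomic exclusion filters, rarefaction, TMM normalization, transforms.

The default preparation for diversity work mirrors common amplicon
practice: drop unassigned ASVs, global singletons and non-target lineages
(Metazoa, Ulvophyceae, Streptophyta, Rhodophyta), then rarefy every sample
to a common depth by subsampling reads without replacement.  Beta-diversity
on normalized counts uses trimmed-mean-of-M-values (TMM) scaling factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microeuk.io import CommunityTable, TaxonomyTable, TableError

log = logging.getLogger(__name__)

#: Lineage terms excluded from the analysis by default.
DEFAULT_EXCLUDE = frozenset({"Metazoa", "Ulvophyceae", "Streptophyta", "Rhodophyta"})


@dataclass
class FilterRules:
    """Which ASVs to drop before diversity analysis."""

    exclude_lineage_terms: frozenset[str] = field(default=DEFAULT_EXCLUDE)
    drop_unassigned: bool = True
    drop_singletons: bool = True

    def __post_init__(self) -> None:
        terms = frozenset(self.exclude_lineage_terms)
        if any(not t for t in terms):
            raise ValueError("exclusion terms must be non-empty strings")
        self.exclude_lineage_terms = terms


@dataclass
class NormalizationFactors:
    """Per-sample positive scaling factors with geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.astype(float)
        if (f <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError("factors must have geometric mean 1")
        self.factors = f


def filter_taxa(
    table: CommunityTable,
    taxonomy: TaxonomyTable | None,
    rules: FilterRules | None = None,
) -> CommunityTable:
    """Remove excluded-lineage ASVs, unassigned ASVs and global singletons.

    An ASV is unassigned when it has no taxonomy entry or a fully empty
    lineage; a singleton has a total count of 1 summed over all samples.
    Sample order is preserved.  Idempotent.
    """
    rules = rules or FilterRules()
    keep = []
    for asv in table.asv_ids:
        lineage: tuple[str, ...] = ()
        if taxonomy is not None and asv in taxonomy:
            lineage = taxonomy.lineage(asv)
        if rules.drop_unassigned and not any(lineage):
            continue
        if any(rank in rules.exclude_lineage_terms for rank in lineage if rank):
            continue
        keep.append(asv)
    filtered = table.counts[keep]
    if rules.drop_singletons:
        totals = filtered.sum(axis=0)
        filtered = filtered.loc[:, totals != 1]
    if filtered.shape[1] == 0:
        raise TableError("all ASVs removed by filter rules")
    return CommunityTable(filtered)


def _shannon(counts: np.ndarray, base: float) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def rarefy(
    table: CommunityTable,
    depth: int,
    n_iterations: int = 100,
    seed: int | None = None,
    shannon_base: float = np.e,
) -> tuple[CommunityTable, pd.DataFrame]:
    """Rarefy each sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Returns the first-iteration rarefied table (used for beta diversity)
    and per-sample mean alpha summaries (richness, Shannon) averaged over
    ``n_iterations`` independent draws — averaging is why reported richness
    can be non-integer.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sample_sums()
    retained = sums.index[sums >= depth]
    if len(retained) == 0:
        raise TableError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s in table.sample_ids if s not in set(retained)]
    if dropped:
        log.warning("dropping %d samples below depth %d: %s", len(dropped), depth, dropped)

    rng = np.random.default_rng(seed)
    counts = table.counts.loc[retained]
    first = np.zeros_like(counts.to_numpy())
    rich = np.zeros(len(retained))
    shan = np.zeros(len(retained))
    for i, (_, row) in enumerate(counts.iterrows()):
        vec = row.to_numpy()
        for it in range(max(n_iterations, 1)):
            draw = rng.multivariate_hypergeometric(vec, depth)
            if it == 0:
                first[i] = draw
            rich[i] += int((draw > 0).sum())
            shan[i] += _shannon(draw, shannon_base)
    n_it = max(n_iterations, 1)
    alpha = pd.DataFrame(
        {"richness": rich / n_it, "shannon": shan / n_it},
        index=pd.Index(retained, name="sample_id"),
    )
    out = CommunityTable(pd.DataFrame(first, index=counts.index, columns=counts.columns))
    return out, alpha


def tmm_factors(
    table: CommunityTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions.  For each sample, M (log2 fold
    change of fractions vs the reference) and A (mean log2 fraction) are
    computed over ASVs nonzero in both; the most extreme ``trim_m`` of M
    and ``trim_a`` of A (two-sided) are discarded and the remaining M are
    averaged with inverse asymptotic-variance weights.  Factors are
    rescaled to geometric mean 1.
    """
    counts = table.counts.to_numpy(dtype=float)
    n_samples = counts.shape[0]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        raise TableError("sample with no reads")
    uq = np.array([np.quantile(c, 0.75) for c in counts]) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[ref_idx]
    n_ref = lib[ref_idx]

    raw = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        obs = counts[j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise TableError(f"sample {table.sample_ids[j]!r} shares no ASV with reference")
        y, r = obs[both], ref[both]
        n_obs = lib[j]
        m = np.log2((y / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((y / n_obs) * (r / n_ref))
        w = 1.0 / ((n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r))
        keep = _double_trim_mask(m, trim_m) & _double_trim_mask(a, trim_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        raw[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(pd.Series(factors, index=table.sample_ids, name="factor"))


def _double_trim_mask(x: np.ndarray, total_trim: float) -> np.ndarray:
    """Keep values between the total_trim/2 and 1 - total_trim/2 rank quantiles."""
    n = len(x)
    lo = np.floor(n * total_trim / 2) + 1
    hi = n + 1 - lo
    ranks = pd.Series(x).rank().to_numpy()
    return (ranks >= lo) & (ranks <= hi)


def apply_factors(table: CommunityTable, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts scaled to effective relative abundances: count / (libsize * factor)."""
    missing = [s for s in table.sample_ids if s not in factors.factors.index]
    if missing:
        raise ValueError(f"missing factors for samples: {missing}")
    lib = table.sample_sums()
    if (lib == 0).any():
        raise TableError("all-zero sample row")
    eff = lib * factors.factors.loc[table.sample_ids]
    return table.counts.div(eff, axis=0)


def hellinger(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of relative abundance; rows have unit sum of squares."""
    df = table.counts if isinstance(table, CommunityTable) else pd.DataFrame(table)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative input to hellinger")
    sums = df.sum(axis=1)
    if (sums == 0).any():
        raise TableError("zero-sum row")
    return np.sqrt(df.div(sums, axis=0))
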