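"""Synthetic data with the statistical structure the analysis assumes.

Every generator carries its ground truth (:class:`SyntheticTruth`), so
each estimator in the pipeline can be validated by parameter recovery:

* neutral beta-binomial community sampling — the sampling dual of the
  Sloan model the NCM fitter inverts;
* pairwise similarity decaying log-linearly with geographic distance;
* lognormal metacommunity abundance distributions;
* trait-labeled taxonomies with trophic-mode shares responding to
  environmental gradients (hump, U or linear shapes).

The default study fixture mirrors a two-season lake survey: 20 sites on a
~40 km transect sampled at three depths (60 samples), reads rarefiable to
18,300, and a 2,000-taxon metacommunity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from microeuk.io import ENV_VARS, RANKS, CommunityTable, DistanceMatrix, SampleMetadata, TaxonomyTable
from microeuk.spatial import geo_distance_matrix

#: Study-shaped defaults: rarefaction depth, metacommunity richness, samples.
DEFAULT_DEPTH = 18_300
DEFAULT_RICHNESS = 2_000
DEFAULT_N_SAMPLES = 60

# Lake-shaped coordinate frame (subtropical, ~40 km east-west extent).
_LAT0, _LON0 = 28.06, 119.65
_TRANSECT_KM = 40.0


@dataclass
class SyntheticTruth:
    """Ground-truth parameters serialized beside every generated dataset."""

    seed: int | None = None
    m: float | None = None
    nm: float | None = None
    n_reads: int | None = None
    s: int | None = None
    lognormal_mu: float | None = None
    lognormal_sigma: float | None = None
    decay_z: float | None = None
    decay_intercept: float | None = None
    decay_noise_sd: float | None = None
    mode_mean_shares: dict = field(default_factory=dict)
    env_effects: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def gen_metacommunity(
    s: int = DEFAULT_RICHNESS,
    mu: float = 0.0,
    sigma: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Lognormal metacommunity relative abundances (length ``s``, sum 1)."""
    if s < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=mu, sigma=sigma, size=s)
    return raw / raw.sum()


def gen_neutral_communities(
    p: np.ndarray,
    nm: float,
    n_reads: int = DEFAULT_DEPTH,
    n_samples: int = 36,
    seed: int | None = None,
    sample_prefix: str = "S",
) -> CommunityTable:
    """Sample local communities under neutral drift with immigration.

    For each sample and taxon the local relative abundance is drawn from
    Beta(Nm*p_i, Nm*(1-p_i)) and reads from Binomial(N, that abundance) —
    exactly the distributional assumption the Sloan fit inverts.
    """
    if nm <= 0:
        raise ValueError("Nm must be positive")
    if n_reads < 1:
        raise ValueError("N_reads must be >= 1")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    alpha = nm * p
    beta = nm * (1.0 - p)
    local = rng.beta(alpha[None, :], beta[None, :], size=(n_samples, len(p)))
    counts = rng.binomial(n_reads, np.clip(local, 0.0, 1.0))
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"{sample_prefix}{i + 1}" for i in range(n_samples)], name="sample_id"),
        columns=[f"asv{i + 1}" for i in range(len(p))],
    )
    return CommunityTable(df)


def transect_coordinates(n_sites: int, span_km: float = _TRANSECT_KM) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced sites along an east-west lake transect."""
    km_per_deg_lon = 111.1949 * np.cos(np.radians(_LAT0))
    lons = _LON0 + np.linspace(0, span_km / km_per_deg_lon, n_sites)
    lats = np.full(n_sites, _LAT0)
    return lats, lons


def gen_decay_dataset(
    n_sites: int = 12,
    z: float = 0.03,
    b: float = -0.1,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[DistanceMatrix, DistanceMatrix, pd.DataFrame]:
    """Pairwise similarities decaying log-linearly with transect distance.

    log10(similarity) = (-2 z) * log10(distance_m) + b + Normal(0, noise_sd)
    for every site pair; similarities are clipped to <= 1 (a warning is
    emitted if that affects more than 10% of pairs).  Returns (similarity
    matrix, geographic distance matrix, site coordinate frame).
    """
    if n_sites < 4:
        raise ValueError("need at least 4 sites")
    if z < 0:
        raise ValueError("z must be non-negative")
    rng = np.random.default_rng(seed)
    lats, lons = transect_coordinates(n_sites)
    labels = [f"site{i + 1}" for i in range(n_sites)]
    dist = geo_distance_matrix(lats, lons, labels=labels)
    log_s = np.zeros((n_sites, n_sites))
    iu = np.triu_indices(n_sites, k=1)
    log_s[iu] = -2 * z * np.log10(dist.values[iu]) + b + rng.normal(0, noise_sd, len(iu[0]))
    sim = 10.0**log_s
    n_clipped = int((sim[iu] > 1).sum())
    if n_clipped > 0.1 * len(iu[0]):
        import warnings

        warnings.warn(f"{n_clipped} pairs clipped to similarity 1", stacklevel=2)
    sim = np.minimum(sim, 1.0)
    sim = np.triu(sim, k=1)
    sim = sim + sim.T
    np.fill_diagonal(sim, 1.0)
    coords = pd.DataFrame({"latitude": lats, "longitude": lons}, index=labels)
    return DistanceMatrix(labels, sim, kind="sorensen_similarity"), dist, coords


@dataclass
class EffectSpec:
    """Per-mode environmental response shapes for the functional generator.

    Phototroph share is a quadratic hump in chlorophyll-a peaking at
    ``photo_peak_chla``; mixotroph share rises linearly with dissolved
    oxygen; heterotroph share is the remainder (hence U-shaped /
    decreasing along the same gradients).  Shares receive Gaussian noise
    and are renormalized.
    """

    photo_peak_chla: float = 4.0
    photo_base: float = 0.28
    photo_amp: float = 0.25
    mixo_base: float = 0.06
    mixo_do_slope: float = 0.012  # share per mg/L DO
    noise_sd: float = 0.02
    chla_range: tuple[float, float] = (0.5, 11.0)
    do_range: tuple[float, float] = (5.0, 12.0)


def gen_study_metadata(
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
    effects: EffectSpec | None = None,
) -> SampleMetadata:
    """Metadata emulating the survey design: sites x 3 depths, two seasons.

    The first 8 sites are spring, the remainder autumn (8 + 12 sites at
    60 samples); all 12 physicochemical variables are drawn from plausible
    lake ranges, chlorophyll-a spanning the productivity gradient.
    """
    if n_samples % 3 != 0:
        raise ValueError("n_samples must be a multiple of 3 (three depths per site)")
    eff = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    n_sites = n_samples // 3
    n_spring = min(8, max(1, n_sites // 2)) if n_sites != 20 else 8
    lats, lons = transect_coordinates(n_sites)
    depths = (0.5, 5.0, 10.0)
    rows = []
    for i in range(n_sites):
        season = "spring" if i < n_spring else "autumn"
        chla_site = rng.uniform(*eff.chla_range)
        do_site = rng.uniform(*eff.do_range)
        for d in depths:
            rows.append(
                {
                    "sample_id": f"{season[:2].upper()}{i + 1}D{d:g}",
                    "site": f"site{i + 1}",
                    "season": season,
                    "depth_m": d,
                    "latitude": lats[i],
                    "longitude": lons[i],
                    "temperature": rng.uniform(12, 20) if season == "spring" else rng.uniform(20, 28),
                    "pH": rng.uniform(6.8, 8.6),
                    "DO": do_site + rng.normal(0, 0.3),
                    "chla": max(chla_site + rng.normal(0, 0.3), 0.05),
                    "NO3_N": rng.uniform(0.1, 1.5),
                    "NO2_N": rng.uniform(0.001, 0.05),
                    "NH4_N": rng.uniform(0.02, 0.5),
                    "TN": rng.uniform(0.5, 2.5),
                    "TP": rng.uniform(0.01, 0.12),
                    "PO4_P": rng.uniform(0.005, 0.06),
                    "CODMn": rng.uniform(1.0, 5.0),
                    "TOC": rng.uniform(1.0, 6.0),
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def _mode_shares(meta: SampleMetadata, eff: EffectSpec, rng: np.random.Generator) -> pd.DataFrame:
    chla = meta.table["chla"].to_numpy(dtype=float)
    do = meta.table["DO"].to_numpy(dtype=float)
    half_width = (eff.chla_range[1] - eff.chla_range[0]) / 2
    photo = eff.photo_base + eff.photo_amp * (1 - ((chla - eff.photo_peak_chla) / half_width) ** 2)
    mixo = eff.mixo_base + eff.mixo_do_slope * (do - eff.do_range[0])
    photo = photo + rng.normal(0, eff.noise_sd, len(chla))
    mixo = mixo + rng.normal(0, eff.noise_sd / 2, len(chla))
    photo = np.clip(photo, 0.02, 0.9)
    mixo = np.clip(mixo, 0.01, 0.5)
    hetero = 1.0 - photo - mixo
    if (hetero < 0).any():
        import warnings

        warnings.warn("shares renormalized (photo + mixo exceeded 1)", stacklevel=3)
        total = photo + mixo
        scale = np.where(total > 0.95, 0.95 / total, 1.0)
        photo, mixo = photo * scale, mixo * scale
        hetero = 1.0 - photo - mixo
    return pd.DataFrame(
        {"phototroph": photo, "mixotroph": mixo, "heterotroph": hetero},
        index=meta.table.index,
    )


_MODE_LINEAGES = {
    "phototroph": ("Eukaryota", "Archaeplastida", "Chlorophyta", "Chlorophyceae"),
    "mixotroph": ("Eukaryota", "Cryptista", "Cryptophyta", "Cryptophyceae"),
    "heterotroph": ("Eukaryota", "Alveolata", "Ciliophora", "Spirotrichea"),
}


def gen_functional_dataset(
    n_samples: int = DEFAULT_N_SAMPLES,
    s_per_mode: int = 120,
    n_reads: int = DEFAULT_DEPTH,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> tuple[SampleMetadata, TaxonomyTable, CommunityTable, SyntheticTruth]:
    """Trait-labeled community whose mode shares track environmental gradients.

    Environment gradients are drawn, trophic-mode shares computed from the
    response shapes in ``effects``, and reads allocated multinomially to
    trait-labeled ASVs (lognormal within-mode abundances).
    """
    eff = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    meta = gen_study_metadata(n_samples, seed=int(rng.integers(2**31)), effects=eff)
    shares = _mode_shares(meta, eff, rng)

    asv_ids, lineage_rows, mode_of = [], [], []
    for mode, lineage in _MODE_LINEAGES.items():
        for k in range(s_per_mode):
            asv_ids.append(f"{mode[:4]}_asv{k + 1}")
            lineage_rows.append(list(lineage) + [""] * (len(RANKS) - len(lineage)))
            mode_of.append(mode)
    taxonomy = TaxonomyTable(
        pd.DataFrame(lineage_rows, index=pd.Index(asv_ids, name="asv_id"), columns=list(RANKS))
    )

    within = {
        mode: gen_metacommunity(s_per_mode, sigma=1.5, seed=int(rng.integers(2**31)))
        for mode in _MODE_LINEAGES
    }
    counts = np.zeros((n_samples, len(asv_ids)), dtype=np.int64)
    mode_of = np.array(mode_of)
    for i, sample in enumerate(meta.sample_ids):
        reads_per_mode = rng.multinomial(n_reads, shares.loc[sample].to_numpy())
        for mode, reads in zip(shares.columns, reads_per_mode):
            cols = np.flatnonzero(mode_of == mode)
            counts[i, cols] = rng.multinomial(reads, within[mode])
    table = CommunityTable(
        pd.DataFrame(counts, index=pd.Index(meta.sample_ids, name="sample_id"), columns=asv_ids)
    )
    truth = SyntheticTruth(
        seed=seed,
        n_reads=n_reads,
        s=len(asv_ids),
        mode_mean_shares={c: float(shares[c].mean()) for c in shares.columns},
        env_effects={
            "photo_peak_chla": eff.photo_peak_chla,
            "mixo_do_slope": eff.mixo_do_slope,
            "noise_sd": eff.noise_sd,
        },
    )
    return meta, taxonomy, table, truth


def gen_study_dataset(
    n_samples: int = DEFAULT_N_SAMPLES,
    s: int = DEFAULT_RICHNESS,
    nm: float = 337.0,
    n_reads: int = DEFAULT_DEPTH,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 2.0,
    seed: int | None = None,
) -> tuple[CommunityTable, TaxonomyTable, SampleMetadata, SyntheticTruth]:
    """Full study-shaped fixture: neutral counts + taxonomy + metadata.

    Counts come from the beta-binomial neutral sampler over a lognormal
    metacommunity; ASVs receive trait-labeled lineages cycling through the
    three trophic modes so the trait stage has signal to summarize.
    """
    rng = np.random.default_rng(seed)
    p = gen_metacommunity(s, lognormal_mu, lognormal_sigma, seed=int(rng.integers(2**31)))
    meta = gen_study_metadata(n_samples, seed=int(rng.integers(2**31)))
    table = gen_neutral_communities(
        p, nm, n_reads=n_reads, n_samples=n_samples, seed=int(rng.integers(2**31))
    )
    table = CommunityTable(table.counts.set_axis(meta.sample_ids, axis=0).rename_axis("sample_id"))
    modes = list(_MODE_LINEAGES)
    lineage_rows = []
    for i, asv in enumerate(table.asv_ids):
        lineage = _MODE_LINEAGES[modes[i % 3]]
        lineage_rows.append(list(lineage) + [""] * (len(RANKS) - len(lineage)))
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            lineage_rows, index=pd.Index(table.asv_ids, name="asv_id"), columns=list(RANKS)
        )
    )
    truth = SyntheticTruth(
        seed=seed,
        m=nm / n_reads,
        nm=nm,
        n_reads=n_reads,
        s=s,
        lognormal_mu=lognormal_mu,
        lognormal_sigma=lognormal_sigma,
    )
    return table, taxonomy, meta, truth
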