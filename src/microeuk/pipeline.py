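"""Whole-analysis orchestration: preprocess -> diversity -> spatial ->
VPA -> NCM -> traits -> RF, from one config, with deterministic seeding.

Each stage receives its own seed derived from the global seed by a fixed
counter scheme (``stage_seed = (global_seed * 1009 + stage_index) mod
2^31``), so a stage re-run standalone with that seed reproduces its part
of the pipeline bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from microeuk import diversity, ncm, ordination, preprocess, spatial, traits
from microeuk.io import (
    ENV_VARS,
    CommunityTable,
    align_tables,
    read_community_table,
    read_metadata,
    read_taxonomy,
)
from microeuk.rf_importance import rf_importance

log = logging.getLogger(__name__)

_STAGES = (
    "preprocess",
    "alpha",
    "beta",
    "decay",
    "vpa",
    "ncm",
    "traits",
    "rf",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    counts_path: str
    metadata_path: str
    taxonomy_path: str | None = None
    trait_rules_path: str | None = None
    output_dir: str = "microeuk_out"
    orientation: str = "samples_in_rows"
    rarefaction_depth: int = 18_300
    rarefaction_iterations: int = 100
    shannon_base: float = float(np.e)
    chla_bin_edges: tuple[float, ...] = (0.0, 2.0, 5.0, 11.0)
    exclude_terms: tuple[str, ...] = tuple(sorted(preprocess.DEFAULT_EXCLUDE))
    env_variables: tuple[str, ...] = ENV_VARS
    n_permutations: int = 999
    ncm_ci_level: float = 0.95
    rf_trees: int = 200
    rf_null: int = 99
    rf_cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for name in ("counts_path", "metadata_path", "taxonomy_path", "trait_rules_path"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + _STAGES.index(stage)) % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write per-stage outputs plus a summary JSON.

    Any stage failure aborts with a stage-tagged :class:`StageError`;
    outputs of completed stages are preserved in ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(asdict(config))}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                summary[name] = _jsonable(fn())
            except Exception as exc:  # noqa: BLE001 - stage tagging
                raise StageError(name, exc) from exc

        return deco

    # -- load & preprocess -------------------------------------------------
    try:
        table = read_community_table(config.counts_path, config.orientation)
        metadata = read_metadata(config.metadata_path)
        taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        table, metadata = align_tables(table, metadata)
        rules = (
            traits.read_trait_rules(config.trait_rules_path)
            if config.trait_rules_path
            else list(traits.DEFAULT_RULES)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    state: dict = {}

    @stage("preprocess")
    def _preprocess():
        filt_rules = preprocess.FilterRules(
            exclude_lineage_terms=frozenset(config.exclude_terms),
            drop_unassigned=taxonomy is not None,
        )
        filtered = (
            preprocess.filter_taxa(table, taxonomy, filt_rules) if taxonomy is not None else table
        )
        rare, alpha = preprocess.rarefy(
            filtered,
            config.rarefaction_depth,
            config.rarefaction_iterations,
            seed=config.stage_seed("preprocess"),
            shannon_base=config.shannon_base,
        )
        factors = preprocess.tmm_factors(rare)
        state["rarefied"] = rare
        state["alpha"] = alpha
        state["normalized"] = preprocess.apply_factors(rare, factors)
        state["meta"] = metadata.table.loc[rare.sample_ids]
        rare.write(out / "rarefied_counts.tsv")
        factors.factors.rename_axis("sample_id").to_csv(out / "tmm_factors.tsv", sep="\t")
        return {
            "n_samples": rare.shape[0],
            "n_asvs": rare.shape[1],
            "n_asvs_input": table.shape[1],
            "depth": config.rarefaction_depth,
        }

    @stage("alpha")
    def _alpha():
        alpha = state["alpha"]
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        meta = state["meta"]
        season_cmp = diversity.group_compare(
            alpha["richness"].to_numpy(), meta["season"], method="t_test"
        )
        chla_fit = diversity.quadratic_fit(meta["chla"].to_numpy(), alpha["richness"].to_numpy())
        return {
            "richness_range": [float(alpha["richness"].min()), float(alpha["richness"].max())],
            "shannon_range": [float(alpha["shannon"].min()), float(alpha["shannon"].max())],
            "season_t_test": season_cmp,
            "richness_vs_chla": {
                "shape": chla_fit.shape,
                "peak_x": chla_fit.peak_x,
                "r2": chla_fit.r2,
                "p_model": chla_fit.p_model,
            },
        }

    @stage("beta")
    def _beta():
        bc = diversity.bray_curtis(state["normalized"])
        bc.write(out / "bray_curtis.tsv")
        meta = state["meta"]
        res = {}
        factors = {
            "season": meta["season"],
            "depth": meta["depth_m"].astype(str),
            "chla_level": diversity.chla_level(
                meta["chla"].to_numpy(), config.chla_bin_edges
            ).astype(str).to_numpy(),
        }
        rng_seed = config.stage_seed("beta")
        for i, (name, groups) in enumerate(factors.items()):
            counts = pd.Series(list(groups)).value_counts()
            if len(counts) < 2 or (counts < 2).any():
                res[name] = {"skipped": "group with <2 members"}
                continue
            pr = diversity.permanova(bc, groups, config.n_permutations, seed=rng_seed + i)
            res[name] = {
                "pseudo_f": pr.pseudo_f,
                "r2": pr.r2,
                "p": pr.p_value,
                "n_permutations": pr.n_permutations,
            }
        coords, stress = diversity.nmds(bc, seed=rng_seed)
        coords.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        res["nmds_stress"] = stress
        state["bray_curtis"] = bc
        return res

    @stage("decay")
    def _decay():
        meta = state["meta"]
        sor = diversity.sorensen_similarity(state["rarefied"])
        geo = spatial.geo_distance_matrix(
            meta["latitude"].to_numpy(), meta["longitude"].to_numpy(), labels=sor.labels
        )
        res = {}
        for scope in ("spring", "autumn", "combined"):
            labels = (
                sor.labels
                if scope == "combined"
                else [s for s, seas in zip(sor.labels, meta["season"]) if seas == scope]
            )
            if len(labels) < 4:
                res[scope] = {"skipped": "too few samples"}
                continue
            try:
                fit = spatial.distance_decay(sor.subset(labels), geo.subset(labels))
            except ValueError as exc:  # e.g. all usable pairs at one distance
                res[scope] = {"skipped": str(exc)}
                continue
            res[scope] = {
                "z": fit.z,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "adj_r2": fit.adj_r2,
                "p": fit.p_value,
                "n_pairs": fit.n_pairs,
                "n_excluded": fit.n_excluded,
            }
        return res

    @stage("vpa")
    def _vpa():
        meta = state["meta"]
        y = preprocess.hellinger(state["rarefied"])
        env = ordination.sqrt_transform_env(meta[list(config.env_variables)])
        env_kept = ordination.vif_prune(env)
        x, ycoord = spatial.to_cartesian(
            meta["latitude"].to_numpy(), meta["longitude"].to_numpy()
        )
        from scipy.spatial.distance import pdist, squareform

        dxy = squareform(pdist(np.column_stack([x, ycoord])))
        from microeuk.io import DistanceMatrix

        basis = spatial.pcnm(DistanceMatrix(list(meta.index), dxy, "euclidean"))
        seed = config.stage_seed("vpa")
        sel_env = ordination.forward_select(
            y, env[env_kept], n_permutations=config.n_permutations, seed=seed
        )
        sel_spa = ordination.forward_select(
            y, basis.eigenvectors, n_permutations=config.n_permutations, seed=seed + 1
        )
        basis.eigenvectors.to_csv(out / "pcnm_axes.tsv", sep="\t")
        if not sel_env and not sel_spa:
            # nothing survives selection: all variation unexplained
            return {
                "vif_retained": env_kept,
                "selected_env": [],
                "selected_spatial": [],
                "fractions": {"pure_env": 0.0, "shared": 0.0, "pure_spatial": 0.0, "residual": 1.0},
                "p_pure_env": None,
                "p_pure_spatial": None,
            }
        vpa = ordination.variation_partition(
            y,
            env[sel_env] if sel_env else None,
            basis.eigenvectors[sel_spa] if sel_spa else None,
            n_permutations=config.n_permutations,
            seed=seed + 2,
        )
        return {
            "vif_retained": env_kept,
            "selected_env": sel_env,
            "selected_spatial": sel_spa,
            "fractions": vpa.fractions(),
            "p_pure_env": vpa.p_a,
            "p_pure_spatial": vpa.p_c,
        }

    @stage("ncm")
    def _ncm():
        result = ncm.ncm_analysis(
            state["rarefied"], n_reads=config.rarefaction_depth, ci_level=config.ncm_ci_level
        )
        result.pop("detail").to_csv(out / "ncm_per_asv.tsv", sep="\t")
        return result

    @stage("traits")
    def _traits():
        if taxonomy is None:
            return {"skipped": "no taxonomy provided"}
        assignments = traits.assign_traits(taxonomy, rules)
        profile = traits.functional_profile(state["rarefied"], assignments)
        profile.to_csv(out / "functional_profile.tsv", sep="\t")
        state["profile"] = profile
        meta = state["meta"]
        fits = {}
        for mode, env_var, model in (
            ("phototroph", "chla", "quadratic"),
            ("heterotroph", "chla", "quadratic"),
            ("mixotroph", "DO", "linear"),
        ):
            if profile[f"prop_{mode}"].isna().all():
                continue
            fit = traits.gradient_response(profile, meta[env_var].to_numpy(), mode, model)
            if model == "quadratic":
                fits[f"{mode}_vs_{env_var}"] = {
                    "model": model,
                    "shape": fit.shape,
                    "peak_x": fit.peak_x,
                    "r2": fit.r2,
                    "p": fit.p_model,
                }
            else:
                fits[f"{mode}_vs_{env_var}"] = {
                    "model": model,
                    "slope": fit.slope,
                    "r2": fit.r2,
                    "p": fit.p_value,
                }
        means = {
            m: float(profile[f"prop_{m}"].mean(skipna=True)) for m in traits.MODES
        }
        return {"mean_proportions": means, "gradient_fits": fits}

    @stage("rf")
    def _rf():
        if "profile" not in state:
            return {"skipped": "no functional profile"}
        meta = state["meta"]
        env = meta[list(config.env_variables)]
        seed = config.stage_seed("rf")
        res = {}
        for i, mode in enumerate(traits.MODES):
            yvals = state["profile"][f"prop_{mode}"].to_numpy(dtype=float)
            if np.isnan(yvals).any() or np.ptp(yvals) == 0:
                res[mode] = {"skipped": "degenerate response"}
                continue
            imp = rf_importance(
                env,
                yvals,
                n_trees=config.rf_trees,
                n_null=config.rf_null,
                cv_folds=config.rf_cv_folds,
                seed=seed + i,
            )
            res[mode] = {
                "explained_variance_pct": imp.explained_variance_pct,
                "cv_r2": imp.cv_r2,
                "importances": imp.importances.round(10).to_dict(orient="index"),
            }
        return res

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
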