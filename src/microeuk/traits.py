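"""Trait-based trophic classification of microeukaryote lineages.

Taxonomic lineages are mapped to one of three simplified trophic modes —
phototroph, mixotroph, heterotroph — by rank-addressed rules.  The rule
matched at the deepest lineage rank wins (a genus-level rule overrides a
division-level one); ties at the same depth are broken by rule priority.

The shipped :data:`DEFAULT_RULES` table is a replaceable default covering
common freshwater lineages; analyses accept a user rule TSV with columns
rank, name, mode, priority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microeuk.io import RANKS, CommunityTable, TaxonomyTable
from microeuk.diversity import QuadraticFit, LinearFit, linear_fit, quadratic_fit

MODES = ("phototroph", "mixotroph", "heterotroph")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TraitRule:
    rank: str  # one of the 8 ranks, or "any"
    name: str  # exact taxon name to match at that rank
    mode: str
    priority: int

    def __post_init__(self) -> None:
        if self.rank != "any" and self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


# Replaceable default trophic-mode lookup for common freshwater lineages.
# Division-level fallbacks sit at low priority; genus/class refinements
# (e.g. heterotrophic dinoflagellates) override them by rank depth.
DEFAULT_RULES: tuple[TraitRule, ...] = (
    TraitRule("division", "Chlorophyta", "phototroph", 10),
    TraitRule("division", "Haptophyta", "phototroph", 11),
    TraitRule("class", "Bacillariophyta", "phototroph", 12),
    TraitRule("class", "Eustigmatophyceae", "phototroph", 13),
    TraitRule("class", "Xanthophyceae", "phototroph", 14),
    TraitRule("division", "Cryptophyta", "mixotroph", 20),
    TraitRule("class", "Chrysophyceae", "mixotroph", 21),
    TraitRule("class", "Dinophyceae", "mixotroph", 22),
    TraitRule("division", "Dinoflagellata", "mixotroph", 23),
    TraitRule("class", "Raphidophyceae", "mixotroph", 24),
    TraitRule("division", "Euglenozoa", "heterotroph", 30),
    TraitRule("division", "Ciliophora", "heterotroph", 31),
    TraitRule("division", "Cercozoa", "heterotroph", 32),
    TraitRule("division", "Fungi", "heterotroph", 33),
    TraitRule("class", "Ascomycota", "heterotroph", 34),
    TraitRule("class", "Basidiomycota", "heterotroph", 35),
    TraitRule("class", "Chytridiomycota", "heterotroph", 36),
    TraitRule("division", "Apicomplexa", "heterotroph", 37),
    TraitRule("class", "Bicosoecida", "heterotroph", 38),
    TraitRule("division", "Katablepharidophyta", "heterotroph", 39),
    TraitRule("genus", "Noctiluca", "heterotroph", 50),
    TraitRule("genus", "Gyrodinium", "heterotroph", 51),
    TraitRule("genus", "Paraphysomonas", "heterotroph", 52),
)


def read_trait_rules(path) -> list[TraitRule]:
    """Load trait rules from a TSV with columns rank, name, mode, priority."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": str, "name": str, "mode": str})
    rules = [
        TraitRule(str(r["rank"]), str(r["name"]), str(r["mode"]), int(r["priority"]))
        for _, r in df.iterrows()
    ]
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    return rules


def write_trait_rules(rules, path) -> None:
    pd.DataFrame(
        [(r.rank, r.name, r.mode, r.priority) for r in rules],
        columns=["rank", "name", "mode", "priority"],
    ).to_csv(path, sep="\t", index=False)


def assign_traits(taxonomy: TaxonomyTable, rules=None) -> pd.Series:
    """Map each ASV to a trophic mode (or ``unclassified``).

    A rule matches when its name equals the lineage entry at its rank
    ("any" matches at whatever rank the name occurs).  Deepest matching
    rank wins; ties break by higher priority.  Deterministic and
    independent of rule order.
    """
    rules = list(rules) if rules is not None else list(DEFAULT_RULES)
    rank_index = {r: i for i, r in enumerate(RANKS)}
    out = {}
    for asv in taxonomy.asv_ids:
        lineage = taxonomy.lineage(asv)
        best: tuple[int, int, str] | None = None  # (depth, priority, mode)
        for rule in rules:
            if rule.rank == "any":
                depths = [i for i, name in enumerate(lineage) if name == rule.name]
                if not depths:
                    continue
                depth = max(depths)
            else:
                depth = rank_index[rule.rank]
                if lineage[depth] != rule.name:
                    continue
            key = (depth, rule.priority, rule.mode)
            if best is None or key[:2] > best[:2]:
                best = key
        out[asv] = best[2] if best else UNCLASSIFIED
    return pd.Series(out, name="mode").rename_axis("asv_id")


def functional_profile(table: CommunityTable, assignments: pd.Series) -> pd.DataFrame:
    """Per-sample richness and read proportion of each trophic mode.

    Read proportions are over classified reads; the unclassified read
    fraction (of all reads) is reported separately, so
    mode proportions sum to 1 and richness over modes plus unclassified
    equals total sample richness.
    """
    modes = assignments.reindex(table.asv_ids).fillna(UNCLASSIFIED)
    counts = table.counts
    rows = []
    for sample in table.sample_ids:
        vec = counts.loc[sample]
        present = vec > 0
        total = float(vec.sum())
        rec = {"sample_id": sample}
        classified_reads = float(vec[modes.isin(MODES).to_numpy()].sum())
        for mode in MODES:
            mask = (modes == mode).to_numpy()
            rec[f"richness_{mode}"] = int((present & mask).sum())
            rec[f"prop_{mode}"] = (
                float(vec[mask].sum()) / classified_reads if classified_reads > 0 else np.nan
            )
        uncl = (modes == UNCLASSIFIED).to_numpy()
        rec["richness_unclassified"] = int((present & uncl).sum())
        rec["unclassified_fraction"] = float(vec[uncl].sum()) / total if total > 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id")


def gradient_response(
    profile: pd.DataFrame,
    env_values,
    mode: str,
    model: str = "quadratic",
    response: str = "proportion",
) -> QuadraticFit | LinearFit:
    """Fit a trophic-mode share (or richness) against an environment gradient.

    ``model`` selects a quadratic (hump/U classification) or linear fit;
    samples are matched positionally to ``env_values``.
    """
    col = f"prop_{mode}" if response == "proportion" else f"richness_{mode}"
    y = profile[col].to_numpy(dtype=float)
    x = np.asarray(env_values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate environment variable")
    ok = np.isfinite(x) & np.isfinite(y)
    if model == "quadratic":
        return quadratic_fit(x[ok], y[ok])
    if model == "linear":
        return linear_fit(x[ok], y[ok])
    raise ValueError(f"unknown model {model!r}")
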