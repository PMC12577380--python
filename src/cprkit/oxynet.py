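"""Oxygen-related metabolic profiling of genome annotations.

Per-genome EC numbers are mapped onto a three-way partition of
metabolic reactions by oxygen dependence: *oxic* reactions that require
oxygen (or oxygen-derived metabolites), *anoxic* reactions possible
strictly without oxygen, and *augmented* reactions — anaerobic
processes replaced by aerobic alternatives. Genes carrying more than
one EC number are excluded from the mapping, ECs are deduplicated per
genome, and only genomes meeting completeness/contamination quality
gates are profiled. A small catalog of directly oxygen-utilizing
enzymes (oxygenases and oxidases) is screened separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .community_stats import dunn_posthoc, group_difference
from .errors import ValidationError
from .io_formats import (
    MagAnnotation,
    ReactionClassTable,
    read_reaction_classes,
)

logger = logging.getLogger(__name__)

#: Directly oxygen-utilizing enzymes screened in CPR genomes, with
#: standard-nomenclature EC assignments (config-overridable).
DEFAULT_OXYGEN_ENZYMES: dict[str, str] = {
    "l-aspartate oxidase": "1.4.3.16",
    "kynurenine 3-monooxygenase": "1.14.13.9",
    "pyridoxamine 5'-phosphate oxidase": "1.4.3.5",
    "catechol 2,3-dioxygenase": "1.13.11.2",
    "4-hydroxyphenylpyruvate dioxygenase": "1.13.11.27",
    "d-amino-acid oxidase": "1.4.3.3",
}


@dataclass
class MagOxyProfile:
    """Oxygen-dependence category counts for one genome's EC set."""

    mag_id: str
    taxon_class: str
    n_oxic: int
    n_anoxic: int
    n_augmented: int
    n_unclassified: int
    oxygen_enzyme_hits: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_oxic + self.n_anoxic + self.n_augmented + self.n_unclassified


def packaged_reaction_classes() -> ReactionClassTable:
    """Load the reaction-class table shipped with the package.

    The shipped table is a synthetic stand-in with the real table's
    structure (the published oxic/anoxic network is not redistributed
    here); swap in a real EC->category TSV for production use.
    """
    with resources.as_file(
        resources.files("cprkit.data") / "reaction_classes_synthetic.tsv"
    ) as path:
        return read_reaction_classes(path)


def filter_mags(
    mags: Sequence[MagAnnotation],
    *,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagAnnotation]:
    """Keep genomes with completeness >= min and contamination <= max."""
    return [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination <= max_contamination
    ]


def extract_ec_set(mag: MagAnnotation) -> set[str]:
    """Deduplicated EC numbers from single-EC genes of one genome.

    Genes with more than one EC number are excluded entirely; genes
    without ECs are ignored; duplicates across genes collapse.
    """
    return {g.ec_numbers[0] for g in mag.genes if len(g.ec_numbers) == 1}


def classify_reactions(
    ecs: set[str],
    table: ReactionClassTable,
    *,
    mag_id: str = "",
    taxon_class: str = "",
) -> MagOxyProfile:
    """Count each EC once in its oxygen-dependence category."""
    counts = {"oxic": 0, "anoxic": 0, "augmented": 0, None: 0}
    for ec in ecs:
        counts[table.category(ec)] += 1
    return MagOxyProfile(
        mag_id=mag_id,
        taxon_class=taxon_class,
        n_oxic=counts["oxic"],
        n_anoxic=counts["anoxic"],
        n_augmented=counts["augmented"],
        n_unclassified=counts[None],
    )


def flag_oxygen_enzymes(
    ecs: set[str], catalog: Mapping[str, str] = DEFAULT_OXYGEN_ENZYMES
) -> list[tuple[str, str]]:
    """Catalog enzymes whose EC appears in the genome's EC set."""
    return [(label, ec) for label, ec in catalog.items() if ec in ecs]


def profile_mags(
    mags: Sequence[MagAnnotation],
    table: ReactionClassTable,
    *,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    catalog: Mapping[str, str] = DEFAULT_OXYGEN_ENZYMES,
) -> list[MagOxyProfile]:
    """Quality-filter genomes and compute their oxygen profiles."""
    kept = filter_mags(
        mags, min_completeness=min_completeness, max_contamination=max_contamination
    )
    profiles = []
    for mag in kept:
        ecs = extract_ec_set(mag)
        profile = classify_reactions(ecs, table, mag_id=mag.mag_id, taxon_class=mag.taxon_class)
        profile.oxygen_enzyme_hits = flag_oxygen_enzymes(ecs, catalog)
        profiles.append(profile)
    return profiles


def profiles_frame(profiles: Sequence[MagOxyProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mag_id": [p.mag_id for p in profiles],
            "taxon_class": [p.taxon_class for p in profiles],
            "n_oxic": [p.n_oxic for p in profiles],
            "n_anoxic": [p.n_anoxic for p in profiles],
            "n_augmented": [p.n_augmented for p in profiles],
            "n_unclassified": [p.n_unclassified for p in profiles],
            "oxygen_enzymes": [
                ";".join(label for label, _ in p.oxygen_enzyme_hits) for p in profiles
            ],
        }
    ).set_index("mag_id")


def compare_function_prevalence(
    presence: pd.DataFrame,
    classes: pd.Series,
    focal_classes: Sequence[str],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test functions for prevalence differences: focal classes vs rest.

    ``presence`` is a genomes x functions 0/1 matrix (KO or function
    label columns); genomes are split into a focal group (union of
    ``focal_classes``) and all other genomes. Per function a
    Kruskal-Wallis omnibus test is followed by Dunn's post hoc with
    Bonferroni correction; a function is selected when its corrected
    pairwise p is below alpha. Functions where a group has fewer than
    two genomes are skipped with a log entry.
    """
    classes = classes.loc[presence.index]
    focal_mask = classes.isin(set(focal_classes))
    if focal_mask.sum() < 2 or (~focal_mask).sum() < 2:
        raise ValidationError("each group needs at least two genomes")
    rows = []
    for fn in presence.columns:
        vals = presence[fn].astype(float)
        groups = {
            "focal": vals[focal_mask].to_numpy(),
            "other": vals[~focal_mask].to_numpy(),
        }
        if min(len(v) for v in groups.values()) < 2:
            logger.info("function %s: group with < 2 genomes; skipped", fn)
            continue
        comparison = group_difference(groups, post_hoc=True, correction="bonferroni")
        p_adj = float(comparison.pairwise["p_adjusted"].iloc[0])
        prev_focal = float(groups["focal"].mean())
        prev_other = float(groups["other"].mean())
        rows.append(
            {
                "function": fn,
                "statistic": comparison.statistic,
                "p_omnibus": comparison.p_value,
                "p_adjusted": p_adj,
                "prevalence_focal": prev_focal,
                "prevalence_other": prev_other,
                "selected": bool(p_adj < alpha),
                "direction": "focal_enriched" if prev_focal > prev_other else "other_enriched",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "function",
            "statistic",
            "p_omnibus",
            "p_adjusted",
            "prevalence_focal",
            "prevalence_other",
            "selected",
            "direction",
        ],
    )


__all__ = [
    "DEFAULT_OXYGEN_ENZYMES",
    "MagOxyProfile",
    "classify_reactions",
    "compare_function_prevalence",
    "dunn_posthoc",
    "extract_ec_set",
    "filter_mags",
    "flag_oxygen_enzymes",
    "packaged_reaction_classes",
    "profile_mags",
    "profiles_frame",
]
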