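"""CPR-subset diversity, supplement associations and rank-based group tests.

The Spearman branch deliberately uses a stringent raw-p cutoff
(alpha = 0.001) rather than multiplicity correction: correlations on
compositional relative abundances are fragile, and the stringent cutoff
is the guard. Externally computed differential-abundance results (e.g.
from a compositional bias-aware method) can be merged in through
:func:`ingest_differential_abundance`, where the conventional adjusted
p < 0.05 rule applies instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError
from .io_formats import (
    RelAbundanceTable,
    SampleRecord,
    TaxonomyTable,
    metadata_frame,
)

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 9  # exact permutation p for tiny samples, asymptotic above


def shannon_cpr(rel: RelAbundanceTable, taxonomy: TaxonomyTable) -> pd.Series:
    """Shannon diversity (natural log) of the renormalized CPR subset.

    Per sample, relative abundances are restricted to CPR ASVs and
    renormalized to sum to one, so H = -sum p ln p measures CPR
    evenness. Samples with zero CPR abundance are omitted with a log
    entry.
    """
    cpr = [a for a in rel.asv_ids if taxonomy.is_cpr.get(a, False)]
    sub = rel.data[cpr].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    out = {}
    for i, sid in enumerate(rel.sample_ids):
        if totals[i] == 0:
            logger.warning("sample %s: no CPR abundance; Shannon undefined", sid)
            continue
        p = sub[i] / totals[i]
        p = p[p > 0]
        out[sid] = float(-(p * np.log(p)).sum())
    return pd.Series(out, name="shannon_cpr", dtype=float)


# ---------------------------------------------------------------------------
# Spearman association branch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    asv_id: str
    parameter: str
    rho: float
    p_value: float
    significant: bool
    direction: str  # positive | negative


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midranks; exact permutation p for n <= 9."""
    n = len(x)
    rho, p = stats.spearmanr(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if n <= EXACT_P_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def supplement_association(
    rel: RelAbundanceTable,
    records: Sequence[SampleRecord],
    *,
    taxonomy: TaxonomyTable | None = None,
    parameters: Sequence[str] | None = None,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Spearman rank correlation of ASV abundance with binary parameters.

    Parameters are supplement presence/absence indicators plus an
    ``oxic`` indicator; parameters constant across the sample set are
    skipped with a log entry. With a taxonomy, testing is restricted to
    CPR ASVs. Returns a tidy frame of AssociationResult rows (all
    tested pairs, with a ``significant`` flag at the given alpha).
    """
    meta = metadata_frame(records).loc[rel.data.index]
    if parameters is None:
        supplements = sorted({s for r in records for s in r.supplements})
        parameters = supplements + ["oxic"]
    asvs = rel.asv_ids
    if taxonomy is not None:
        asvs = [a for a in asvs if taxonomy.is_cpr.get(a, False)]
    rows = []
    for param in parameters:
        if param == "oxic":
            indicator = (meta["oxygen_status"] == "oxic").to_numpy(dtype=float)
        else:
            indicator = np.array(
                [param in set(str(s).split(";")) for s in meta["supplements"]],
                dtype=float,
            )
        if indicator.min() == indicator.max():
            logger.info("parameter %s constant across samples; skipped", param)
            continue
        for asv in asvs:
            y = rel.data[asv].to_numpy(dtype=float)
            rho, p = _spearman(indicator, y)
            if math.isnan(rho):
                continue
            rows.append(
                {
                    "asv_id": asv,
                    "parameter": param,
                    "rho": rho,
                    "p_value": p,
                    "significant": bool(p < alpha),
                    "direction": "positive" if rho > 0 else "negative",
                }
            )
    return pd.DataFrame(
        rows, columns=["asv_id", "parameter", "rho", "p_value", "significant", "direction"]
    )


def ingest_differential_abundance(
    source: str | Path | pd.DataFrame, *, alpha: float = 0.05
) -> pd.DataFrame:
    """Load externally computed differential-abundance results.

    Expects columns asv_id, parameter, log2_fold_change, adjusted_p;
    adds ``significant`` (adjusted p < alpha) and ``direction`` columns
    so the table aligns with the Spearman branch output.
    """
    df = (
        source.copy()
        if isinstance(source, pd.DataFrame)
        else pd.read_csv(source, sep="\t")
    )
    required = {"asv_id", "parameter", "log2_fold_change", "adjusted_p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"differential-abundance table lacks columns {sorted(missing)}")
    df["significant"] = df["adjusted_p"] < alpha
    df["direction"] = np.where(df["log2_fold_change"] > 0, "positive", "negative")
    return df


def merge_association_reports(
    spearman: pd.DataFrame, differential: pd.DataFrame | None
) -> pd.DataFrame:
    """Stack the Spearman branch with ingested differential-abundance rows."""
    spearman = spearman.assign(method="spearman")
    if differential is None or differential.empty:
        return spearman
    diff = differential.assign(method="differential_abundance")
    return pd.concat([spearman, diff], ignore_index=True, sort=False)


# ---------------------------------------------------------------------------
# rank-based group comparison (omnibus + Dunn's post hoc)
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    statistic: float  # Kruskal-Wallis H
    p_value: float
    groups: list[str]
    pairwise: pd.DataFrame | None  # Dunn's z and (corrected) p per pair


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    *,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise rank-sum comparisons with tie correction.

    z for a pair is the difference of mean pooled ranks over its
    standard error; two-sided normal p values are Bonferroni-multiplied
    by the number of pairs when requested.
    """
    if correction not in ("bonferroni", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    i = 0
    for g in groups:
        n = len(values_by_group[g])
        mean_ranks[g] = float(ranks[i : i + n].mean())
        sizes[g] = n
        i += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for a, b in combinations(groups, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if correction == "bonferroni":
            p = min(1.0, p * n_pairs)
        rows.append({"group_a": a, "group_b": b, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_adjusted"])


def group_difference(
    values_by_group: Mapping[str, Sequence[float]],
    *,
    post_hoc: bool = True,
    correction: str = "bonferroni",
    min_group_size: int = 2,
) -> GroupComparison:
    """Kruskal-Wallis omnibus test with optional Dunn's post hoc.

    Groups smaller than ``min_group_size`` are excluded with a log
    entry; at least two usable groups are required.
    """
    usable = {
        g: np.asarray(v, dtype=float)
        for g, v in values_by_group.items()
        if len(v) >= min_group_size
    }
    for g in values_by_group:
        if g not in usable:
            logger.info("group %s has < %d members; excluded", g, min_group_size)
    if len(usable) < 2:
        raise ValidationError("need at least two groups with enough members")
    samples = list(usable.values())
    if np.unique(np.concatenate(samples)).size == 1:
        h, p = 0.0, 1.0  # all observations tied: no evidence of difference
    else:
        h, p = stats.kruskal(*samples)
    pairwise = dunn_posthoc(usable, correction=correction) if post_hoc else None
    return GroupComparison(
        statistic=float(h), p_value=float(p), groups=list(usable), pairwise=pairwise
    )
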