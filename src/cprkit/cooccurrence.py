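"""Co-occurrence networks between CPR and non-CPR ASVs per treatment.

Two edge-weight estimators are provided. The default, "rank", is
pairwise Spearman correlation of relative abundances — deterministic
and dependency-light. "sparcc" implements the log-ratio
basis-correlation procedure for compositional counts: with pseudocount
fractions x, the variation matrix t_ij = var(log(x_i/x_j)) is inverted
for approximate basis variances under a sparsity assumption, strongly
correlated pairs are iteratively excluded from the system, and
correlations are recomputed. The deterministic pseudocount variant is
used by default (no Dirichlet resampling), so identical inputs give
identical networks.

Edge filtering follows the CPR-focused rules: keep only edges with at
least one CPR endpoint, positive weight strictly exceeding the
threshold (default 0.1); for order-level link counting, CPR-CPR edges
are excluded, at most the strongest 200 edges are counted, and non-CPR
orders with fewer than three links total are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import CountTable, TaxonomyTable

logger = logging.getLogger(__name__)

MIN_SAMPLES = 4


@dataclass
class CoocNetwork:
    """Undirected weighted ASV co-occurrence edges for one treatment."""

    treatment_group: str
    edges: pd.DataFrame  # columns asv_a, asv_b, weight; asv_a < asv_b

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and not (e["asv_a"] < e["asv_b"]).all():
            raise ValidationError("edges must be canonically ordered (asv_a < asv_b)")


@dataclass
class EdgeCountChord:
    """CPR-order x non-CPR-order link counts for one treatment."""

    treatment_group: str
    rows: pd.DataFrame  # columns cpr_order, non_cpr_order, n_links


def _prevalence_filter(counts: pd.DataFrame, floor: float) -> pd.DataFrame:
    prev = (counts > 0).mean(axis=0)
    kept = counts.loc[:, prev >= floor]
    dropped = counts.shape[1] - kept.shape[1]
    if dropped:
        logger.info("prevalence floor %.2f removed %d ASVs", floor, dropped)
    return kept


def sparcc_correlations(
    counts: np.ndarray,
    *,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_excluded_pairs: int = 10,
) -> np.ndarray:
    """Basis correlations from compositional counts (samples x ASVs).

    Deterministic pseudocount variant: fractions are (counts + c) row-
    normalized; t_ij = var(log(x_i/x_j)); basis variances solve the
    linear system implied by E[t_ij] = w_i + w_j over non-excluded
    pairs; the most strongly correlated pair above the exclusion
    threshold is removed from the system each round, up to the cap.
    """
    frac = (counts + pseudocount).astype(float)
    frac /= frac.sum(axis=1, keepdims=True)
    logf = np.log(frac)
    m = logf.shape[1]
    if m < 2:
        raise ValidationError("need at least two ASVs for correlation estimation")
    # variation matrix
    var_log = logf.var(axis=0, ddof=1)
    cov_log = np.cov(logf, rowvar=False, ddof=1)
    t_mat = var_log[:, None] + var_log[None, :] - 2.0 * cov_log
    np.fill_diagonal(t_mat, 0.0)

    included = np.ones((m, m), dtype=bool)
    np.fill_diagonal(included, False)
    excluded_pairs: list[tuple[int, int]] = []
    rho = np.zeros((m, m))
    for _ in range(max_excluded_pairs + 1):
        degree = included.sum(axis=1)
        a = included.astype(float)
        np.fill_diagonal(a, degree)
        t_vec = (t_mat * included).sum(axis=1)
        try:
            w = np.linalg.solve(a, t_vec)
        except np.linalg.LinAlgError:  # degenerate system after exclusions
            break
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = np.clip((w[:, None] + w[None, :] - t_mat) / denom, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if len(excluded_pairs) >= max_excluded_pairs:
            break
        abs_rho = np.abs(rho)
        abs_rho[~included] = 0.0
        iu = np.triu_indices(m, 1)
        order = np.argmax(abs_rho[iu])
        i, j = iu[0][order], iu[1][order]
        if abs_rho[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        excluded_pairs.append((int(i), int(j)))
    return rho


def estimate_network(
    counts: CountTable | pd.DataFrame,
    *,
    treatment_group: str = "",
    method: str = "rank",
    prevalence_floor: float = 0.2,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_excluded_pairs: int = 10,
) -> CoocNetwork:
    """Estimate pairwise co-occurrence weights for one treatment's samples.

    "rank": Spearman correlation on total-sum-scaled abundances; edges
    involving a constant ASV are undefined and omitted. "sparcc": see
    :func:`sparcc_correlations`. ASVs present in fewer than
    ``prevalence_floor`` of the samples are removed first; fewer than
    four samples is an error.
    """
    df = counts.data if isinstance(counts, CountTable) else counts
    if df.shape[0] < MIN_SAMPLES:
        raise ValidationError(
            f"co-occurrence estimation needs >= {MIN_SAMPLES} samples, got {df.shape[0]}"
        )
    df = _prevalence_filter(df, prevalence_floor)
    asvs = list(df.columns)
    arr = df.to_numpy(dtype=float)
    if method == "rank":
        if arr.shape[1] < 2:
            raise ValidationError("need at least two ASVs after prevalence filtering")
        totals = arr.sum(axis=1, keepdims=True)
        rel = arr / np.where(totals == 0, 1.0, totals)
        ranks = np.apply_along_axis(stats.rankdata, 0, rel)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)  # NaN for constant columns
    elif method == "sparcc":
        rho = sparcc_correlations(
            arr,
            pseudocount=pseudocount,
            exclusion_threshold=exclusion_threshold,
            max_excluded_pairs=max_excluded_pairs,
        )
    else:
        raise ValidationError(f"unknown network method {method!r}")
    rho = np.asarray(rho, dtype=float)
    rows = []
    m = len(asvs)
    for i in range(m):
        for j in range(i + 1, m):
            w = rho[i, j]
            if np.isnan(w):
                continue  # constant ASV under rank correlation
            a, b = sorted((asvs[i], asvs[j]))
            rows.append({"asv_a": a, "asv_b": b, "weight": float(w)})
    edges = pd.DataFrame(rows, columns=["asv_a", "asv_b", "weight"])
    return CoocNetwork(treatment_group=treatment_group, edges=edges)


def filter_cpr_edges(
    net: CoocNetwork, taxonomy: TaxonomyTable, *, min_weight: float = 0.1
) -> CoocNetwork:
    """Keep edges with a CPR endpoint and weight strictly above threshold."""
    is_cpr = taxonomy.is_cpr
    missing = (set(net.edges["asv_a"]) | set(net.edges["asv_b"])) - set(taxonomy.asv_ids)
    if missing:
        raise ValidationError(f"edges reference ASVs without taxonomy: {sorted(missing)[:5]}")
    e = net.edges
    mask = (
        (e["asv_a"].map(is_cpr) | e["asv_b"].map(is_cpr))
        & (e["weight"] > min_weight)
    )
    return CoocNetwork(net.treatment_group, e[mask].reset_index(drop=True))


def count_order_links(
    net: CoocNetwork,
    taxonomy: TaxonomyTable,
    *,
    top_n: int = 200,
    min_links: int = 3,
) -> EdgeCountChord:
    """Count filtered links between each CPR order and each non-CPR order.

    CPR-CPR edges are excluded; when more than ``top_n`` edges remain,
    only the ``top_n`` with the highest weight are counted (ties broken
    by the canonical edge id for determinism); non-CPR orders with
    fewer than ``min_links`` links in total are dropped.
    """
    is_cpr = taxonomy.is_cpr
    e = net.edges.copy()
    cpr_a = e["asv_a"].map(is_cpr)
    cpr_b = e["asv_b"].map(is_cpr)
    e = e[cpr_a ^ cpr_b].copy()  # exactly one CPR endpoint
    if len(e) > top_n:
        e = e.sort_values(
            ["weight", "asv_a", "asv_b"], ascending=[False, True, True]
        ).head(top_n)
    order = {a: taxonomy.rank_of(a, "order") for a in set(e["asv_a"]) | set(e["asv_b"])}
    rows = []
    for _, row in e.iterrows():
        a, b = row["asv_a"], row["asv_b"]
        cpr_asv, other_asv = (a, b) if is_cpr[a] else (b, a)
        rows.append({"cpr_order": order[cpr_asv], "non_cpr_order": order[other_asv]})
    if not rows:
        return EdgeCountChord(
            net.treatment_group,
            pd.DataFrame(columns=["cpr_order", "non_cpr_order", "n_links"]),
        )
    tidy = (
        pd.DataFrame(rows)
        .groupby(["cpr_order", "non_cpr_order"], sort=True)
        .size()
        .rename("n_links")
        .reset_index()
    )
    per_order = tidy.groupby("non_cpr_order")["n_links"].sum()
    keep = tidy["non_cpr_order"].map(per_order) >= min_links
    return EdgeCountChord(net.treatment_group, tidy[keep].reset_index(drop=True))
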