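"""Exponential growth-rate and doubling-time estimation per ASV.

Under exponential growth N_i(t) = N_i(0) e^{k t}, the natural log of
the absolute abundance is linear in time; the per-ASV growth rate k is
the ordinary-least-squares slope of ln(copies/L) on incubation time in
days. Observations where the ASV is absent (zero copies) are dropped —
the fit conditions on occurrence — and a fit is attempted only when the
ASV occurs at three or more distinct time points. Doubling times
T_d = ln 2 / k are defined for positive rates only; negative rates are
discarded from all summaries. Because a single slope is fitted across
the whole incubation, the estimates are conservative: an organism that
grew fast early and stalled later is assigned the lower average rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AbsAbundanceTable,
    SampleRecord,
    TaxonomyTable,
    metadata_frame,
)

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
MIN_TIME_POINTS = 3


@dataclass(frozen=True)
class GrowthEstimate:
    """Fitted exponential growth parameters for one ASV in one experiment."""

    asv_id: str
    experiment_id: str
    k: float  # per-day rate (regression slope)
    ln_n0: float  # intercept: ln copies/L at t = 0
    n_points: int  # regression observations (replicates count separately)
    n_time_points: int  # distinct time values covered
    r_squared: float

    @property
    def doubling_time_days(self) -> float | None:
        return doubling_time(self.k)


def doubling_time(k: float) -> float | None:
    """T_d = ln 2 / k for k > 0; None otherwise (negative rates discarded)."""
    if not math.isfinite(k) or k <= 0:
        return None
    return LN2 / k


def fit_growth_rate(
    abs_table: AbsAbundanceTable,
    records: Sequence[SampleRecord],
    asv_id: str,
    experiment_id: str,
    *,
    include_insitu: bool = False,
    replicate_id: str | None = None,
) -> GrowthEstimate | None:
    """OLS fit of ln(absolute abundance) on time for one ASV/experiment.

    Returns None when the ASV occurs (abundance > 0) at fewer than three
    distinct time points. Field (InSitu) samples are excluded unless
    requested; ``replicate_id`` restricts the fit to one replicate.
    """
    meta = metadata_frame(records)
    sel = meta["experiment_id"] == experiment_id
    if not include_insitu:
        sel &= meta["treatment_group"] != "InSitu"
    if replicate_id is not None:
        sel &= meta["replicate_id"] == replicate_id
    samples = meta.index[sel].intersection(abs_table.data.index)
    if len(samples) == 0:
        return None
    y = abs_table.data.loc[samples, asv_id]
    t = meta.loc[samples, "time_days"].astype(float)
    occ = y > 0
    y, t = y[occ], t[occ]
    n_times = t.nunique()
    if n_times < MIN_TIME_POINTS:
        return None
    res = stats.linregress(t.to_numpy(), np.log(y.to_numpy(dtype=float)))
    return GrowthEstimate(
        asv_id=asv_id,
        experiment_id=experiment_id,
        k=float(res.slope),
        ln_n0=float(res.intercept),
        n_points=int(len(y)),
        n_time_points=int(n_times),
        r_squared=float(res.rvalue**2),
    )


def fit_all_growth_rates(
    abs_table: AbsAbundanceTable,
    records: Sequence[SampleRecord],
    *,
    include_insitu: bool = False,
) -> list[GrowthEstimate]:
    """Fit every (ASV, experiment) combination that meets the filters."""
    experiments = sorted({r.experiment_id for r in records})
    out: list[GrowthEstimate] = []
    for exp in experiments:
        for asv in abs_table.asv_ids:
            est = fit_growth_rate(
                abs_table, records, asv, exp, include_insitu=include_insitu
            )
            if est is not None:
                out.append(est)
    return out


def estimates_frame(estimates: Sequence[GrowthEstimate]) -> pd.DataFrame:
    """Tidy table of growth estimates; doubling time empty for k <= 0."""
    return pd.DataFrame(
        {
            "asv_id": [e.asv_id for e in estimates],
            "experiment_id": [e.experiment_id for e in estimates],
            "k_per_day": [e.k for e in estimates],
            "ln_n0": [e.ln_n0 for e in estimates],
            "n_points": [e.n_points for e in estimates],
            "n_time_points": [e.n_time_points for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "doubling_time_days": [e.doubling_time_days for e in estimates],
        }
    )


def summarize_growth(
    estimates: Sequence[GrowthEstimate],
    taxonomy: TaxonomyTable,
    *,
    group_by: str = "class",
) -> pd.DataFrame:
    """Per-taxon distribution of rates and doubling times, CPR split out.

    Only estimates with positive k enter the summary (negative rates are
    discarded); groups left empty after that filter are omitted with a
    log entry. Quartiles use linear interpolation (the default of the
    surrounding numeric stack).
    """
    rows = []
    by_group: dict[tuple[bool, str], list[GrowthEstimate]] = {}
    for e in estimates:
        group = taxonomy.rank_of(e.asv_id, group_by)
        is_cpr = bool(taxonomy.is_cpr.get(e.asv_id, False))
        by_group.setdefault((is_cpr, group), [])
        if e.k > 0:
            by_group[(is_cpr, group)].append(e)
    for (is_cpr, group), ests in sorted(by_group.items()):
        if not ests:
            logger.info("group %s: no positive-rate estimates; omitted", group)
            continue
        ks = np.array([e.k for e in ests])
        tds = np.array([e.doubling_time_days for e in ests])
        rows.append(
            {
                "group": group,
                "is_cpr": is_cpr,
                "n_estimates": len(ests),
                "k_median": np.median(ks),
                "k_q1": np.percentile(ks, 25),
                "k_q3": np.percentile(ks, 75),
                "td_median_days": np.median(tds),
                "td_q1_days": np.percentile(tds, 25),
                "td_q3_days": np.percentile(tds, 75),
                "td_min_days": tds.min(),
                "td_max_days": tds.max(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "is_cpr",
            "n_estimates",
            "k_median",
            "k_q1",
            "k_q3",
            "td_median_days",
            "td_q1_days",
            "td_q3_days",
            "td_min_days",
            "td_max_days",
        ],
    )
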