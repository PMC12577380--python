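"""Count normalization, qPCR anchoring and fold enrichment.

Counts are first total-sum scaled into relative abundances; multiplying
each sample's composition by its total 16S gene copy number per liter
(from qPCR) yields estimated absolute abundances per ASV, the quantity
all growth and enrichment analyses operate on.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io_formats import (
    AbsAbundanceTable,
    CountTable,
    QpcrTotals,
    RelAbundanceTable,
    SampleRecord,
    metadata_frame,
)

logger = logging.getLogger(__name__)


def total_sum_scale(counts: CountTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total (TSS normalization).

    Samples with zero total counts stay all-zero and are logged.
    """
    arr = counts.data.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        for sid in counts.data.index[zero]:
            logger.warning("sample %s has zero total counts; row left at zero", sid)
    safe = np.where(zero, 1.0, totals)
    rel = arr / safe[:, None]
    return RelAbundanceTable(
        pd.DataFrame(rel, index=counts.data.index.copy(), columns=counts.data.columns.copy())
    )


def absolute_abundance(rel: RelAbundanceTable, qpcr: QpcrTotals) -> AbsAbundanceTable:
    """Anchor relative abundances to qPCR totals (copies per liter)."""
    missing = [s for s in rel.sample_ids if s not in qpcr.totals.index]
    if missing:
        raise ValidationError(
            f"samples without qPCR totals: {', '.join(map(str, missing))}"
        )
    totals = qpcr.totals.loc[rel.data.index].to_numpy()
    abs_arr = rel.data.to_numpy(dtype=float) * totals[:, None]
    return AbsAbundanceTable(
        pd.DataFrame(abs_arr, index=rel.data.index.copy(), columns=rel.data.columns.copy())
    )


def fold_enrichment(
    abs_table: AbsAbundanceTable,
    records: Sequence[SampleRecord],
    *,
    baseline_group: str = "Start",
) -> pd.DataFrame:
    """Maximum fold enrichment of each ASV versus the incubation start.

    The baseline is the mean absolute abundance over the experiment's
    Start replicates (t = 0); later time points are first averaged over
    replicates, and the reported value is the maximum over time points
    of mean(t)/baseline. Only increases (fold > 1) are reported; ASVs
    with a zero baseline are undefined and excluded with a log entry.

    Returns a tidy frame with columns asv_id, experiment_id, max_fold,
    time_of_max_days.
    """
    meta = metadata_frame(records)
    meta = meta.loc[meta.index.intersection(abs_table.data.index)]
    rows = []
    for exp_id, sub in meta.groupby("experiment_id", sort=True):
        if baseline_group == "Start":
            base_mask = (sub["treatment_group"] == "Start") | (
                (sub["time_days"] == 0) & (sub["treatment_group"] != "InSitu")
            )
        else:
            base_mask = sub["treatment_group"] == baseline_group
        base_samples = sub.index[base_mask]
        if len(base_samples) == 0:
            raise ValidationError(
                f"experiment {exp_id!r} has no {baseline_group} (baseline) sample"
            )
        baseline = abs_table.data.loc[base_samples].mean(axis=0)
        later = sub[(~base_mask) & (sub["time_days"] > 0)]
        if later.empty:
            continue
        by_time = (
            abs_table.data.loc[later.index]
            .groupby(later["time_days"])
            .mean()
        )
        for asv in abs_table.asv_ids:
            b = baseline[asv]
            series = by_time[asv]
            if b == 0:
                if (series > 0).any():
                    logger.warning(
                        "ASV %s in experiment %s: zero start baseline; "
                        "fold enrichment undefined, excluded",
                        asv,
                        exp_id,
                    )
                continue
            folds = series / b
            t_max = folds.idxmax()
            fold = float(folds.loc[t_max])
            if fold > 1.0:
                rows.append(
                    {
                        "asv_id": asv,
                        "experiment_id": exp_id,
                        "max_fold": fold,
                        "time_of_max_days": float(t_max),
                    }
                )
    return pd.DataFrame(rows, columns=["asv_id", "experiment_id", "max_fold", "time_of_max_days"])
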