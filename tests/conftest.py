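"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cprkit.io_formats import (
    AbsAbundanceTable,
    CountTable,
    QpcrTotals,
    SampleRecord,
    TaxonomyTable,
    TAXONOMY_RANKS,
)
from cprkit.synthetic import SynthConfig, simulate_experiment


def make_taxonomy(classes: dict[str, tuple[str, str]]) -> TaxonomyTable:
    """Taxonomy from a mapping asv_id -> (class, order)."""
    rows = {
        asv: ("Bacteria", "p", cls, order, "f", "g")
        for asv, (cls, order) in classes.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TAXONOMY_RANKS))
    df.index.name = "asv_id"
    return TaxonomyTable(df)


def exponential_series(
    k: float,
    n0: float,
    times: tuple[float, ...],
    asv_id: str = "ASV0",
    experiment_id: str = "E0",
    n_replicates: int = 1,
) -> tuple[AbsAbundanceTable, list[SampleRecord]]:
    """Noise-free absolute-abundance trajectory N(t) = n0 e^{kt}."""
    records, rows, ids = [], [], []
    for t in times:
        for r in range(n_replicates):
            sid = f"S_t{t:g}_r{r}"
            ids.append(sid)
            rows.append([n0 * np.exp(k * t)])
            records.append(
                SampleRecord(
                    sample_id=sid,
                    experiment_id=experiment_id,
                    treatment_group="Start" if t == 0 else "Auto",
                    time_days=float(t),
                    replicate_id=f"R{r + 1}",
                )
            )
    table = AbsAbundanceTable(
        pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=[asv_id])
    )
    return table, records


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        seed=11,
        n_asv_cpr=8,
        n_asv_noncpr=12,
        n_experiments=2,
        time_points=(0.0, 7.0, 14.0, 21.0),
        n_replicates=2,
        depth=20000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def noise_free_config() -> SynthConfig:
    return SynthConfig(
        seed=3,
        n_asv_cpr=3,
        n_asv_noncpr=3,
        n_experiments=1,
        time_points=(0.0, 2.0, 4.0, 6.0),
        n_replicates=1,
        noise_sd_log=0.0,
        qpcr_noise_sd_log=0.0,
        depth=None,
        n0_median=1.0e8,
        growth_rates=np.array([0.5, 0.1, -0.2, 0.0, 0.3, -0.1]),
        initial_abundances=np.full(6, 1.0e8),
    )
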