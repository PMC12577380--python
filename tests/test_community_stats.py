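"""Shannon diversity of the CPR subset, associations, rank group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprkit.community_stats import (
    dunn_posthoc,
    group_difference,
    ingest_differential_abundance,
    merge_association_reports,
    shannon_cpr,
    supplement_association,
)
from cprkit.errors import FormatError, ValidationError
from cprkit.io_formats import RelAbundanceTable, SampleRecord
from conftest import make_taxonomy


def rel_table(rows, asvs, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    return RelAbundanceTable(pd.DataFrame(rows, index=samples, columns=asvs))


TAX = make_taxonomy(
    {
        "c1": ("Parcubacteria", "UBA9983"),
        "c2": ("ABY1", "Magasanikbacteria"),
        "c3": ("Gracilibacteria", "Absconditabacterales"),
        "n1": ("Bacteroidia", "Chitinophagales"),
    }
)


class TestShannon:
    def test_two_equal_cpr_asvs_give_ln2(self):
        rel = rel_table([[0.2, 0.2, 0.0, 0.6]], ["c1", "c2", "c3", "n1"])
        h = shannon_cpr(rel, TAX)
        assert h.iloc[0] == pytest.approx(np.log(2))

    def test_single_cpr_asv_gives_zero(self):
        rel = rel_table([[0.4, 0.0, 0.0, 0.6]], ["c1", "c2", "c3", "n1"])
        assert shannon_cpr(rel, TAX).iloc[0] == pytest.approx(0.0)

    def test_uniform_over_n_gives_ln_n(self):
        rel = rel_table([[0.1, 0.1, 0.1, 0.7]], ["c1", "c2", "c3", "n1"])
        assert shannon_cpr(rel, TAX).iloc[0] == pytest.approx(np.log(3))

    def test_no_cpr_sample_omitted(self, caplog):
        rel = rel_table([[0.0, 0.0, 0.0, 1.0]], ["c1", "c2", "c3", "n1"])
        with caplog.at_level("WARNING"):
            h = shannon_cpr(rel, TAX)
        assert h.empty and "no CPR abundance" in caplog.text

    def test_matches_skbio_on_renormalized_subset(self):
        from skbio.diversity.alpha import shannon

        rel = rel_table([[0.15, 0.05, 0.3, 0.5]], ["c1", "c2", "c3", "n1"])
        p = np.array([0.15, 0.05, 0.3])
        expected = shannon(p / p.sum(), base=np.e)
        assert shannon_cpr(rel, TAX).iloc[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=3))
    def test_bounds(self, cpr_weights):
        """0 <= H <= ln(number of CPR ASVs present)."""
        cpr = cpr_weights + [0.0] * (3 - len(cpr_weights))
        w = np.array(cpr + [1.0])
        w /= w.sum()
        rel = rel_table([w], ["c1", "c2", "c3", "n1"])
        h = shannon_cpr(rel, TAX).iloc[0]
        assert -1e-12 <= h <= np.log(len(cpr_weights)) + 1e-12


def make_association_inputs(n_on=20, n_off=20, separated=True, seed=0):
    rng = np.random.default_rng(seed)
    records, rows, ids = [], [], []
    for i in range(n_on + n_off):
        on = i < n_on
        sid = f"S{i}"
        ids.append(sid)
        records.append(
            SampleRecord(
                sid, "E0", "Auto",
                frozenset({"thiosulfate"}) if on else frozenset(),
                "oxic", 7.0, "R1", "H41",
            )
        )
        if separated:
            c1 = rng.uniform(0.3, 0.6) if on else rng.uniform(0.0, 0.05)
        else:
            c1 = rng.uniform(0.0, 0.5)
        rows.append([c1, 1.0 - c1])
    rel = rel_table(rows, ["c1", "n1"], ids)
    return rel, records


class TestAssociations:
    def test_clean_separation_significant_positive(self):
        rel, records = make_association_inputs()
        out = supplement_association(rel, records, taxonomy=TAX)
        row = out[(out["asv_id"] == "c1") & (out["parameter"] == "thiosulfate")].iloc[0]
        assert row["significant"] and row["direction"] == "positive"

    def test_constant_parameter_skipped(self, caplog):
        rel, records = make_association_inputs()
        with caplog.at_level("INFO"):
            out = supplement_association(
                rel, records, taxonomy=TAX, parameters=["oxic"]
            )
        assert out.empty  # every sample oxic
        assert "constant" in caplog.text

    def test_negating_indicator_flips_direction_preserves_p(self):
        rel, records = make_association_inputs(separated=True)
        flipped = [
            SampleRecord(
                r.sample_id, r.experiment_id, r.treatment_group,
                frozenset() if "thiosulfate" in r.supplements else frozenset({"thiosulfate"}),
                r.oxygen_status, r.time_days, r.replicate_id, r.well_id,
            )
            for r in records
        ]
        a = supplement_association(rel, records, taxonomy=TAX, parameters=["thiosulfate"])
        b = supplement_association(rel, flipped, taxonomy=TAX, parameters=["thiosulfate"])
        ra = a[a["asv_id"] == "c1"].iloc[0]
        rb = b[b["asv_id"] == "c1"].iloc[0]
        assert ra["rho"] == pytest.approx(-rb["rho"])
        assert ra["p_value"] == pytest.approx(rb["p_value"])

    def test_exact_p_for_tiny_samples_is_valid_probability(self):
        rel, records = make_association_inputs(n_on=3, n_off=3)
        out = supplement_association(rel, records, taxonomy=TAX, parameters=["thiosulfate"])
        assert ((out["p_value"] > 0) & (out["p_value"] <= 1)).all()

    def test_ingest_differential_abundance_rules(self, tmp_path):
        df = pd.DataFrame(
            {
                "asv_id": ["c1", "c2"],
                "parameter": ["nitrate", "nitrate"],
                "log2_fold_change": [2.0, -1.0],
                "adjusted_p": [0.01, 0.2],
            }
        )
        out = ingest_differential_abundance(df)
        assert out["significant"].tolist() == [True, False]
        assert out["direction"].tolist() == ["positive", "negative"]
        with pytest.raises(FormatError):
            ingest_differential_abundance(df.drop(columns=["adjusted_p"]))

    def test_merge_keeps_both_branches(self):
        rel, records = make_association_inputs()
        spearman = supplement_association(rel, records, taxonomy=TAX)
        diff = ingest_differential_abundance(
            pd.DataFrame(
                {
                    "asv_id": ["c1"],
                    "parameter": ["nitrate"],
                    "log2_fold_change": [1.0],
                    "adjusted_p": [0.01],
                }
            )
        )
        merged = merge_association_reports(spearman, diff)
        assert set(merged["method"]) == {"spearman", "differential_abundance"}


class TestGroupDifference:
    def test_identical_groups_no_evidence(self):
        res = group_difference({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_complete_separation_maximal_statistic(self):
        res = group_difference({"a": [1, 2, 3], "b": [101, 102, 103]})
        # maximal H for group sizes (3, 3) with no ties
        n = 6
        mean_ranks = {"a": 2.0, "b": 5.0}
        h_max = 12 / (n * (n + 1)) * sum(
            3 * (m - (n + 1) / 2) ** 2 for m in mean_ranks.values()
        )
        assert res.statistic == pytest.approx(h_max)

    def test_small_group_excluded(self, caplog):
        with caplog.at_level("INFO"):
            res = group_difference({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7]})
        assert "c" not in res.groups

    def test_fewer_than_two_usable_groups_rejected(self):
        with pytest.raises(ValidationError):
            group_difference({"a": [1, 2, 3], "b": [1]})

    def test_dunn_z_matches_hand_computation(self):
        # two groups, no ties: z = (meanR_a - meanR_b) / sqrt(N(N+1)/12 * (1/n_a + 1/n_b))
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        out = dunn_posthoc(groups, correction="none")
        n = 6
        z_expected = (2.0 - 5.0) / np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        assert out.iloc[0]["z"] == pytest.approx(z_expected)

    def test_bonferroni_scales_p(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [3.0, 4.0, 5.0]}
        raw = dunn_posthoc(groups, correction="none")
        adj = dunn_posthoc(groups, correction="bonferroni")
        np.testing.assert_allclose(
            np.minimum(1.0, raw["p_adjusted"] * 3), adj["p_adjusted"]
        )

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        res = group_difference({"a": a, "b": b})
        assert res.p_value < 0.05
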