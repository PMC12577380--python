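"""Co-occurrence estimation and the CPR-focused edge rules."""

import numpy as np
import pandas as pd
import pytest

from cprkit.cooccurrence import (
    CoocNetwork,
    count_order_links,
    estimate_network,
    filter_cpr_edges,
    sparcc_correlations,
)
from cprkit.errors import ValidationError
from conftest import make_taxonomy


def counts_frame(columns: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"S{i}" for i in range(n)])


TAX = make_taxonomy(
    {
        "cpr1": ("Parcubacteria", "UBA9983"),
        "cpr2": ("Saccharimonadia", "Saccharimonadales"),
        "non1": ("Bacteroidia", "Chitinophagales"),
        "non2": ("Gammaproteobacteria", "Burkholderiales"),
    }
)


class TestEstimateNetwork:
    def test_identical_profiles_have_rank_weight_one(self):
        df = counts_frame(
            {"cpr1": [1, 5, 9, 20], "non1": [2, 10, 18, 40], "non2": [30, 8, 4, 2]}
        )
        net = estimate_network(df, prevalence_floor=0.0)
        w = net.edges.set_index(["asv_a", "asv_b"])["weight"]
        assert w[("cpr1", "non1")] == pytest.approx(1.0)

    def test_anti_ranked_profiles_have_weight_minus_one(self):
        df = counts_frame({"cpr1": [1, 5, 9, 20], "non2": [40, 22, 9, 3]})
        net = estimate_network(df, prevalence_floor=0.0)
        assert net.edges.iloc[0]["weight"] == pytest.approx(-1.0)

    def test_fewer_than_four_samples_rejected(self):
        df = counts_frame({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(ValidationError, match="4 samples"):
            estimate_network(df)

    def test_constant_asv_edges_omitted(self):
        # totals are constant, so cpr1's relative abundance is constant too
        df = counts_frame({"cpr1": [5, 5, 5, 5], "non1": [1, 2, 3, 4], "non2": [4, 3, 2, 1]})
        net = estimate_network(df, prevalence_floor=0.0)
        touching = net.edges[(net.edges["asv_a"] == "cpr1") | (net.edges["asv_b"] == "cpr1")]
        assert touching.empty

    def test_prevalence_floor_removes_rare_asvs(self):
        df = counts_frame(
            {"rare": [0, 0, 0, 1, 0], "a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]}
        )
        net = estimate_network(df, prevalence_floor=0.25)
        assert "rare" not in set(net.edges["asv_a"]) | set(net.edges["asv_b"])
        kept = estimate_network(df, prevalence_floor=0.2)  # 1/5 is not below 20%
        assert "rare" in set(kept.edges["asv_a"]) | set(kept.edges["asv_b"])

    def test_sparcc_deterministic(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(50, size=(30, 8))
        a = sparcc_correlations(arr)
        b = sparcc_correlations(arr)
        np.testing.assert_array_equal(a, b)
        assert np.abs(a).max() <= 1.0

    def test_sparcc_detects_strong_proportionality(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(3, 1, size=(80, 25))
        base[:, 1] = 2.0 * base[:, 0]  # proportional pair among background taxa
        counts = rng.poisson(base * 10)
        rho = sparcc_correlations(counts)
        assert rho[0, 1] > 0.5


class TestFilterEdges:
    def edges(self, rows):
        return CoocNetwork("Auto", pd.DataFrame(rows, columns=["asv_a", "asv_b", "weight"]))

    def test_rules_applied(self):
        net = self.edges(
            [
                ("cpr1", "non1", 0.25),  # kept
                ("cpr1", "non2", 0.1),  # dropped: not strictly above 0.1
                ("non1", "non2", 0.9),  # dropped: no CPR endpoint
                ("cpr2", "non2", -0.5),  # dropped: negative
            ]
        )
        out = filter_cpr_edges(net, TAX)
        assert out.edges[["asv_a", "asv_b"]].values.tolist() == [["cpr1", "non1"]]

    def test_soundness_on_random_networks(self):
        rng = np.random.default_rng(11)
        asvs = list(TAX.asv_ids)
        for _ in range(25):
            rows = []
            for i in range(len(asvs)):
                for j in range(i + 1, len(asvs)):
                    rows.append((asvs[i], asvs[j], float(rng.uniform(-1, 1))))
            out = filter_cpr_edges(self.edges(rows), TAX)
            for _, e in out.edges.iterrows():
                assert e["weight"] > 0.1
                assert TAX.is_cpr[e["asv_a"]] or TAX.is_cpr[e["asv_b"]]


class TestOrderLinks:
    def test_three_links_counted(self):
        tax = make_taxonomy(
            {
                **{f"c{i}": ("Saccharimonadia", "Saccharimonadales") for i in range(3)},
                **{f"n{i}": ("Bacteroidia", "Chitinophagales") for i in range(3)},
            }
        )
        net = CoocNetwork(
            "Defined",
            pd.DataFrame(
                [(f"c{i}", f"n{i}", 0.5) for i in range(3)],
                columns=["asv_a", "asv_b", "weight"],
            ),
        )
        out = count_order_links(net, tax)
        assert out.rows.values.tolist() == [["Saccharimonadales", "Chitinophagales", 3]]

    def test_order_with_two_links_dropped(self):
        tax = make_taxonomy(
            {
                **{f"c{i}": ("Saccharimonadia", "Saccharimonadales") for i in range(3)},
                **{f"n{i}": ("Bacteroidia", "Chitinophagales") for i in range(2)},
                "x0": ("Nitrospiria", "Nitrospirales"),
            }
        )
        rows = [("c0", "n0", 0.5), ("c1", "n1", 0.5), ("c2", "x0", 0.4)]
        net = CoocNetwork("Auto", pd.DataFrame(rows, columns=["asv_a", "asv_b", "weight"]))
        out = count_order_links(net, tax, min_links=3)
        assert out.rows.empty  # both non-CPR orders have < 3 links

    def test_top_n_cap_applied(self):
        tax = make_taxonomy(
            {
                **{f"c{i:03d}": ("Parcubacteria", "UBA9983") for i in range(250)},
                "n0": ("Bacteroidia", "Chitinophagales"),
            }
        )
        rows = [(f"c{i:03d}", "n0", 0.2 + i * 0.003) for i in range(250)]
        net = CoocNetwork("Auto", pd.DataFrame(rows, columns=["asv_a", "asv_b", "weight"]))
        out = count_order_links(net, tax, top_n=200, min_links=3)
        assert out.rows["n_links"].sum() == 200

    def test_cpr_cpr_edges_excluded(self):
        tax = make_taxonomy(
            {
                "c0": ("Parcubacteria", "UBA9983"),
                "c1": ("ABY1", "Magasanikbacteria"),
                **{f"n{i}": ("Bacteroidia", "Chitinophagales") for i in range(3)},
            }
        )
        rows = [("c0", "c1", 0.9)] + [("c0", f"n{i}", 0.5) for i in range(3)]
        net = CoocNetwork("Auto", pd.DataFrame(rows, columns=["asv_a", "asv_b", "weight"]))
        out = count_order_links(net, tax)
        assert out.rows["n_links"].sum() == 3


def test_planted_pair_detected_in_network(small_config):
    """A CPR ASV proportional to a non-CPR partner yields a strong edge."""
    import dataclasses
    from cprkit.synthetic import simulate_experiment

    cfg = dataclasses.replace(small_config, planted_pairs=1, n_experiments=2)
    counts, records, _, tax, truth = simulate_experiment(cfg)
    net = estimate_network(counts.data, method="rank")
    filtered = filter_cpr_edges(net, tax)
    pairs = set(map(tuple, filtered.edges[["asv_a", "asv_b"]].values))
    a, b = sorted(truth.planted_pairs[0])
    assert (a, b) in pairs
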