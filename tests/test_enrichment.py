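"""Hypergeometric overrepresentation vs an exhaustive-enumeration oracle,
EASE jackknife, annotation-cluster scores, and the upstream z statistic."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from arraycascade import (
    GeneSet,
    GeneSetCollection,
    annotation_clusters,
    cluster_score,
    ease_p,
    fisher_enrich,
    upstream_z,
)
from arraycascade.enrichment import hypergeom_tail
from arraycascade.errors import DataError
from arraycascade.io import RegulatorNetwork


def hypergeom_oracle(hits, universe, set_size, query):
    """P(X >= hits) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(hits, min(set_size, query) + 1):
        total += comb(set_size, k) * comb(universe - set_size, query - k)
    return total / comb(universe, query)


def _collection(**sets):
    return GeneSetCollection(
        {name: GeneSet("cat", tuple(members)) for name, members in sets.items()}
    )


class TestHypergeomTail:
    def test_matches_enumeration_for_small_universes(self):
        for universe in range(2, 13):
            for set_size in range(1, universe + 1):
                for query in range(1, universe + 1):
                    for hits in range(0, min(set_size, query) + 1):
                        expected = hypergeom_oracle(hits, universe, set_size, query)
                        got = hypergeom_tail(hits, universe, set_size, query)
                        assert got == pytest.approx(expected, rel=1e-9), (
                            universe, set_size, query, hits
                        )

    @given(st.integers(0, 2**31 - 1))
    def test_matches_enumeration_sampled_up_to_25(self, seed):
        rng = np.random.default_rng(seed)
        universe = int(rng.integers(13, 26))
        set_size = int(rng.integers(1, universe + 1))
        query = int(rng.integers(1, universe + 1))
        hits = int(rng.integers(0, min(set_size, query) + 1))
        assert hypergeom_tail(hits, universe, set_size, query) == pytest.approx(
            hypergeom_oracle(hits, universe, set_size, query), rel=1e-9
        )

    def test_frozen_fraction_20_5_5_4(self):
        # enumeration: (C(5,4)C(15,1) + C(5,5)C(15,0)) / C(20,5) = 76/15504
        assert hypergeom_tail(4, 20, 5, 5) == pytest.approx(76 / 15504, rel=1e-12)


class TestFisherEnrich:
    def test_query_equals_universe_forces_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        table = fisher_enrich(uni, _collection(S1=uni[:4]), uni)
        assert table.loc["S1", "p_fisher"] == pytest.approx(1.0)

    def test_disjoint_set_p_one(self):
        uni = [f"g{i}" for i in range(20)]
        table = fisher_enrich(uni[:5], _collection(S1=uni[10:15]), uni)
        assert table.loc["S1", "p_fisher"] == pytest.approx(1.0)
        assert table.loc["S1", "n_hits"] == 0

    def test_enriched_overlap_matches_oracle(self):
        uni = [f"g{i}" for i in range(20)]
        query = uni[:5]
        table = fisher_enrich(query, _collection(S1=uni[1:5] + [uni[10]]), uni)
        assert table.loc["S1", "n_hits"] == 4
        assert table.loc["S1", "p_fisher"] == pytest.approx(76 / 15504, rel=1e-9)
        # EASE: one hit jackknifed -> tail at 3 hits = 1126/15504
        assert table.loc["S1", "p_ease"] == pytest.approx(1126 / 15504, rel=1e-9)

    def test_symbols_case_normalized(self):
        table = fisher_enrich(["tp53"], _collection(S1=["TP53", "MYC"]),
                              ["TP53", "myc", "EGFR"])
        assert table.loc["S1", "n_hits"] == 1

    def test_query_outside_universe_rejected(self):
        with pytest.raises(DataError, match="outside"):
            fisher_enrich(["x"], _collection(S1=["a"]), ["a", "b"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            fisher_enrich([], _collection(S1=["a"]), ["a"])
        with pytest.raises(DataError):
            fisher_enrich(["a"], _collection(S1=["a"]), [])


class TestEase:
    @pytest.mark.parametrize("hits,expected", [(0, 1.0), (1, 1.0)])
    def test_degenerate_hits_give_one(self, hits, expected):
        assert ease_p(hits, 5, 5, 20) == expected

    @given(st.integers(0, 2**31 - 1))
    def test_ease_never_below_fisher(self, seed):
        rng = np.random.default_rng(seed)
        universe = int(rng.integers(2, 40))
        set_size = int(rng.integers(1, universe + 1))
        query = int(rng.integers(1, universe + 1))
        hits = int(rng.integers(0, min(set_size, query) + 1))
        assert ease_p(hits, set_size, query, universe) >= hypergeom_tail(
            hits, universe, set_size, query
        ) - 1e-12


class TestClusterScore:
    def test_two_member_score(self):
        assert cluster_score([0.01, 0.001]) == pytest.approx(2.5)

    def test_singleton_score(self):
        assert cluster_score([0.1]) == pytest.approx(1.0)

    def test_all_ones_score_zero(self):
        assert cluster_score([1.0, 1.0]) == pytest.approx(0.0)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(DataError):
            cluster_score([0.0, 0.1])

    def test_greedy_clusters_group_overlapping_sets(self):
        uni = [f"g{i}" for i in range(30)]
        query = uni[:6]
        coll = _collection(
            A=uni[:5],           # hits g0..g4
            B=uni[:4] + [uni[20]],  # hits g0..g3 (jaccard 4/5 with A)
            C=uni[10:15] + [uni[5]],  # hits g5 only (disjoint from A)
        )
        table = fisher_enrich(query, coll, uni)
        clusters = annotation_clusters(table, coll, query, jaccard_min=0.5)
        grouped = {frozenset(c.members) for c in clusters}
        assert frozenset({"A", "B"}) in grouped
        assert frozenset({"C"}) in grouped
        for c in clusters:
            expected = np.mean([-np.log10(table.loc[s, "p_ease"])
                                for s in c.members])
            assert c.score == pytest.approx(expected)


class TestUpstreamZ:
    def _de(self, signs):
        return pd.DataFrame(
            {
                "symbol": [f"T{i}" for i in range(len(signs))],
                "delta": list(signs),
                "fc": [2.0 * s for s in signs],
                "level": ["L1"] * len(signs),
            },
            index=pd.Index([f"p{i}" for i in range(len(signs))], name="probe_id"),
        )

    def test_four_concordant_targets_activated(self):
        net = RegulatorNetwork([("R", f"T{i}", 1) for i in range(4)])
        calls = upstream_z(self._de([1, 1, 1, 1]), net)
        assert calls.loc["R", "z"] == pytest.approx(2.0)
        assert calls.loc["R", "call"] == "activated"

    def test_balanced_targets_no_call(self):
        net = RegulatorNetwork([("R", f"T{i}", 1) for i in range(4)])
        calls = upstream_z(self._de([1, 1, -1, -1]), net)
        assert calls.loc["R", "z"] == pytest.approx(0.0)
        assert calls.loc["R", "call"] == "none"

    def test_nine_discordant_targets_inhibited(self):
        net = RegulatorNetwork([("R", f"T{i}", 1) for i in range(9)])
        calls = upstream_z(self._de([-1] * 9), net)
        assert calls.loc["R", "z"] == pytest.approx(-3.0)
        assert calls.loc["R", "call"] == "inhibited"

    def test_repressive_edges_invert_observed_sign(self):
        net = RegulatorNetwork([("R", f"T{i}", -1) for i in range(4)])
        calls = upstream_z(self._de([-1, -1, -1, -1]), net)
        assert calls.loc["R", "call"] == "activated"

    def test_antisymmetric_under_sign_flip(self):
        rng = np.random.default_rng(0)
        signs = rng.choice([-1, 1], 12)
        net = RegulatorNetwork(
            [("R", f"T{i}", int(s)) for i, s in enumerate(rng.choice([-1, 1], 12))]
        )
        z1 = upstream_z(self._de(signs), net).loc["R", "z"]
        z2 = upstream_z(self._de(-signs), net).loc["R", "z"]
        assert z1 == pytest.approx(-z2)

    def test_too_few_targets_omitted(self):
        net = RegulatorNetwork([("R", "T0", 1), ("R", "T1", 1)])
        calls = upstream_z(self._de([1, 1]), net, min_targets=3)
        assert "R" not in calls.index

    def test_only_selected_level_contributes(self):
        de = self._de([1, 1, 1, 1])
        de.loc["p3", "level"] = "L3"
        net = RegulatorNetwork([("R", f"T{i}", 1) for i in range(4)])
        calls = upstream_z(de, net)
        assert calls.loc["R", "n_targets_used"] == 3
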