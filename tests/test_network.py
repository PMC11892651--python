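import io as _io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdkit import (
    DegreeClassifier,
    build_network,
    build_reference_cloud,
    classify_degree,
    classify_edges_by_region,
    export_edgelist,
    pair_filter_trans,
    pair_summaries,
)
from ibdkit.network import ConfigurationError, export_components, read_edgelist


class TestPairFilterTrans:
    @pytest.mark.parametrize(
        "tracts,expected",
        [
            ([9, 9, 10], True),   # three medium tracts
            ([13], True),         # one long tract
            ([9, 9], False),
            ([], False),
        ],
    )
    def test_disjunctive_reading(self, tracts, expected):
        summary = {
            "n_8_12": sum(1 for t in tracts if 8 <= t < 12),
            "n_ge12": sum(1 for t in tracts if t >= 12),
        }
        assert pair_filter_trans(summary) is expected

    def test_conjunctive_flag(self):
        both = {"n_8_12": 3, "n_ge12": 1}
        medium_only = {"n_8_12": 3, "n_ge12": 0}
        assert pair_filter_trans(both, conjunctive=True)
        assert not pair_filter_trans(medium_only, conjunctive=True)


@pytest.fixture()
def toy_summaries(toy_segments):
    return pair_summaries(toy_segments)


class TestBuildNetwork:
    def test_trans_filter_components(self, toy_summaries, toy_meta):
        g = build_network(toy_summaries, toy_meta, edge_rule="trans_filter")
        assert g.components[0] == frozenset({"A", "B", "C"})
        assert g.component_sizes == [3]
        assert "D" not in g.graph  # isolated individuals excluded

    def test_min_tract_20_single_edge(self, toy_summaries, toy_meta):
        g = build_network(toy_summaries, toy_meta, edge_rule="min_tract_20")
        assert g.n_edges == 1
        assert g.component_sizes == [2]
        assert set(g.graph.edges) == {("A", "B")}

    def test_min_tract_8_includes_all(self, toy_summaries):
        g = build_network(toy_summaries, edge_rule="min_tract_8")
        assert g.n_edges == 3
        assert g.component_sizes == [4]

    def test_empty_input_empty_graph(self, toy_summaries):
        g = build_network(toy_summaries.iloc[:0], edge_rule="trans_filter")
        assert g.n_nodes == 0 and g.n_edges == 0
        assert g.component_sizes == []

    def test_unknown_rule_rejected(self, toy_summaries):
        with pytest.raises(ConfigurationError, match="edge rule"):
            build_network(toy_summaries, edge_rule="bogus")

    def test_components_invariant_to_row_order(self, toy_summaries, toy_meta):
        shuffled = toy_summaries.sample(frac=1.0, random_state=4)
        a = build_network(toy_summaries, toy_meta)
        b = build_network(shuffled, toy_meta)
        assert a.components == b.components

    def test_components_stable_under_relabeling(self, toy_summaries, toy_meta):
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        relabeled = toy_summaries.assign(
            iid1=toy_summaries["iid1"].map(mapping),
            iid2=toy_summaries["iid2"].map(mapping),
        )
        meta = toy_meta.assign(iid=toy_meta["iid"].map(mapping))
        a = build_network(toy_summaries, toy_meta)
        b = build_network(relabeled, meta)
        assert [
            frozenset(mapping[x] for x in comp) for comp in a.components
        ] == b.components


summaries_strategy = st.lists(
    st.tuples(
        st.integers(0, 9), st.integers(0, 9),
        st.integers(0, 5), st.integers(0, 3),
    ).filter(lambda t: t[0] != t[1]),
    max_size=25,
)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(rows=summaries_strategy)
def test_stricter_rule_never_grows_network(rows):
    """Raising the tract threshold 8 -> 20 cM cannot add edges, nodes, or
    grow any component."""
    columns = ["iid1", "iid2", "sum_cM", "n_segments", "max_cM",
               "n_8_12", "n_ge12", "n_ge20"]
    frame = pd.DataFrame(
        [
            (
                f"I{min(a, b)}",
                f"I{max(a, b)}",
                9.0 * n_med + 21.0 * n_long,
                n_med + n_long,
                21.0 if n_long else (9.0 if n_med else 0.0),
                n_med,
                n_long,
                n_long,
            )
            for a, b, n_med, n_long in rows
        ],
        columns=columns,
    ).drop_duplicates(subset=["iid1", "iid2"])
    frame = frame.loc[frame["n_segments"] > 0]
    loose = build_network(frame, edge_rule="min_tract_8")
    strict = build_network(frame, edge_rule="min_tract_20")
    assert strict.n_edges <= loose.n_edges
    assert strict.n_nodes <= loose.n_nodes
    for comp in strict.components:
        # every strict component is contained in some loose component
        assert any(comp <= big for big in loose.components)


class TestRegionTallies:
    def test_toy_tally(self, toy_summaries, toy_meta):
        g = build_network(toy_summaries, toy_meta, edge_rule="trans_filter")
        tally = classify_edges_by_region(g)
        assert tally == {
            ("C.Basin", "C.Basin"): 1,
            ("C.Basin", "E.E.Steppe"): 1,
        }

    def test_tally_sums_to_edge_count(self, toy_summaries, toy_meta):
        g = build_network(toy_summaries, toy_meta, edge_rule="min_tract_8")
        tally = classify_edges_by_region(g)
        assert sum(tally.values()) == g.n_edges

    def test_empty_graph_empty_tally(self, toy_summaries, toy_meta):
        g = build_network(toy_summaries.iloc[:0], toy_meta)
        assert classify_edges_by_region(g) == {}

    def test_missing_region_names_node(self, toy_summaries):
        g = build_network(toy_summaries, meta=None, edge_rule="trans_filter")
        with pytest.raises(ConfigurationError, match="A"):
            classify_edges_by_region(g)


class TestDegreeClassifier:
    def test_parent_child_signature(self, reference_cloud, gmap):
        clf = DegreeClassifier(reference_cloud)
        call = clf.classify(gmap.total_cM, 22)
        assert not call.unrelated
        assert call.degree_lo <= 1 <= call.degree_hi

    def test_zero_sharing_is_unrelated(self, reference_cloud):
        call = DegreeClassifier(reference_cloud).classify(0.0, 0)
        assert call.unrelated
        assert call.degree_range == "unrelated"

    def test_missing_degree_is_configuration_error(self, reference_cloud):
        partial = reference_cloud.loc[reference_cloud["degree"] != 4]
        with pytest.raises(ConfigurationError, match="4"):
            DegreeClassifier(partial)

    @pytest.mark.parametrize("degree", [1, 2, 3, 4, 5])
    def test_self_consistency_close_degrees(self, reference_cloud, gmap, degree):
        """Simulated pairs of a known degree receive ranges covering that
        degree in at least 80% of replicates (degrees 1-5)."""
        clf = DegreeClassifier(reference_cloud)
        test = build_reference_cloud(
            degrees=[degree], n_per_degree=100, gmap=gmap,
            min_len_cM=8.0, seed=500 + degree,
        )
        hits = 0
        for row in test.itertuples():
            call = clf.classify(row.sum_cM, row.n_segments)
            if not call.unrelated and call.degree_lo <= degree <= call.degree_hi:
                hits += 1
        assert hits >= 0.8 * len(test)

    def test_degree_five_range_width_reported(self, reference_cloud, gmap):
        # interval-style call, e.g. "5th- to 7th-degree"
        test = build_reference_cloud(
            degrees=[5], n_per_degree=20, gmap=gmap, min_len_cM=8.0, seed=77
        )
        clf = DegreeClassifier(reference_cloud)
        calls = [clf.classify(r.sum_cM, r.n_segments) for r in test.itertuples()]
        related = [c for c in calls if not c.unrelated]
        assert related, "degree-5 pairs should mostly be classifiable"
        assert all(c.degree_lo <= c.degree_hi for c in related)

    def test_convenience_wrapper(self, reference_cloud):
        call = classify_degree(
            {"sum_cM": 1700.0, "n_segments": 60, "iid1": "A", "iid2": "B"},
            reference_cloud,
        )
        assert call.iid1 == "A" and not call.unrelated


class TestExportEdgelist:
    def test_toy_export_rows_and_roundtrip(self, toy_summaries, toy_meta, tmp_path):
        g = build_network(toy_summaries, toy_meta, edge_rule="trans_filter")
        path = tmp_path / "edges.tsv"
        frame = export_edgelist(g, path)
        assert len(frame) == 2
        back = read_edgelist(path)
        assert set(zip(back["iid1"], back["iid2"])) == set(
            zip(frame["iid1"], frame["iid2"])
        )
        assert "region_pair" in back.columns

    def test_empty_graph_header_only(self, toy_summaries, tmp_path):
        g = build_network(toy_summaries.iloc[:0])
        path = tmp_path / "edges.tsv"
        export_edgelist(g, path)
        assert path.read_text().strip() == "\t".join(
            ["iid1", "iid2", "sum_cM", "max_cM", "n_segments", "region_pair"]
        )

    def test_component_export(self, toy_summaries, toy_meta, tmp_path):
        g = build_network(toy_summaries, toy_meta, edge_rule="min_tract_8")
        frame = export_components(g, tmp_path / "comp.tsv")
        assert set(frame["iid"]) == {"A", "B", "C", "D"}
        assert (frame["component_size"] == 4).all()
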