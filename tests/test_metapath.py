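"""Meta-path enumeration, attribute propagation and pair scoring."""

import pytest

import hetlink.metapath as mpx
from hetlink.hetnet import AttributeSpec, HeterogeneousNetwork, NetworkSchema
from hetlink.metapath import (
    AttributeStats,
    attribute_similarity,
    enrich_attributes,
    enumerate_metapaths,
    materialize_sequences,
    pathscore,
    score_all_pairs,
    sequence_similarity,
)
from hetlink.synth import toy_sequence_fixture

from conftest import random_network
from oracle import brute_force_scores


class TestEnumeration:
    def test_two_metapaths_on_minimal_schema(self, toy_net):
        mps = enumerate_metapaths(toy_net, max_len=2)
        assert [m.node_types for m in mps] == [
            ("ncRNA", "disease"),
            ("ncRNA", "gene", "disease"),
        ]

    def test_three_metapaths_with_gene_protein_and_direct_routes(self):
        schema = NetworkSchema(
            node_types={t: [] for t in ("ncRNA", "disease", "gene", "protein")},
            target_types=("ncRNA", "disease"),
            edge_types={
                "ncRNA-disease": ("ncRNA", "disease"),
                "ncRNA-gene": ("ncRNA", "gene"),
                "gene-disease": ("gene", "disease"),
                "ncRNA-protein": ("ncRNA", "protein"),
                "protein-disease": ("protein", "disease"),
            },
        )
        net = HeterogeneousNetwork(schema=schema, nodes={}, edges={})
        mps = enumerate_metapaths(net, max_len=2)
        assert len(mps) == 3
        assert {m.node_types for m in mps} == {
            ("ncRNA", "disease"),
            ("ncRNA", "gene", "disease"),
            ("ncRNA", "protein", "disease"),
        }

    def test_no_direct_type_and_max_len_one_yields_nothing(self):
        net = random_network(seed=0, with_direct=False)
        with pytest.warns(UserWarning, match="no meta-path"):
            assert enumerate_metapaths(net, max_len=1) == []

    def test_type_cycles_are_forbidden(self, toy_net):
        for mp in enumerate_metapaths(toy_net, max_len=5):
            assert len(set(mp.node_types)) == len(mp.node_types)


@pytest.fixture
def protein_net():
    """Gene g1 carries two off-path proteins with numeric and categorical
    attributes; proteins sit on no meta-path."""
    schema = NetworkSchema(
        node_types={
            "ncRNA": [],
            "disease": [],
            "gene": [],
            "protein": [
                AttributeSpec("score", "numeric"),
                AttributeSpec("loc", "categorical"),
            ],
        },
        target_types=("ncRNA", "disease"),
        edge_types={
            "ncRNA-gene": ("ncRNA", "gene"),
            "gene-disease": ("gene", "disease"),
            "gene-protein": ("gene", "protein"),
            "protein-protein": ("protein", "protein"),
        },
    )
    nodes = {
        "ncRNA": {"n1": {}},
        "disease": {"d1": {}},
        "gene": {"g1": {}, "g2": {}},
        "protein": {
            "p1": {"score": 2.0, "loc": "nucleus"},
            "p2": {"score": 4.0, "loc": "nucleus"},
            "p3": {"score": 9.0, "loc": "cytosol"},
        },
    }
    edges = {
        "ncRNA-gene": {("n1", "g1")},
        "gene-disease": {("g1", "d1")},
        "gene-protein": {("g1", "p1"), ("g1", "p2")},
        "protein-protein": {("p2", "p3")},
    }
    return HeterogeneousNetwork(schema=schema, nodes=nodes, edges=edges)


class TestEnrichment:
    def test_depth_zero_is_identity(self, protein_net):
        mps = enumerate_metapaths(protein_net, max_len=2)
        assert enrich_attributes(protein_net, mps, depth=0) is protein_net

    def test_mean_of_off_path_numeric_neighbors(self, protein_net):
        mps = enumerate_metapaths(protein_net, max_len=2)
        out = enrich_attributes(protein_net, mps, depth=1)
        assert out.nodes["gene"]["g1"]["protein.score@d1"] == pytest.approx(3.0)
        # g2 has no protein neighbors: missing, not zero
        assert out.nodes["gene"]["g2"]["protein.score@d1"] is None

    def test_mode_with_tie_takes_lexicographically_smallest(self, protein_net):
        mps = enumerate_metapaths(protein_net, max_len=2)
        # depth 2 reaches p3 through p2: labels {nucleus, nucleus, cytosol}
        out = enrich_attributes(protein_net, mps, depth=2)
        assert out.nodes["gene"]["g1"]["protein.loc@d2"] == "nucleus"
        assert out.nodes["gene"]["g1"]["protein.score@d2"] == pytest.approx(5.0)
        # force a tie: {nucleus, cytosol} at depth 1 on a two-protein split
        protein_net.nodes["protein"]["p2"]["loc"] = "cytosol"
        out = enrich_attributes(protein_net, mps, depth=1)
        assert out.nodes["gene"]["g1"]["protein.loc@d1"] == "cytosol"

    def test_original_attributes_untouched(self, protein_net):
        mps = enumerate_metapaths(protein_net, max_len=2)
        out = enrich_attributes(protein_net, mps, depth=1)
        assert out.nodes["protein"] == protein_net.nodes["protein"]


class TestAttributeSimilarity:
    def test_numeric_range_normalised(self):
        assert attribute_similarity("numeric", 2.0, 4.0, (0.0, 10.0)) == pytest.approx(0.8)

    @pytest.mark.parametrize(
        "v1,v2,expected", [("mirna", "mirna", 1.0), ("mirna", "lncrna", 0.0)]
    )
    def test_categorical_identity(self, v1, v2, expected):
        assert attribute_similarity("categorical", v1, v2) == expected

    def test_constant_numeric_attribute_is_maximally_similar(self):
        assert attribute_similarity("numeric", 5.0, 5.0, (5.0, 5.0)) == 1.0

    def test_missing_value_returns_sentinel(self):
        assert attribute_similarity("numeric", None, 1.0, (0.0, 1.0)) is None


class TestSequenceSimilarity:
    def setup_method(self):
        self.net = toy_sequence_fixture()
        self.mps = enumerate_metapaths(self.net, max_len=2)
        self.mp = self.mps[1]  # ncRNA-gene-disease
        self.stats = AttributeStats.from_network(self.net)

    def test_identical_sequences_score_one(self):
        seq = ("h19", "g1", "d2")
        assert sequence_similarity(self.net, self.mp, seq, seq, self.stats) == 1.0

    def test_hand_computed_mean_of_attribute_similarities(self):
        # three attribute pairs with similarities 1, 0.8 and 0 average to 0.6
        schema = NetworkSchema(
            node_types={
                "ncRNA": [
                    AttributeSpec("a", "numeric"),
                    AttributeSpec("b", "numeric"),
                    AttributeSpec("c", "categorical"),
                ],
                "disease": [],
            },
            target_types=("ncRNA", "disease"),
            edge_types={"ncRNA-disease": ("ncRNA", "disease")},
        )
        net = HeterogeneousNetwork(
            schema=schema,
            nodes={
                "ncRNA": {
                    "x": {"a": 1.0, "b": 2.0, "c": "u"},
                    "y": {"a": 1.0, "b": 4.0, "c": "v"},
                },
                "disease": {"d": {}},
            },
            edges={"ncRNA-disease": {("x", "d"), ("y", "d")}},
        )
        mp = enumerate_metapaths(net, max_len=1)[0]
        stats = AttributeStats.from_network(net)  # b ranges over [2, 4]
        sim = sequence_similarity(net, mp, ("x", "d"), ("y", "d"), stats)
        # a -> 1 (constant attribute), b -> 1 - 2/2 = 0, c -> 0; mean = 1/3
        assert sim == pytest.approx(1.0 / 3)

    def test_no_declared_attributes_warns_and_scores_zero(self):
        schema = NetworkSchema(
            node_types={"ncRNA": [], "disease": []},
            target_types=("ncRNA", "disease"),
            edge_types={"ncRNA-disease": ("ncRNA", "disease")},
        )
        net = HeterogeneousNetwork(
            schema=schema,
            nodes={"ncRNA": {"x": {}}, "disease": {"d": {}}},
            edges={"ncRNA-disease": {("x", "d")}},
        )
        mp = enumerate_metapaths(net, max_len=1)[0]
        with pytest.warns(UserWarning, match="no comparable attributes"):
            assert sequence_similarity(net, mp, ("x", "d"), ("x", "d"), AttributeStats({})) == 0.0

    def test_symmetry(self):
        store = materialize_sequences(self.net, self.mp)
        seqs = [s for bucket in store.by_start.values() for s in bucket]
        for s1 in seqs[:5]:
            for s2 in seqs[:5]:
                assert sequence_similarity(
                    self.net, self.mp, s1, s2, self.stats
                ) == pytest.approx(
                    sequence_similarity(self.net, self.mp, s2, s1, self.stats)
                )


class TestPathscore:
    def test_direct_edge_scores_one(self, toy_net):
        mp = enumerate_metapaths(toy_net, max_len=1)[0]
        store = materialize_sequences(toy_net, mp)
        stats = AttributeStats.from_network(toy_net)
        assert pathscore(toy_net, mp, "n1", "d2", store, stats) == 1.0

    def test_two_by_four_sequence_sets_compared_exhaustively(self, monkeypatch):
        """The disconnected ncRNA/disease pair is scored as a max over
        exactly |starts| x |ends| = 2 x 4 sequence comparisons."""
        net = toy_sequence_fixture()
        mp = enumerate_metapaths(net, max_len=2)[1]
        store = materialize_sequences(net, mp)
        assert len(store.by_start["h19"]) == 2
        assert len(store.by_end["asthma"]) == 4
        calls = []
        real = mpx.sequence_similarity

        def counting(*args, **kw):
            calls.append(args)
            return real(*args, **kw)

        monkeypatch.setattr(mpx, "sequence_similarity", counting)
        stats = AttributeStats.from_network(net)
        s = pathscore(net, mp, "h19", "asthma", store, stats)
        assert len(calls) == 8
        assert 0.0 <= s <= 1.0

    def test_untouched_endpoint_scores_zero(self):
        net = toy_sequence_fixture()
        mp = enumerate_metapaths(net, max_len=2)[1]
        # remove every path out of h19
        net.edges["ncRNA-gene"] -= {("h19", "g1"), ("h19", "g2")}
        net._invalidate()
        store = materialize_sequences(net, mp)
        stats = AttributeStats.from_network(net)
        assert pathscore(net, mp, "h19", "asthma", store, stats) == 0.0


class TestScoreAllPairs:
    def test_direct_pairs_score_exactly_one(self, toy_net):
        scores = score_all_pairs(toy_net)
        assert scores.get(("n1", "d2")) == 1.0

    def test_fuzzy_or_takes_the_best_metapath(self):
        net = toy_sequence_fixture()
        full = score_all_pairs(net, max_len=2)
        mp_list = enumerate_metapaths(net, max_len=2)
        stats = AttributeStats.from_network(net)
        per_mp = []
        for mp in mp_list:
            store = materialize_sequences(net, mp)
            per_mp.append(pathscore(net, mp, "h19", "asthma", store, stats))
        assert full.get(("h19", "asthma")) == pytest.approx(max(per_mp))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        net = random_network(seed=seed)
        ours = score_all_pairs(net, max_len=3, seq_cap=10_000).scores
        ref = brute_force_scores(net, max_len=3)
        assert set(ours) == set(ref)
        for pair in ref:
            assert ours[pair] == pytest.approx(ref[pair], abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_scores_bounded_and_direct_rule(self, seed):
        net = random_network(seed=100 + seed)
        scores = score_all_pairs(net)
        assert all(0.0 <= s <= 1.0 for s in scores.scores.values())
        for pair in net.known_target_pairs():
            assert scores.get(pair) == 1.0

    def test_longer_metapath_bound_never_decreases_scores(self):
        """Max-composition monotonicity: adding meta-paths can only raise s."""
        net = random_network(seed=42)
        short = score_all_pairs(net, max_len=1).scores
        longer = score_all_pairs(net, max_len=3).scores
        for pair, s in short.items():
            assert longer.get(pair, 0.0) >= s - 1e-12

    def test_output_frame_is_deterministically_ordered(self, toy_net):
        frame = score_all_pairs(toy_net).to_frame()
        assert list(frame.columns) == ["ncrna_id", "disease_id", "score", "best_metapath"]
        assert frame[["ncrna_id", "disease_id"]].apply(tuple, axis=1).is_monotonic_increasing
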