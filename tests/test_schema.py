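"""Schema graph combinatorics and story instantiation."""

import numpy as np
import pytest
from scipy import stats

from schemabind import schema as sw


@pytest.fixture(scope="module")
def graph():
    return sw.build_coffee_shop_graph()


def brute_force_paths(edges, start, terminal):
    """Independent oracle: iterative breadth-first path enumeration."""
    complete, frontier = [], [(start,)]
    while frontier:
        nxt = []
        for path in frontier:
            if path[-1] == terminal:
                complete.append(path)
                continue
            for succ in edges.get(path[-1], ()):
                nxt.append(path + (succ,))
        frontier = nxt
    return complete


class TestCoffeeShopGraph:
    def test_has_24_paths(self, graph):
        assert len(sw.enumerate_paths(graph)) == 24

    def test_paths_match_brute_force_oracle(self, graph):
        expected = brute_force_paths(graph.edges, graph.start, graph.terminal)
        assert sorted(sw.enumerate_paths(graph)) == sorted(expected)

    def test_every_path_hits_mandatory_states(self, graph):
        for path in sw.enumerate_paths(graph):
            assert {"BEGIN", "SIT", "POETRY", "END"} <= set(path)

    def test_graph_is_acyclic(self, graph):
        assert not graph._has_cycle()

    def test_112_query_frames(self, graph):
        assert len(sw.enumerate_query_frames(graph)) == 112

    def test_per_role_frame_counts(self, graph):
        """Subject/Friend/Poet on every path; Emcee, Drink, Dessert on branches."""
        frames = sw.enumerate_query_frames(graph)
        counts = {}
        for f in frames:
            counts[f.query_role] = counts.get(f.query_role, 0) + 1
        assert counts == {"Subject": 24, "Friend": 24, "Poet": 24,
                          "Emcee": 12, "Drink": 16, "Dessert": 12}

    def test_frames_query_roles_present_on_path(self, graph):
        for f in sw.enumerate_query_frames(graph):
            assert f.query_role in sw.path_roles(graph, f.path)

    def test_emcee_frames_are_paths_through_intro(self, graph):
        frames = [f for f in sw.enumerate_query_frames(graph)
                  if f.query_role == "Emcee"]
        assert len(frames) == 12
        assert all("INTRO" in f.path for f in frames)


class TestEnumerationOnToyGraphs:
    def make(self, states, edges, start, terminal):
        return sw.SchemaGraph(
            states={n: sw.SchemaState(n.lower()) for n in states},
            edges=edges, start=start, terminal=terminal)

    def test_linear_chain_single_path(self):
        g = self.make("ABC", {"A": ("B",), "B": ("C",)}, "A", "C")
        assert sw.enumerate_paths(g) == [("A", "B", "C")]

    def test_diamond_two_paths(self):
        g = self.make("ABCD", {"A": ("B", "C"), "B": ("D",), "C": ("D",)}, "A", "D")
        assert len(sw.enumerate_paths(g)) == 2

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            self.make("AB", {"A": ("B",), "B": ("A",)}, "A", "B")

    def test_single_role_chain_one_frame(self):
        g = sw.SchemaGraph(
            states={"A": sw.SchemaState("a", ("Poet",)), "B": sw.SchemaState("b")},
            edges={"A": ("B",)}, start="A", terminal="B")
        frames = sw.enumerate_query_frames(g)
        assert len(frames) == 1 and frames[0].query_role == "Poet"


class TestSamplePath:
    def test_chain_always_unique_path(self):
        g = sw.SchemaGraph(
            states={n: sw.SchemaState(n.lower()) for n in "AB"},
            edges={"A": ("B",)}, start="A", terminal="B")
        rng = np.random.default_rng(0)
        assert all(sw.sample_path(g, rng) == ("A", "B") for _ in range(5))

    def test_begin_to_sit_frequency(self, graph):
        """BEGIN has out-degree 2, so half of all samples go straight to SIT."""
        rng = np.random.default_rng(42)
        n = 10_000
        direct = sum(sw.sample_path(g := graph, rng)[1] == "SIT" for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(direct - n / 2) < 3 * sigma

    def test_path_frequencies_match_analytic_products(self, graph):
        """Chi-squared goodness of fit against products of 1/out-degree."""
        rng = np.random.default_rng(7)
        paths = sw.enumerate_paths(graph)
        index = {p: i for i, p in enumerate(paths)}
        n = 12_000
        observed = np.zeros(len(paths))
        for _ in range(n):
            observed[index[sw.sample_path(graph, rng)]] += 1
        expected = n * np.array([sw.path_probability(graph, p) for p in paths])
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.01


class TestInstantiateStory:
    FRAME = sw.StoryFrame(("BEGIN", "SIT", "POETRY", "PERFORM", "GOODBYE", "END"),
                          "Poet")
    FILLERS = {"Subject": "alice", "Friend": "bob", "Poet": "chris"}

    def test_reference_story_body(self, graph):
        """The canonical example: keywords and fillers in slot order."""
        body = sw.story_body(graph, self.FRAME.path, self.FILLERS)
        assert body == ("begin alice sit alice bob poet_performs chris "
                        "subject_performs alice bob say_goodbye alice bob "
                        "end alice").split()

    def test_instance_layout(self, graph):
        rng = np.random.default_rng(3)
        inst = sw.instantiate_story(graph, self.FRAME, self.FILLERS, 25, rng)
        assert len(inst.tokens) == 25
        assert inst.tokens[-1] == "qpoet"
        assert inst.target_token == "chris"
        # 15-token body plus the inserted pad occupy the first 16 positions
        assert inst.tokens[:16].count(sw.PAD_TOKEN) == 1

    def test_exact_fit_length(self, graph):
        """length == body + pad + query leaves no tail padding."""
        rng = np.random.default_rng(0)
        inst = sw.instantiate_story(graph, self.FRAME, self.FILLERS, 17, rng)
        assert len(inst.tokens) == 17
        assert inst.tokens.count(sw.PAD_TOKEN) == 1

    def test_too_short_length_rejected(self, graph):
        with pytest.raises(ValueError, match="does not fit"):
            sw.instantiate_story(graph, self.FRAME, self.FILLERS, 10,
                                 np.random.default_rng(0))

    def test_missing_filler_rejected(self, graph):
        with pytest.raises(KeyError, match="missing filler"):
            sw.instantiate_story(graph, self.FRAME, {"Subject": "alice"}, 25,
                                 np.random.default_rng(0))

    def test_pad_position_uniform(self, graph):
        """Chi-squared test of the uniform-insertion law over body positions."""
        rng = np.random.default_rng(11)
        body_len = 15
        counts = np.zeros(body_len + 1)
        for _ in range(1000):
            inst = sw.instantiate_story(graph, self.FRAME, self.FILLERS, 25, rng)
            counts[inst.tokens[:body_len + 1].index(sw.PAD_TOKEN)] += 1
        _, pval = stats.chisquare(counts)
        assert pval > 0.01

    def test_pinned_pad_position(self, graph):
        rng = np.random.default_rng(0)
        a = sw.instantiate_story(graph, self.FRAME, self.FILLERS, 25, rng, pad_position=4)
        b = sw.instantiate_story(graph, self.FRAME, self.FILLERS, 25, rng, pad_position=4)
        assert a.tokens == b.tokens


class TestLinearFrame:
    def test_template_token_order(self):
        t = sw.build_linear_frame()
        flat = [i if isinstance(i, str) else i[0].lower() for i in t]
        assert flat == ("begin subject sit subject friend announce emcee "
                        "perform poet consume dessert drink goodbye").split()

    def test_subject_slot_appears_twice(self):
        slots = [i[0] for i in sw.build_linear_frame() if isinstance(i, tuple)]
        assert slots.count("Subject") == 2

    def test_instantiation_gives_13_token_body(self):
        fillers = {r: r.lower() + "_f" for r in sw.ROLES}
        inst = sw.instantiate_template(sw.build_linear_frame(), fillers, 15,
                                       np.random.default_rng(0), "Poet")
        assert len(inst.tokens) == 15
        body = [t for t in inst.tokens[:-1] if t != sw.PAD_TOKEN]
        assert len(body) == 13

    def test_shuffle_is_the_fixed_stage_permutation(self):
        shuffled = sw.shuffle_stages(sw.build_linear_frame())
        flat = [i if isinstance(i, str) else i[0].lower() for i in shuffled]
        assert flat == ("consume dessert drink goodbye begin subject sit "
                        "subject friend announce emcee perform poet").split()

    def test_shuffle_preserves_token_multiset(self):
        assert sorted(map(str, sw.build_linear_frame())) == \
            sorted(map(str, sw.shuffle_stages(sw.build_linear_frame())))

    def test_shuffle_rejects_other_templates(self):
        with pytest.raises(ValueError):
            sw.shuffle_stages(("begin", ("Subject",)))
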