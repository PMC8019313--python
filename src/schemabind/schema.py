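"""Event-schema graphs and stochastic story generation.

A schema is a DAG of story states. Each state contributes a fixed keyword
plus zero or more role slots (Subject, Friend, Emcee, Poet, Drink,
Dessert); a story is a start-to-end traversal with every role slot
substituted by a concrete filler token. The coffee-shop schema built here
has 24 distinct traversals and 112 answerable (path, query-role) frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ROLES = ("Subject", "Friend", "Emcee", "Poet", "Drink", "Dessert")

PAD_TOKEN = "zzz"

#: query token per role, fed as the final input word
QUERY_TOKENS = {role: "q" + role.lower() for role in ROLES}


@dataclass(frozen=True)
class SchemaState:
    """One story state: a keyword plus an ordered tuple of role slots."""

    name: str
    role_slots: tuple[str, ...] = ()

    def __post_init__(self):
        for role in self.role_slots:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class SchemaGraph:
    """Directed acyclic story grammar with a unique start and terminal state."""

    states: dict[str, SchemaState]
    edges: dict[str, tuple[str, ...]]
    start: str
    terminal: str

    def __post_init__(self):
        if self.start not in self.states or self.terminal not in self.states:
            raise ValueError("start/terminal must be states")
        for src, succs in self.edges.items():
            for dst in succs:
                if dst not in self.states:
                    raise ValueError(f"edge to unknown state {dst!r}")
        if self._has_cycle():
            raise ValueError("schema graph must be acyclic")

    def _has_cycle(self) -> bool:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {name: 0 for name in self.states}

        def visit(u: str) -> bool:
            color[u] = GRAY
            for v in self.edges.get(u, ()):
                if color[v] == GRAY:
                    return True
                if color[v] == WHITE and visit(v):
                    return True
            color[u] = BLACK
            return False

        return any(color[u] == WHITE and visit(u) for u in self.states)

    def successors(self, name: str) -> tuple[str, ...]:
        return self.edges.get(name, ())


@dataclass(frozen=True)
class StoryFrame:
    """A traversal of the schema plus the role that will be queried."""

    path: tuple[str, ...]
    query_role: str


@dataclass
class StoryInstance:
    """One supervised example: token sequence, query, and target filler.

    ``filler_vectors`` optionally carries per-story embeddings for fillers
    that are freshly generated rather than part of a fixed lexicon;
    ``input_overrides`` carries input-side vector substitutions (used by
    the ambiguous zero-vector probe) that never affect the target.
    """

    tokens: list[str]
    query_token: str
    target_token: str
    binding: dict[str, str]
    frame: StoryFrame | None = None
    filler_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    input_overrides: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        rec = {
            "tokens": self.tokens,
            "query": self.query_token,
            "target": self.target_token,
            "binding": self.binding,
            "frame": list(self.frame.path) if self.frame else None,
        }
        return json.dumps(rec)


def build_coffee_shop_graph() -> SchemaGraph:
    """The 11-state coffee-shop schema.

    An evening at a poetry-night coffee shop: the subject arrives (and may
    order a possibly too-expensive drink), sits down with a friend, watches
    a poet perform (possibly introduced by an emcee), is invited on stage
    and either declines or performs, then leaves or orders dessert.
    """
    states = {
        "BEGIN": SchemaState("begin", ("Subject",)),
        "ORDER_DRINK": SchemaState("order_drink", ("Subject", "Drink")),
        "EXPENSIVE": SchemaState("too_expensive", ("Subject",)),
        "SIT": SchemaState("sit", ("Subject", "Friend")),
        "INTRO": SchemaState("emcee_intro", ("Emcee", "Poet")),
        "POETRY": SchemaState("poet_performs", ("Poet",)),
        "DECLINE": SchemaState("subject_declines", ("Subject",)),
        "PERFORM": SchemaState("subject_performs", ("Subject", "Friend")),
        "GOODBYE": SchemaState("say_goodbye", ("Subject", "Friend")),
        "ORDER_DESSERT": SchemaState("order_dessert", ("Subject", "Dessert")),
        "END": SchemaState("end", ("Subject",)),
    }
    edges = {
        "BEGIN": ("ORDER_DRINK", "SIT"),
        "ORDER_DRINK": ("EXPENSIVE", "SIT"),
        "EXPENSIVE": ("SIT",),
        "SIT": ("INTRO", "POETRY"),
        "INTRO": ("POETRY",),
        "POETRY": ("DECLINE", "PERFORM"),
        "DECLINE": ("GOODBYE", "ORDER_DESSERT"),
        "PERFORM": ("GOODBYE", "ORDER_DESSERT"),
        "GOODBYE": ("END",),
        "ORDER_DESSERT": ("END",),
    }
    # dict keyed by internal state id; SchemaState.name is the surface keyword
    return SchemaGraph(states=states, edges=edges, start="BEGIN", terminal="END")


def enumerate_paths(graph: SchemaGraph) -> list[tuple[str, ...]]:
    """All start-to-terminal traversals, in lexicographic successor order."""
    paths: list[tuple[str, ...]] = []
    stack: list[str] = [graph.start]

    def dfs(node: str) -> None:
        if node == graph.terminal:
            paths.append(tuple(stack))
            return
        for succ in graph.successors(node):
            stack.append(succ)
            dfs(succ)
            stack.pop()

    dfs(graph.start)
    return paths


def path_roles(graph: SchemaGraph, path: tuple[str, ...]) -> list[str]:
    """Distinct roles appearing on a path, in ROLES order."""
    present = {role for name in path for role in graph.states[name].role_slots}
    return [r for r in ROLES if r in present]


def enumerate_query_frames(graph: SchemaGraph) -> list[StoryFrame]:
    """One frame per (path, answerable role): 112 for the coffee-shop graph."""
    return [
        StoryFrame(path=path, query_role=role)
        for path in enumerate_paths(graph)
        for role in path_roles(graph, path)
    ]


def sample_path(graph: SchemaGraph, rng: np.random.Generator) -> tuple[str, ...]:
    """Sample a traversal; each outgoing transition is equally likely."""
    path = [graph.start]
    while path[-1] != graph.terminal:
        succs = graph.successors(path[-1])
        if not succs:
            raise ValueError(f"dead end at {path[-1]!r}")
        path.append(succs[rng.integers(len(succs))])
    return tuple(path)


def path_probability(graph: SchemaGraph, path: tuple[str, ...]) -> float:
    """Analytic sampling probability: product of 1/out-degree along the path."""
    p = 1.0
    for name in path[:-1]:
        p /= len(graph.successors(name))
    return p


def story_body(graph: SchemaGraph, path: tuple[str, ...],
               fillers: dict[str, str]) -> list[str]:
    """Keyword + slot fillers per state, in path and slot order."""
    body: list[str] = []
    for name in path:
        state = graph.states[name]
        body.append(state.name)
        for role in state.role_slots:
            if role not in fillers:
                raise KeyError(f"missing filler for role {role!r} on path")
            body.append(fillers[role])
    return body


def max_body_length(graph: SchemaGraph) -> int:
    """Length of the longest story body over all traversals."""
    return max(
        sum(1 + len(graph.states[n].role_slots) for n in path)
        for path in enumerate_paths(graph)
    )


def default_sequence_length(graph: SchemaGraph) -> int:
    """Smallest fixed length fitting the longest body + one pad + the query."""
    return max_body_length(graph) + 2


def instantiate_story(graph: SchemaGraph, frame: StoryFrame,
                      fillers: dict[str, str], length: int,
                      rng: np.random.Generator,
                      pad_position: int | None = None) -> StoryInstance:
    """Realize a frame as a fixed-length token sequence.

    One pad token is inserted at a uniformly random position inside the
    body (``pad_position`` pins it, for identical-frame decoding sets);
    the tail is padded so every instance has the same length; the query
    token comes last.
    """
    body = story_body(graph, frame.path, fillers)
    if len(body) + 2 > length:
        raise ValueError(f"body of {len(body)} tokens does not fit in length {length}")
    pos = int(rng.integers(len(body) + 1)) if pad_position is None else pad_position
    tokens = body[:pos] + [PAD_TOKEN] + body[pos:]
    tokens += [PAD_TOKEN] * (length - 1 - len(tokens))
    query = QUERY_TOKENS[frame.query_role]
    tokens.append(query)
    binding = {r: fillers[r] for r in path_roles(graph, frame.path)}
    return StoryInstance(tokens=tokens, query_token=query,
                         target_token=fillers[frame.query_role],
                         binding=binding, frame=frame)


# -- fixed linear frame for the correlation experiments -----------------------

#: template items: plain keywords, or (role,) slots
LINEAR_TEMPLATE: tuple = (
    "begin", ("Subject",), "sit", ("Subject",), ("Friend",),
    "announce", ("Emcee",), "perform", ("Poet",),
    "consume", ("Dessert",), ("Drink",), "goodbye",
)

#: the fixed stage shuffle used by the shuffled-story stress test
SHUFFLED_TEMPLATE: tuple = (
    "consume", ("Dessert",), ("Drink",), "goodbye",
    "begin", ("Subject",), "sit", ("Subject",), ("Friend",),
    "announce", ("Emcee",), "perform", ("Poet",),
)


def build_linear_frame() -> tuple:
    """The fixed 13-token story template of the correlation experiments."""
    return LINEAR_TEMPLATE


def shuffle_stages(template: tuple) -> tuple:
    """The fixed stage-shuffled variant of the linear frame."""
    if template != LINEAR_TEMPLATE:
        raise ValueError("shuffle_stages is defined for the linear frame")
    return SHUFFLED_TEMPLATE


def template_roles(template: tuple) -> list[str]:
    present = {item[0] for item in template if isinstance(item, tuple)}
    return [r for r in ROLES if r in present]


def instantiate_template(template: tuple, fillers: dict[str, str], length: int,
                         rng: np.random.Generator, query_role: str,
                         pad_position: int | None = None) -> StoryInstance:
    """Realize a fixed template (pad insertion and query as for graph stories)."""
    body = [fillers[item[0]] if isinstance(item, tuple) else item for item in template]
    if len(body) + 2 > length:
        raise ValueError("template does not fit in requested length")
    pos = int(rng.integers(len(body) + 1)) if pad_position is None else pad_position
    tokens = body[:pos] + [PAD_TOKEN] + body[pos:]
    tokens += [PAD_TOKEN] * (length - 1 - len(tokens))
    query = QUERY_TOKENS[query_role]
    tokens.append(query)
    binding = {r: fillers[r] for r in template_roles(template)}
    return StoryInstance(tokens=tokens, query_token=query,
                         target_token=fillers[query_role], binding=binding)
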