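"""Causal path models as labelled DAGs, constrained exhaustive enumeration,
and d-separation basis sets.

The model space searched by the exploratory path analysis is the set of ALL
labelled directed acyclic graphs over the declared variables whose every edge
is permitted by the user's constraints: groups of mutually exogenous variables
(predictable only by each other) and per-variable forbidden parents.
Disconnected graphs are included; an optional connectivity filter is
available in :func:`enumerate_dags`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "DagModel",
    "ConstraintSpec",
    "IndependenceClaim",
    "is_acyclic",
    "enumerate_dags",
    "count_dags",
    "basis_set",
    "to_dot",
    "from_dot",
]


def _topological_order(nodes: Sequence[str], edges: Iterable[tuple[str, str]]):
    """Kahn's algorithm with first-declared tie-breaking; None if cyclic."""
    idx = {v: i for i, v in enumerate(nodes)}
    indeg = {v: 0 for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    ready = sorted((v for v in nodes if indeg[v] == 0), key=idx.get)
    order: list[str] = []
    while ready:
        v = ready.pop(0)
        order.append(v)
        changed = False
        for w in children[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                ready.append(w)
                changed = True
        if changed:
            ready.sort(key=idx.get)
    return order if len(order) == len(nodes) else None


def is_acyclic(edges: Iterable[tuple[str, str]], nodes: Sequence[str] | None = None) -> bool:
    """True iff a topological order exists over the edge set."""
    edges = list(edges)
    if nodes is None:
        nodes = sorted({v for e in edges for v in e})
    return _topological_order(list(nodes), edges) is not None


@dataclass(frozen=True)
class DagModel:
    """A candidate causal structure: ordered variable names plus directed edges."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        declared = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge {u!r} -> {v!r}")
            if u not in declared or v not in declared:
                raise ValueError(f"edge {u!r} -> {v!r} references undeclared node")
        if _topological_order(self.nodes, self.edges) is None:
            raise ValueError("edge set contains a cycle")

    @cached_property
    def parents(self) -> dict[str, frozenset[str]]:
        par: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            par[v].add(u)
        return {v: frozenset(s) for v, s in par.items()}

    @cached_property
    def topological_order(self) -> tuple[str, ...]:
        order = _topological_order(self.nodes, self.edges)
        assert order is not None
        return tuple(order)

    def sorted_edges(self) -> list[tuple[str, str]]:
        idx = {v: i for i, v in enumerate(self.nodes)}
        return sorted(self.edges, key=lambda e: (idx[e[0]], idx[e[1]]))

    def to_json_obj(self) -> dict:
        return {"nodes": list(self.nodes), "edges": [list(e) for e in self.sorted_edges()]}


_EDGE_STR = re.compile(r"^\s*(\S+)\s*->\s*(\S+)\s*$")


@dataclass(frozen=True)
class ConstraintSpec:
    """Rules defining the searchable model space.

    ``mutually_exogenous`` lists groups of variables that may be predicted
    only by members of their own group (the classic case: two environmental
    variables that may influence each other but cannot be caused by anything
    socio-cultural).  ``forbidden_parents`` maps a variable to the set of
    variables that may never be its parents, and ``forbidden_edges`` lists
    individually banned ``(cause, effect)`` pairs.
    """

    mutually_exogenous: tuple[frozenset[str], ...] = ()
    forbidden_parents: Mapping[str, frozenset[str]] = field(default_factory=dict)
    forbidden_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self,
            "mutually_exogenous",
            tuple(frozenset(g) for g in self.mutually_exogenous),
        )
        object.__setattr__(
            self,
            "forbidden_parents",
            {k: frozenset(v) for k, v in dict(self.forbidden_parents).items()},
        )
        object.__setattr__(
            self, "forbidden_edges", frozenset(tuple(e) for e in self.forbidden_edges)
        )

    def allows(self, cause: str, effect: str) -> bool:
        if (cause, effect) in self.forbidden_edges:
            return False
        for group in self.mutually_exogenous:
            if effect in group and cause not in group:
                return False
        banned = self.forbidden_parents.get(effect)
        if banned is not None and cause in banned:
            return False
        return True

    def allowed_edges(self, nodes: Sequence[str]) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and self.allows(u, v)
        ]

    def validate(self, nodes: Sequence[str]) -> None:
        declared = set(nodes)
        referenced = set().union(*self.mutually_exogenous, set()) if self.mutually_exogenous else set()
        referenced |= set(self.forbidden_parents)
        referenced |= {v for s in self.forbidden_parents.values() for v in s}
        referenced |= {v for e in self.forbidden_edges for v in e}
        unknown = referenced - declared
        if unknown:
            raise ValueError(f"constraints reference undeclared variables: {sorted(unknown)}")

    def restrict(self, nodes: Sequence[str]) -> "ConstraintSpec":
        """Project the constraints onto a subset of variables (rules about
        variables outside the subset are dropped)."""
        keep = set(nodes)
        return ConstraintSpec(
            mutually_exogenous=tuple(
                frozenset(g & keep) for g in self.mutually_exogenous
                if g & keep
            ),
            forbidden_parents={
                v: frozenset(s & keep)
                for v, s in self.forbidden_parents.items() if v in keep
            },
            forbidden_edges=frozenset(
                e for e in self.forbidden_edges
                if e[0] in keep and e[1] in keep
            ),
        )

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ConstraintSpec":
        """Build from a config mapping with keys ``mutually_exogenous``
        (list of variable-name lists) and ``forbidden_edges`` (list of
        ``"X -> Y"`` strings)."""
        groups = tuple(frozenset(g) for g in cfg.get("mutually_exogenous", []))
        edges = set()
        for s in cfg.get("forbidden_edges", []):
            m = _EDGE_STR.match(s)
            if not m:
                raise ValueError(f"cannot parse forbidden edge {s!r}; expected 'X -> Y'")
            edges.add((m.group(1), m.group(2)))
        fp = {k: frozenset(v) for k, v in cfg.get("forbidden_parents", {}).items()}
        return cls(
            mutually_exogenous=groups,
            forbidden_parents=fp,
            forbidden_edges=frozenset(edges),
        )


class ModelSpaceTooLarge(ValueError):
    pass


def _prepare(nodes, constraints, node_limit, allow_large, max_allowed_edges):
    nodes = tuple(nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate variable names")
    if len(nodes) > node_limit and not allow_large:
        raise ModelSpaceTooLarge(
            f"{len(nodes)} nodes exceeds the limit of {node_limit}; "
            "pass allow_large=True (or raise node_limit) to override"
        )
    constraints = constraints or ConstraintSpec()
    constraints.validate(nodes)
    allowed = constraints.allowed_edges(nodes)
    if len(allowed) > max_allowed_edges and not allow_large:
        raise ModelSpaceTooLarge(
            f"{len(allowed)} permitted edges imply 2^{len(allowed)} candidate "
            "edge sets; pass allow_large=True to force enumeration"
        )
    return nodes, allowed


def _edge_subset_masks(nodes: tuple[str, ...], allowed: list[tuple[str, str]]):
    """Yield (mask, index-pair list) for every acyclic subset of the allowed
    edges, in ascending mask order (deterministic and restartable)."""
    idx = {v: i for i, v in enumerate(nodes)}
    pairs = [(idx[u], idx[v]) for u, v in allowed]
    n = len(nodes)
    m = len(pairs)
    for mask in range(1 << m):
        sel = [pairs[b] for b in range(m) if (mask >> b) & 1]
        indeg = [0] * n
        children: list[list[int]] = [[] for _ in range(n)]
        for i, j in sel:
            children[i].append(j)
            indeg[j] += 1
        stack = [v for v in range(n) if indeg[v] == 0]
        seen = 0
        while stack:
            v = stack.pop()
            seen += 1
            for w in children[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        if seen == n:
            yield mask, sel


def enumerate_dags(
    nodes: Sequence[str],
    constraints: ConstraintSpec | None = None,
    node_limit: int = 7,
    allow_large: bool = False,
    max_allowed_edges: int = 25,
    connected_only: bool = False,
) -> Iterator[DagModel]:
    """Yield every constraint-satisfying labelled DAG over ``nodes``.

    Generation order is deterministic (ascending over subsets of the sorted
    permitted-edge list) so the stream regenerates identically.  The guard on
    node count / permitted-edge count protects against combinatorial blow-up;
    it can be overridden.
    """
    nodes, allowed = _prepare(nodes, constraints, node_limit, allow_large, max_allowed_edges)
    # reuse one tuple object per allowed edge so enumerated models share them
    allowed_tuples = [tuple(e) for e in allowed]
    idx = {v: i for i, v in enumerate(nodes)}
    pair_to_edge = {(idx[u], idx[v]): t for t, (u, v) in zip(allowed_tuples, allowed)}
    for _, sel in _edge_subset_masks(nodes, allowed):
        edges = frozenset(pair_to_edge[p] for p in sel)
        if connected_only and not _weakly_connected(nodes, edges):
            continue
        model = DagModel.__new__(DagModel)
        object.__setattr__(model, "nodes", nodes)
        object.__setattr__(model, "edges", edges)
        yield model


def _weakly_connected(nodes, edges) -> bool:
    if len(nodes) <= 1:
        return True
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nodes)


def count_dags(
    nodes: Sequence[str],
    constraints: ConstraintSpec | None = None,
    node_limit: int = 7,
    allow_large: bool = False,
    max_allowed_edges: int = 25,
) -> int:
    """Number of models :func:`enumerate_dags` would yield, without building them."""
    nodes, allowed = _prepare(nodes, constraints, node_limit, allow_large, max_allowed_edges)
    return sum(1 for _ in _edge_subset_masks(nodes, allowed))


@dataclass(frozen=True)
class IndependenceClaim:
    """One conditional-independence statement entailed by a DAG.

    ``x`` and ``y`` are non-adjacent in the source model; the claim is
    x independent of y given ``conditioning`` (the union of the two
    variables' parents).  ``response`` records which of the pair is regressed
    on the other when the claim is tested: the one later in the model's
    topological order, as in regression-based d-separation practice.
    """

    x: str
    y: str
    conditioning: frozenset[str]
    response: str

    def __post_init__(self):
        if self.x == self.y:
            raise ValueError("claim requires two distinct variables")
        if self.response not in (self.x, self.y):
            raise ValueError("response must be one of the claim's variables")
        if self.x in self.conditioning or self.y in self.conditioning:
            raise ValueError("conditioning set must exclude the claim pair")

    @property
    def predictor(self) -> str:
        return self.y if self.response == self.x else self.x

    def key(self) -> tuple:
        """Canonical cache key: unordered pair + sorted conditioning + response."""
        a, b = sorted((self.x, self.y))
        return (a, b, tuple(sorted(self.conditioning)), self.response)


def basis_set(model: DagModel) -> list[IndependenceClaim]:
    """The d-separation basis of ``model``: one claim per non-adjacent pair,
    conditioned on the union of the pair's parents, in canonical order.

    Its size is always ``v(v-1)/2 - |E|``.
    """
    pos = {v: i for i, v in enumerate(model.topological_order)}
    idx = {v: i for i, v in enumerate(model.nodes)}
    adjacent = {frozenset(e) for e in model.edges}
    par = model.parents
    claims = []
    for x, y in itertools.combinations(model.nodes, 2):
        if frozenset((x, y)) in adjacent:
            continue
        cond = (par[x] | par[y]) - {x, y}
        response = x if pos[x] > pos[y] else y
        claims.append(IndependenceClaim(x=x, y=y, conditioning=cond, response=response))
    claims.sort(key=lambda c: (idx[c.x], idx[c.y], tuple(sorted(c.conditioning))))
    return claims


def to_dot(
    model: DagModel,
    annotations: Mapping[tuple[str, str], float] | None = None,
    name: str = "model",
) -> str:
    """Deterministic DOT text; edge width scales with |coefficient| and
    negative coefficients are drawn in red."""
    annotations = dict(annotations or {})
    max_abs = max((abs(c) for c in annotations.values()), default=0.0)
    lines = [f"digraph {name} {{"]
    for v in model.nodes:
        lines.append(f'  "{v}";')
    for u, v in model.sorted_edges():
        coef = annotations.get((u, v))
        attrs = []
        if coef is not None:
            width = 1.0 + (3.0 * abs(coef) / max_abs if max_abs > 0 else 0.0)
            attrs.append(f'label="{coef:.3f}"')
            attrs.append(f"penwidth={width:.3f}")
            attrs.append(f'color={"red3" if coef < 0 else "black"}')
        suffix = f' [{", ".join(attrs)}]' if attrs else ""
        lines.append(f'  "{u}" -> "{v}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_EDGE = re.compile(r'"([^"]+)"\s*->\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*(?:\[[^\]]*\])?\s*;\s*$')


def from_dot(text: str) -> DagModel:
    """Recover the node and edge sets from DOT produced by :func:`to_dot`."""
    nodes: list[str] = []
    edges = set()
    for line in text.splitlines():
        m = _DOT_EDGE.search(line)
        if m:
            edges.add((m.group(1), m.group(2)))
            continue
        m = _DOT_NODE.match(line)
        if m and m.group(1) not in nodes:
            nodes.append(m.group(1))
    for u, v in edges:
        for w in (u, v):
            if w not in nodes:
                nodes.append(w)
    return DagModel(nodes=tuple(nodes), edges=frozenset(edges))
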