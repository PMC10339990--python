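"""Chromosomal rearrangement events and minimum-event ancestral reconstruction.

The model evolves abstract haploid karyotypes — counts of chromosomes per
Levan morphology class — under four whole-chromosome events:

* **centric (Robertsonian) fusion**: two telocentrics join into one biarmed
  chromosome (n decreases by 1, the diploid fundamental number is conserved);
* **centric fission**: the reverse split (n increases by 1, FN conserved);
* **pericentric inversion**: one chromosome changes morphology class
  (n conserved, diploid FN moves by -2, 0 or +2);
* **centromere repositioning**: the same state change as a pericentric
  inversion, produced by relocation of centromere activity instead of an
  inversion; cytogenetic data of this kind cannot tell the two apart, so
  they are merged in search and reports whenever their costs are equal.

Ancestral states on a fixed rooted tree are reconstructed with exact Sankoff
dynamic programming over an explicit state space, with pairwise transition
costs equal to the minimal total event cost between states (uniform-cost
search). Costs may be asymmetric: the default configuration penalises
fissions, encoding the standard squamate prior that high chromosome numbers
and telocentric complements are ancestral, so fusion-driven descent is
preferred over fission-driven ascent.
"""

from __future__ import annotations

import enum
import heapq
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .karyotype_core import BIARMED_CLASSES, PURE_CLASSES, KaryotypeState, MorphClass

__all__ = [
    "EventKind",
    "Event",
    "EventModel",
    "EventError",
    "ReconstructionError",
    "apply_event",
    "neighbors",
    "event_distance",
    "enumerate_state_space",
    "transition_cost_matrix",
    "sankoff_reconstruct",
    "scenario_report",
    "ReconstructionResult",
]


class EventError(ValueError):
    """An event was applied to a state lacking its prerequisites."""


class ReconstructionError(RuntimeError):
    """Ancestral reconstruction failed or hit a configured search bound."""


class EventKind(str, enum.Enum):
    CENTRIC_FUSION = "centric_fusion"
    CENTRIC_FISSION = "centric_fission"
    PERICENTRIC_INVERSION = "pericentric_inversion"
    CENTROMERE_REPOSITIONING = "centromere_repositioning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Event:
    """One rearrangement event.

    ``target`` is the product class of a fusion; ``source`` the biarmed
    class consumed by a fission; inversions/repositionings reclassify one
    chromosome from ``source`` to ``target``.
    """

    kind: EventKind
    source: MorphClass | None = None
    target: MorphClass | None = None

    def __post_init__(self) -> None:
        k = self.kind
        if k is EventKind.CENTRIC_FUSION:
            if self.target not in BIARMED_CLASSES or self.source is not None:
                raise ValueError("fusion takes only a biarmed target class")
        elif k is EventKind.CENTRIC_FISSION:
            if self.source not in BIARMED_CLASSES or self.target is not None:
                raise ValueError("fission takes only a biarmed source class")
        else:
            if (
                self.source not in PURE_CLASSES
                or self.target not in PURE_CLASSES
                or self.source is self.target
            ):
                raise ValueError(
                    "reclassification needs two distinct pure morphology classes"
                )

    def describe(self, merged_inv_repo: bool = True) -> str:
        if self.kind is EventKind.CENTRIC_FUSION:
            return f"centric fusion (t + t -> {self.target})"
        if self.kind is EventKind.CENTRIC_FISSION:
            return f"centric fission ({self.source} -> t + t)"
        label = (
            "inv/repo"
            if merged_inv_repo
            else ("inversion" if self.kind is EventKind.PERICENTRIC_INVERSION else "repositioning")
        )
        return f"{label} ({self.source} -> {self.target})"


@dataclass(frozen=True)
class EventModel:
    """Per-event-kind positive costs plus search-space configuration.

    The defaults are the case-study configuration: fusions and
    inversions/repositionings cost 1, fissions cost 5. The fission penalty
    operationalises the prior that larger, more telocentric complements are
    ancestral; with all-equal costs the reconstruction is free to prefer
    smaller ancestral chromosome numbers.
    """

    fusion_cost: float = 1.0
    fission_cost: float = 5.0
    inversion_cost: float = 1.0
    repositioning_cost: float = 1.0
    fusion_target: MorphClass = MorphClass.M
    state_radius: int = 6
    max_n: int = 30

    def __post_init__(self) -> None:
        for name in ("fusion_cost", "fission_cost", "inversion_cost", "repositioning_cost"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fusion_target not in BIARMED_CLASSES:
            raise ValueError("fusion_target must be a biarmed class")
        if self.state_radius < 1 or self.max_n < 2:
            raise ValueError("state_radius >= 1 and max_n >= 2 required")

    def cost(self, kind: EventKind) -> float:
        return {
            EventKind.CENTRIC_FUSION: self.fusion_cost,
            EventKind.CENTRIC_FISSION: self.fission_cost,
            EventKind.PERICENTRIC_INVERSION: self.inversion_cost,
            EventKind.CENTROMERE_REPOSITIONING: self.repositioning_cost,
        }[kind]

    @property
    def reclass_cost(self) -> float:
        """Cost of the cheaper of inversion / repositioning."""
        return min(self.inversion_cost, self.repositioning_cost)

    @property
    def reclass_kind(self) -> EventKind:
        if self.repositioning_cost < self.inversion_cost:
            return EventKind.CENTROMERE_REPOSITIONING
        return EventKind.PERICENTRIC_INVERSION

    @property
    def inv_repo_merged(self) -> bool:
        return self.inversion_cost == self.repositioning_cost

    @property
    def symmetric(self) -> bool:
        return self.fusion_cost == self.fission_cost


def apply_event(s: KaryotypeState, e: Event) -> KaryotypeState:
    """Apply one event, returning the resulting state (input unmodified)."""
    c = dict(zip(PURE_CLASSES, (s.m, s.sm, s.st, s.t)))
    if e.kind is EventKind.CENTRIC_FUSION:
        if c[MorphClass.T] < 2:
            raise EventError(
                f"centric fusion needs two telocentrics, state {s} has {s.t}"
            )
        c[MorphClass.T] -= 2
        c[e.target] += 1
    elif e.kind is EventKind.CENTRIC_FISSION:
        if c[e.source] < 1:
            raise EventError(
                f"centric fission needs a {e.source} chromosome, none in {s}"
            )
        c[e.source] -= 1
        c[MorphClass.T] += 2
    else:
        if c[e.source] < 1:
            raise EventError(
                f"reclassification needs a {e.source} chromosome, none in {s}"
            )
        c[e.source] -= 1
        c[e.target] += 1
    return KaryotypeState.from_counts(c)


def neighbors(
    s: KaryotypeState, model: EventModel | None = None
) -> list[tuple[Event, KaryotypeState]]:
    """All states one applicable event away.

    Inversion and repositioning produce identical state changes; when their
    costs are equal only the cheaper-kind representative is listed, so each
    (event, resulting state) pair is unique. With unequal costs both kinds
    are enumerated (they are then distinguishable in cost).
    """
    model = model or EventModel()
    out: list[tuple[Event, KaryotypeState]] = []
    if s.t >= 2:
        for target in BIARMED_CLASSES:
            e = Event(EventKind.CENTRIC_FUSION, target=target)
            out.append((e, apply_event(s, e)))
    for source in BIARMED_CLASSES:
        if s.counts[source] >= 1:
            e = Event(EventKind.CENTRIC_FISSION, source=source)
            out.append((e, apply_event(s, e)))
    reclass_kinds = (
        (model.reclass_kind,)
        if model.inv_repo_merged
        else (EventKind.PERICENTRIC_INVERSION, EventKind.CENTROMERE_REPOSITIONING)
    )
    for source, target in itertools.permutations(PURE_CLASSES, 2):
        if s.counts[source] >= 1:
            for kind in reclass_kinds:
                e = Event(kind, source=source, target=target)
                out.append((e, apply_event(s, e)))
    return out


def event_distance(
    a: KaryotypeState,
    b: KaryotypeState,
    model: EventModel | None = None,
    max_n: int | None = None,
) -> tuple[float, list[Event]]:
    """Minimal-cost event path ``a -> b`` by uniform-cost (Dijkstra) search.

    The search explores all states with haploid number ``n <= max_n``
    (default from the model). Returns the cost and one optimal path; with a
    symmetric model (fission cost = fusion cost) the cost is symmetric in
    its arguments.
    """
    model = model or EventModel()
    bound = model.max_n if max_n is None else max_n
    if a.n > bound or b.n > bound:
        raise ValueError(
            f"states exceed the search bound max_n={bound}; raise max_n"
        )
    start, goal = a.as_tuple(), b.as_tuple()
    dist: dict[tuple[int, int, int, int], float] = {start: 0.0}
    prev: dict[tuple, tuple[tuple, Event]] = {}
    counter = itertools.count()  # tie-breaker keeps heap entries comparable
    heap: list = [(0.0, next(counter), start)]
    done: set[tuple] = set()
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in done:
            continue
        if u == goal:
            path: list[Event] = []
            node = u
            while node != start:
                node, ev = prev[node][0], prev[node][1]
                path.append(ev)
            path.reverse()
            return d, path
        done.add(u)
        su = KaryotypeState(*u)
        for ev, sv in neighbors(su, model):
            if sv.n > bound:
                continue
            v = sv.as_tuple()
            nd = d + model.cost(ev.kind)
            if v not in dist or nd < dist[v] - 1e-12:
                dist[v] = nd
                prev[v] = (u, ev)
                heapq.heappush(heap, (nd, next(counter), v))
    raise ReconstructionError(
        f"{b} unreachable from {a} within max_n={bound}; try a larger max_n"
    )


# ---------------------------------------------------------------------------
# explicit state space + all-pairs transition costs (for Sankoff)
# ---------------------------------------------------------------------------


def enumerate_state_space(
    seeds: Iterable[KaryotypeState],
    radius: int,
    max_n: int,
    model: EventModel | None = None,
) -> dict[KaryotypeState, int]:
    """States within ``radius`` single events of any seed state.

    Returns a mapping state -> minimal event depth from the nearest seed
    (depth, not cost: every applicable event counts as one step). Used to
    bound the Sankoff search and to detect when a reconstruction presses
    against the configured radius.
    """
    model = model or EventModel()
    seeds = list(seeds)
    if not seeds:
        raise ValueError("state space needs at least one seed state")
    depth: dict[KaryotypeState, int] = {}
    frontier = []
    for s in seeds:
        if s.n > max_n:
            raise ValueError(f"seed state {s} exceeds max_n={max_n}")
        if s not in depth:
            depth[s] = 0
            frontier.append(s)
    for d in range(1, radius + 1):
        nxt = []
        for s in frontier:
            for _, t in neighbors(s, model):
                if t.n <= max_n and t not in depth:
                    depth[t] = d
                    nxt.append(t)
        frontier = nxt
    return depth


def transition_cost_matrix(
    states: Sequence[KaryotypeState], model: EventModel
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], Event]]:
    """Directed all-pairs minimal event costs among an explicit state set.

    Builds the one-event graph restricted to ``states`` and runs Dijkstra
    from every state (``scipy.sparse.csgraph``). Returns the dense cost
    matrix, the predecessor matrix, and the map from one-event edges to
    their cheapest realising :class:`Event` (used to decompose branch paths
    into event lists).
    """
    index = {s: i for i, s in enumerate(states)}
    rows, cols, weights = [], [], []
    edge_event: dict[tuple[int, int], Event] = {}
    for i, s in enumerate(states):
        best: dict[int, tuple[float, Event]] = {}
        for ev, t in neighbors(s, model):
            j = index.get(t)
            if j is None:
                continue
            w = model.cost(ev.kind)
            if j not in best or w < best[j][0]:
                best[j] = (w, ev)
        for j, (w, ev) in best.items():
            rows.append(i)
            cols.append(j)
            weights.append(w)
            edge_event[(i, j)] = ev
    n = len(states)
    graph = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
    costs, predecessors = _csgraph_dijkstra(
        graph, directed=True, return_predecessors=True
    )
    return costs, predecessors, edge_event


def _walk_path(
    i: int, j: int, predecessors: np.ndarray, edge_event: Mapping[tuple[int, int], Event]
) -> list[Event]:
    """Reconstruct the event list of the shortest path i -> j."""
    if i == j:
        return []
    path_nodes = [j]
    while path_nodes[-1] != i:
        p = predecessors[i, path_nodes[-1]]
        if p < 0:
            raise ReconstructionError("no path inside the state space")
        path_nodes.append(int(p))
    path_nodes.reverse()
    return [edge_event[(u, v)] for u, v in zip(path_nodes, path_nodes[1:])]


# ---------------------------------------------------------------------------
# Sankoff reconstruction
# ---------------------------------------------------------------------------


def node_labels(tree) -> dict[int, str]:
    """Deterministic node labels: tip taxa for leaves, N1.. in preorder.

    Keys are ``id(node)`` so the labels can annotate any dendropy tree
    without mutating it; the same scheme is used by the simulator so that
    simulated truth and reconstruction output line up node by node.
    """
    labels: dict[int, str] = {}
    counter = itertools.count(1)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            labels[id(nd)] = nd.taxon.label
        else:
            labels[id(nd)] = f"N{next(counter)}"
    return labels


@dataclass
class ReconstructionResult:
    """Outcome of a Sankoff reconstruction.

    ``node_states`` holds, per node label, every state that occurs in at
    least one globally optimal labeling; ``designated`` is one deterministic
    optimal labeling (ties resolved towards the largest diploid number,
    then lexicographically smallest (m, sm, st, t) counts).
    """

    total_cost: float
    node_states: dict[str, tuple[KaryotypeState, ...]]
    designated: dict[str, KaryotypeState]
    branch_events: dict[tuple[str, str], tuple[Event, ...]]
    branch_costs: dict[tuple[str, str], float]
    tip_labels: tuple[str, ...]
    node_tips: dict[str, tuple[str, ...]]
    root_label: str
    model: EventModel
    state_space_size: int
    notes: tuple[str, ...] = ()
    #: total tree cost if the root is forced to a given candidate state;
    #: lets reports compare the optimum against a hypothesised ancestral
    #: condition without re-running the DP
    root_costs: dict[KaryotypeState, float] = field(default_factory=dict)


def _tiebreak_key(s: KaryotypeState) -> tuple:
    # prefer the largest haploid number (ancestral-condition prior), then
    # the lexicographically smallest count vector — deterministic output
    return (-s.n, s.as_tuple())


def sankoff_reconstruct(
    tree,
    tip_states: Mapping[str, KaryotypeState | None],
    model: EventModel | None = None,
    state_space: Iterable[KaryotypeState] | None = None,
) -> ReconstructionResult:
    """Exact Sankoff parsimony over karyotype states on a rooted tree.

    Parameters
    ----------
    tree
        A rooted ``dendropy.Tree`` (or any object exposing the same
        ``seed_node``/``child_nodes``/``taxon`` interface).
    tip_states
        Maps each tip label to its :class:`KaryotypeState`, or ``None`` for
        tips without karyotype data; unknown tips contribute zero cost for
        every candidate ancestral state. Every key must name a tree tip.
    model
        Event costs and search configuration; defaults to the asymmetric
        case-study model (fission cost 5).
    state_space
        Explicit candidate states; by default all states within
        ``model.state_radius`` single events of any known tip state. The
        reconstruction refuses to answer if an optimal node state sits on
        that radius boundary, since the optimum could then lie outside the
        enumerated space.
    """
    model = model or EventModel()

    leaves = [lf for lf in tree.leaf_node_iter()]
    leaf_labels = [lf.taxon.label for lf in leaves]
    if len(set(leaf_labels)) != len(leaf_labels):
        raise ValueError("tree has duplicate tip labels")
    unknown_keys = set(tip_states) - set(leaf_labels)
    if unknown_keys:
        raise ValueError(
            f"tip labels absent from the tree: {sorted(unknown_keys)}"
        )
    known = {
        label: s for label, s in tip_states.items() if s is not None
    }
    if not known:
        raise ValueError("no tip has a known karyotype state")

    if state_space is None:
        depth = enumerate_state_space(
            known.values(), model.state_radius, model.max_n, model
        )
        boundary = {s for s, d in depth.items() if d >= model.state_radius}
        states = sorted(depth, key=lambda s: s.as_tuple())
    else:
        states = sorted(set(state_space), key=lambda s: s.as_tuple())
        boundary = set()
        missing = [s for s in known.values() if s not in set(states)]
        if missing:
            raise ValueError(
                f"state space does not contain tip states: {missing}"
            )
    index = {s: i for i, s in enumerate(states)}
    K = len(states)

    cost_mat, predecessors, edge_event = transition_cost_matrix(states, model)

    # --- node bookkeeping: deterministic preorder labels for internal nodes
    node_label = node_labels(tree)
    node_tips: dict[str, tuple[str, ...]] = {}
    for nd in tree.preorder_node_iter():
        tips = tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))
        node_tips[node_label[id(nd)]] = tips

    INF = np.inf
    up: dict[int, np.ndarray] = {}  # id(node) -> S_v over states
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            s = known.get(label)
            vec = np.zeros(K) if s is None else np.full(K, INF)
            if s is not None:
                vec[index[s]] = 0.0
            up[id(nd)] = vec
        else:
            vec = np.zeros(K)
            for ch in nd.child_nodes():
                # contribution of child ch for each candidate parent state
                vec = vec + (cost_mat + up[id(ch)][None, :]).min(axis=1)
            up[id(nd)] = vec

    root = tree.seed_node
    total = float(up[id(root)].min())
    if not np.isfinite(total):
        raise ReconstructionError(
            "no connecting path inside the state space; increase state_radius"
        )

    # --- down-pass: states occurring in at least one optimal labeling
    down: dict[int, np.ndarray] = {id(root): np.zeros(K)}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        for ch in nd.child_nodes():
            contrib = (cost_mat + up[id(ch)][None, :]).min(axis=1)
            q = down[id(nd)] + up[id(nd)] - contrib  # rest-of-tree cost per parent state
            down[id(ch)] = (q[:, None] + cost_mat).min(axis=0)

    tol = 1e-9
    node_states: dict[str, tuple[KaryotypeState, ...]] = {}
    for nd in tree.preorder_node_iter():
        f = up[id(nd)] + down[id(nd)]
        opt = [states[i] for i in np.flatnonzero(f <= total + tol)]
        node_states[node_label[id(nd)]] = tuple(
            sorted(opt, key=_tiebreak_key)
        )

    # --- designated labeling (deterministic tie-breaking), branch events
    root_opt = node_states[node_label[id(root)]]
    designated: dict[str, KaryotypeState] = {
        node_label[id(root)]: min(root_opt, key=_tiebreak_key)
    }
    branch_events: dict[tuple[str, str], tuple[Event, ...]] = {}
    branch_costs: dict[tuple[str, str], float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        p_state = designated[node_label[id(nd)]]
        pi = index[p_state]
        for ch in nd.child_nodes():
            through = cost_mat[pi, :] + up[id(ch)]
            best = through.min()
            cand = [states[i] for i in np.flatnonzero(through <= best + tol)]
            c_state = min(cand, key=_tiebreak_key)
            designated[node_label[id(ch)]] = c_state
            ci = index[c_state]
            key = (node_label[id(nd)], node_label[id(ch)])
            branch_costs[key] = float(cost_mat[pi, ci])
            branch_events[key] = tuple(
                _walk_path(pi, ci, predecessors, edge_event)
            )

    # sanity: the designated labeling realises the DP optimum exactly
    assert abs(sum(branch_costs.values()) - total) <= 1e-6

    touched = [
        s
        for label, opts in node_states.items()
        for s in opts
        if s in boundary
    ]
    if touched:
        raise ReconstructionError(
            "optimal states touch the state-space radius boundary "
            f"(radius={model.state_radius}); increase state_radius to be sure "
            f"the optimum is inside the enumerated space: {sorted(set(map(str, touched)))}"
        )

    notes = []
    if model.inv_repo_merged:
        notes.append(
            "pericentric inversion and centromere repositioning have equal "
            "costs and are indistinguishable in this data; reported merged "
            "as 'inv/repo'"
        )
    return ReconstructionResult(
        total_cost=total,
        node_states=node_states,
        designated=designated,
        branch_events=branch_events,
        branch_costs=branch_costs,
        tip_labels=tuple(leaf_labels),
        node_tips=node_tips,
        root_label=node_label[id(root)],
        model=model,
        state_space_size=K,
        notes=tuple(notes),
        root_costs={
            s: float(c) for s, c in zip(states, up[id(root)]) if np.isfinite(c)
        },
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _event_counts(events: Sequence[Event], merged: bool) -> dict[str, int]:
    out: dict[str, int] = {}
    for ev in events:
        key = ev.describe(merged_inv_repo=merged)
        out[key] = out.get(key, 0) + 1
    return out


def scenario_report(result: ReconstructionResult) -> dict:
    """Structured (JSON-serialisable) account of a reconstruction.

    Lists every node with its optimal state set, designated state, diploid
    number and fundamental number, and every branch with its event
    decomposition; total cost equals the sum of branch costs.
    """
    merged = result.model.inv_repo_merged
    nodes = []
    for label in sorted(
        result.node_states, key=lambda lb: (len(result.node_tips[lb]), lb)
    ):
        s = result.designated[label]
        nodes.append(
            {
                "label": label,
                "tips_below": list(result.node_tips[label]),
                "is_root": label == result.root_label,
                "state": {"m": s.m, "sm": s.sm, "st": s.st, "t": s.t},
                "haploid_n": s.n,
                "diploid_number": s.diploid_number,
                "fundamental_number": s.fundamental_number,
                "optimal_states": [
                    {"m": o.m, "sm": o.sm, "st": o.st, "t": o.t}
                    for o in result.node_states[label]
                ],
            }
        )
    branches = []
    for (parent, child), events in sorted(result.branch_events.items()):
        branches.append(
            {
                "parent": parent,
                "child": child,
                "cost": result.branch_costs[(parent, child)],
                "n_events": len(events),
                "events": _event_counts(events, merged),
            }
        )
    return {
        "total_cost": result.total_cost,
        "root": result.root_label,
        "state_space_size": result.state_space_size,
        "model": {
            "fusion_cost": result.model.fusion_cost,
            "fission_cost": result.model.fission_cost,
            "inversion_cost": result.model.inversion_cost,
            "repositioning_cost": result.model.repositioning_cost,
            "state_radius": result.model.state_radius,
            "max_n": result.model.max_n,
        },
        "notes": list(result.notes),
        "nodes": nodes,
        "branches": branches,
    }


def scenario_text(report: dict) -> str:
    """Human-readable rendering of :func:`scenario_report` output."""
    lines = []
    lines.append(f"total cost: {report['total_cost']:g}")
    lines.append(f"state space: {report['state_space_size']} candidate states")
    for note in report["notes"]:
        lines.append(f"note: {note}")
    lines.append("")
    lines.append("nodes (designated optimal labeling):")
    for nd in report["nodes"]:
        s = nd["state"]
        state_str = ", ".join(f"{k}:{v}" for k, v in s.items() if v)
        tag = " [root]" if nd["is_root"] else ""
        alt = len(nd["optimal_states"])
        lines.append(
            f"  {nd['label']:<14} 2n={nd['diploid_number']:<3} "
            f"FN={nd['fundamental_number']:<3} {{{state_str}}}"
            f"{' (+%d other optima)' % (alt - 1) if alt > 1 else ''}{tag}"
        )
    lines.append("")
    lines.append("branches:")
    for br in report["branches"]:
        if br["events"]:
            ev = "; ".join(f"{k} x{v}" for k, v in sorted(br["events"].items()))
        else:
            ev = "no events"
        lines.append(
            f"  {br['parent']} -> {br['child']:<14} cost={br['cost']:g}  {ev}"
        )
    return "\n".join(lines) + "\n"
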