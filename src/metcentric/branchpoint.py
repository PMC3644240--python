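"""Branch point analysis: condensing the active bipartite flux graph.

The analysis starts from the complete bipartite reaction graph of a flux
distribution — one node per active reaction and per active metabolite, with
an edge wherever the partial flux is above threshold, directed along the net
flux and labelled with the split ratio at the adjacent metabolite endpoint.

The graph is then condensed to the metabolic context of user-selected hub
nodes in five steps:

1. remove excluded nodes (typically H2O, H+) with their edges;
2. split each "disconnect" node (promiscuous currency metabolites) into one
   instance per incident edge;
3. iteratively bridge transitory nodes — every non-hub node with exactly
   two countable incident edges (edges to instances do not count) joining
   two distinct neighbours is replaced by a dashed edge — until a fixed
   point is reached; a transitory metabolite is one produced by a single
   reaction and consumed by a single other reaction;
4. drop nodes farther than the maximum distance from the nearest hub, with
   every edge (dashed included) counting as one hop on the bridged graph;
5. if the result is disconnected, keep only the largest connected component.

Steps 3-5 are repeated until nothing changes: pruning can leave new
transitory nodes at the cut boundary, and the condensed result must contain
only hubs, instances, and true branch points.  This also makes the
reduction idempotent.

What remains are the hubs and the metabolic branch points around them.  The
result can be exported as Graphviz DOT (green metabolite nodes annotated
with the flux sum, yellow reaction nodes, dashed bridge edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .lp import ACTIVITY_THRESHOLD, FluxDistribution
from .model import ModelError, StoichiometricModel
from .splitratio import all_flux_sums

__all__ = ["BranchGraph", "build_reaction_graph", "reduce_graph", "export_dot"]


@dataclass
class BranchGraph:
    """A (possibly condensed) bipartite flux graph.

    ``graph`` is a :class:`networkx.MultiDiGraph`.  Node attributes: ``kind``
    (``"metabolite"`` | ``"reaction"``), ``flux_sum`` or ``flux``, and for
    disconnected instances ``instance_of``.  Edge attributes: ``style``
    (``"solid"`` | ``"dashed"``), ``ratios`` (mapping metabolite endpoint →
    split ratio), ``via`` (bridged-away chain), ``directed`` (False when the
    flux direction through a bridge was ambiguous).
    """

    graph: nx.MultiDiGraph
    hubs: set[str] = field(default_factory=set)

    @property
    def metabolite_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"]

    @property
    def reaction_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "reaction"]


def build_reaction_graph(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    threshold: float = ACTIVITY_THRESHOLD,
) -> BranchGraph:
    """Bipartite graph of all reactions and metabolites active in ``v``.

    Nodes are reactions with ``|v_j| > threshold`` and metabolites with
    ``Phi_i > threshold``; an edge exists wherever ``|rho_ij| > threshold``,
    pointing reaction→metabolite when the reaction produces the metabolite
    (net-flux direction for reversible reactions running backwards).
    """
    fluxes = v.fluxes if isinstance(v, FluxDistribution) else dict(v)
    phi = all_flux_sums(model, fluxes, threshold)
    G = nx.MultiDiGraph()
    for r in model.reactions:
        vj = fluxes.get(r.id, 0.0)
        if abs(vj) <= threshold:
            continue
        G.add_node(r.id, kind="reaction", flux=vj)
        for mid, coeff in r.stoichiometry.items():
            rho = coeff * vj
            if abs(rho) <= threshold or phi[mid] <= threshold:
                continue
            if mid not in G:
                G.add_node(mid, kind="metabolite", flux_sum=phi[mid])
            ratio = abs(rho) / phi[mid]
            if rho > 0:
                G.add_edge(r.id, mid, style="solid", ratios={mid: ratio},
                           partial=rho)
            else:
                G.add_edge(mid, r.id, style="solid", ratios={mid: ratio},
                           partial=rho)
    return BranchGraph(G)


def _neighbours(G: nx.MultiDiGraph, n: str) -> set[str]:
    return set(G.predecessors(n)) | set(G.successors(n))


def _countable_edges(G: nx.MultiDiGraph, n: str):
    """Incident edges whose far endpoint is not a disconnected instance,
    as (u, v, key, data) tuples in stored direction."""
    out = []
    for u, w, k, d in list(G.in_edges(n, keys=True, data=True)) + list(
        G.out_edges(n, keys=True, data=True)
    ):
        far = u if w == n else w
        if G.nodes[far].get("instance_of") is None:
            out.append((u, w, k, d))
    return out


def _edges_between(G: nx.MultiDiGraph, a: str, b: str):
    """All edges between a and b, as (u, v, key, data) in stored direction."""
    out = []
    for u, w in ((a, b), (b, a)):
        if G.has_edge(u, w):
            for k, d in G[u][w].items():
                out.append((u, w, k, d))
    return out


def reduce_graph(
    bg: BranchGraph,
    hubs: set[str] | list[str],
    exclude: set[str] | list[str] = (),
    disconnect: set[str] | list[str] = (),
    max_distance: int | None = None,
) -> BranchGraph:
    """Condense the graph to the metabolic context of ``hubs`` (see module
    docstring for the five steps).  Raises if a hub is excluded or absent
    from the active graph."""
    hubs, exclude, disconnect = set(hubs), set(exclude), set(disconnect)
    if not hubs:
        raise ModelError("at least one hub is required")
    if hubs & exclude:
        raise ModelError(f"hub(s) {hubs & exclude} are in the exclude list")
    missing = hubs - set(bg.graph.nodes)
    if missing:
        raise ModelError(f"hub(s) {missing} not in the active graph")
    G: nx.MultiDiGraph = bg.graph.copy()

    # 1. excluded nodes vanish with their incident edges
    G.remove_nodes_from(exclude & set(G.nodes))

    # 2. split disconnect nodes into one instance per incident edge
    for node in sorted(disconnect & set(G.nodes)):
        if node in hubs:
            continue
        data = dict(G.nodes[node])
        idx = 0
        for u, w, _, d in sorted(
            list(G.in_edges(node, keys=True, data=True))
            + list(G.out_edges(node, keys=True, data=True)),
            key=lambda e: (e[0], e[1]),
        ):
            idx += 1
            inst = f"{node}@{idx}"
            G.add_node(inst, **data, instance_of=node)
            ratios = {
                (inst if k == node else k): r for k, r in d.get("ratios", {}).items()
            }
            dd = dict(d, ratios=ratios)
            if u == node:
                G.add_edge(inst, w, **dd)
            else:
                G.add_edge(u, inst, **dd)
        G.remove_node(node)

    # Steps 3-5 are iterated to a global fixed point: distance pruning and
    # component selection can expose new transitory nodes at the cut
    # boundary, and the condensed graph must not contain any.
    while True:
        before = (G.number_of_nodes(), G.number_of_edges())
        _bridge_to_fixed_point(G, hubs)
        _prune_beyond(G, hubs, max_distance)
        _keep_largest_component(G)
        if (G.number_of_nodes(), G.number_of_edges()) == before:
            break

    return BranchGraph(G, hubs & set(G.nodes))


def _bridge_to_fixed_point(G: nx.MultiDiGraph, hubs: set[str]) -> None:
    """Step 3: replace transitory nodes by dashed edges until none remain."""
    changed = True
    while changed:
        changed = False
        for node in sorted(G.nodes):
            if node in hubs or G.nodes[node].get("instance_of") is not None:
                continue
            edges = _countable_edges(G, node)
            if len(edges) != 2:
                continue
            ends = sorted(
                (e[0] if e[1] == node else e[1]) for e in edges
            )
            if ends[0] == ends[1]:  # a collapsed 2-cycle; not transitory
                continue
            u, w = ends
            eu = next(e for e in edges if u in (e[0], e[1]))
            ew = next(e for e in edges if e is not eu)
            # orient the bridge along the flux through the chain
            if eu[1] == node and ew[0] == node:  # u -> node -> w
                src, dst, directed = u, w, True
            elif ew[1] == node and eu[0] == node:  # w -> node -> u
                src, dst, directed = w, u, True
            else:
                src, dst, directed = u, w, False
            ratios = {}
            for end, (a, b, _, d) in ((u, eu), (w, ew)):
                for k, r in d.get("ratios", {}).items():
                    if k == end:
                        ratios[k] = r
            via = (
                eu[3].get("via", [])[::-1]
                + [node]
                + ew[3].get("via", [])
            )
            G.add_edge(src, dst, style="dashed", ratios=ratios, via=via,
                       directed=directed)
            # orphaned instances hanging off the bridged node vanish with it
            orphans = [
                m
                for m in _neighbours(G, node)
                if G.nodes[m].get("instance_of") is not None
                and _neighbours(G, m) == {node}
            ]
            G.remove_node(node)
            G.remove_nodes_from(orphans)
            changed = True
            break


def _prune_beyond(
    G: nx.MultiDiGraph, hubs: set[str], max_distance: int | None
) -> None:
    """Step 4: drop nodes beyond max_distance hops from the nearest hub
    (dashed edges count as one hop)."""
    if max_distance is None:
        return
    U = G.to_undirected(as_view=True)
    dist = nx.multi_source_dijkstra_path_length(
        U, hubs & set(G.nodes), weight=lambda *a: 1
    )
    keep = {n for n, d in dist.items() if d <= max_distance}
    G.remove_nodes_from(set(G.nodes) - keep)


def _keep_largest_component(G: nx.MultiDiGraph) -> None:
    """Step 5: keep only the largest connected component (ties broken by
    total flux sum, then smallest node id)."""
    comps = list(nx.connected_components(G.to_undirected(as_view=True)))
    if len(comps) <= 1:
        return

    def _key(comp):
        total_phi = sum(
            G.nodes[n].get("flux_sum", 0.0)
            for n in comp
            if G.nodes[n]["kind"] == "metabolite"
        )
        return (-len(comp), -total_phi, min(comp))

    best = min(comps, key=_key)
    G.remove_nodes_from(set(G.nodes) - best)


def _fmt_phi(x: float) -> str:
    """2-3 significant digits, the style used in rendered flux maps."""
    if x == 0:
        return "0"
    return f"{x:.3g}"


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_dot(bg: BranchGraph) -> str:
    """Render the graph as Graphviz DOT text.

    Metabolite nodes are green and carry the flux sum in the label, reaction
    nodes are yellow boxes, bridge edges are dashed, and edge labels are
    split-ratio percentages relative to the adjacent metabolite endpoint(s).
    """
    lines = ["digraph branchpoints {", "  rankdir=LR;"]
    for n in sorted(bg.graph.nodes):
        d = bg.graph.nodes[n]
        label = _dot_escape(n)
        if d["kind"] == "metabolite":
            phi = d.get("flux_sum")
            if phi is not None:
                label += f"\\n{_fmt_phi(phi)}"
            attrs = 'shape=ellipse, style=filled, fillcolor=palegreen'
        else:
            attrs = 'shape=box, style=filled, fillcolor=khaki'
        if n in bg.hubs:
            attrs += ", penwidth=3"
        lines.append(f'  "{_dot_escape(n)}" [label="{label}", {attrs}];')
    for u, w, d in sorted(
        bg.graph.edges(data=True), key=lambda e: (e[0], e[1])
    ):
        ratios = d.get("ratios", {})
        label = " | ".join(
            f"{ratios[k] * 100:.2f}%" for k in sorted(ratios)
        )
        style = d.get("style", "solid")
        extra = ', dir=none' if d.get("directed") is False else ""
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(w)}" '
            f'[label="{label}", style={style}{extra}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
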