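"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: LP optima come from
exhaustive enumeration of basic feasible solutions, partial fluxes from a
double loop over the stoichiometric matrix, and graph condensation from a
literal step-by-step re-implementation on an undirected multigraph.
"""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np


def enumerate_vertices(A_eq, b_eq, lb, ub, tol=1e-8):
    """All basic feasible solutions of {A_eq x = b_eq, lb <= x <= ub}.

    Every vertex of the polytope has n - rank(A_eq) variables at a bound;
    enumerate all choices of basic columns and bound patterns.  Only viable
    for a handful of variables with finite bounds.
    """
    A = np.asarray(A_eq, dtype=float)
    b = np.asarray(b_eq, dtype=float)
    n = A.shape[1]
    r = np.linalg.matrix_rank(A)
    vertices = []
    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        B = A[:, basic]
        if np.linalg.matrix_rank(B) < r:
            continue
        for pattern in product((0, 1), repeat=len(nonbasic)):
            x = np.zeros(n)
            for bit, j in zip(pattern, nonbasic):
                x[j] = lb[j] if bit == 0 else ub[j]
            rhs = b - A[:, nonbasic] @ x[nonbasic]
            xb, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            x[list(basic)] = xb
            if np.max(np.abs(A @ x - b)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            vertices.append(x)
    return vertices


def fba_optimum_by_enumeration(problem):
    """FBA optimum via vertex enumeration (independent of the LP solver)."""
    A_eq, b_eq = problem.equalities()
    c = problem.objective_vector()
    verts = enumerate_vertices(A_eq, b_eq, problem.lb, problem.ub)
    assert verts, "no feasible vertex found"
    vals = [c @ v for v in verts]
    return max(vals) if problem.objective_sense == "max" else min(vals)


def fva_ranges_by_enumeration(problem, opt):
    """FVA ranges at gamma = 1: per-reaction min/max over the vertices of
    the optimal face (objective pinned to its optimum as an equality)."""
    A_eq, b_eq = problem.equalities()
    c = problem.objective_vector()
    A = np.vstack([A_eq, c[None, :]])
    b = np.append(b_eq, opt)
    verts = enumerate_vertices(A, b, problem.lb, problem.ub)
    assert verts
    V = np.array(verts)
    return {
        r.id: (float(V[:, j].min()), float(V[:, j].max()))
        for j, r in enumerate(problem.model.reactions)
    }


def partial_fluxes_brute_force(model, fluxes, threshold=1e-12):
    """{metabolite: (producing dict, consuming dict)} via a double loop."""
    out = {}
    for i, met in enumerate(model.metabolites):
        prod, cons = {}, {}
        for j, rxn in enumerate(model.reactions):
            rho = model.S[i, j] * fluxes.get(rxn.id, 0.0)
            if abs(rho) <= threshold:
                continue
            (prod if rho > 0 else cons)[rxn.id] = rho
        out[met.id] = (prod, cons)
    return out


# ---------------------------------------------------------------------------
# Literal five-step graph condensation on an undirected multigraph
# ---------------------------------------------------------------------------


def reference_reduce(bg_graph, hubs, exclude, disconnect, max_distance):
    """Apply the five condensation steps literally, ignoring edge direction.

    Returns an undirected MultiGraph with the same node naming scheme for
    disconnected instances as the package (instance identity is compared
    canonically by the caller, not by name).
    """
    hubs, exclude, disconnect = set(hubs), set(exclude), set(disconnect)
    G = nx.MultiGraph()
    for n, d in bg_graph.nodes(data=True):
        G.add_node(n, **d)
    for u, w, d in bg_graph.edges(data=True):
        G.add_edge(u, w, style=d.get("style", "solid"))

    # step 1: excluded nodes vanish
    G.remove_nodes_from(exclude & set(G.nodes))

    # step 2: disconnect nodes split into one single-edge instance each
    for node in sorted(disconnect & set(G.nodes)):
        if node in hubs:
            continue
        data = dict(G.nodes[node])
        for i, (u, w, k) in enumerate(
            sorted(G.edges(node, keys=True), key=lambda e: (e[1], e[2])), 1
        ):
            inst = f"{node}#{i}"
            G.add_node(inst, **data, instance_of=node)
            G.add_edge(inst, w, **G.edges[u, w, k])
        G.remove_node(node)

    def countable_edges(n):
        return [
            (n, w, k)
            for _, w, k in G.edges(n, keys=True)
            if G.nodes[w].get("instance_of") is None
        ]

    # steps 3-5 are repeated until the graph stops changing (pruning can
    # expose new transitory nodes at the cut boundary)
    while True:
        size = (G.number_of_nodes(), G.number_of_edges())

        # step 3: bridge transitory nodes until fixed point (sorted order,
        # restart after every change)
        while True:
            for node in sorted(G.nodes):
                if node in hubs or G.nodes[node].get("instance_of") is not None:
                    continue
                ce = countable_edges(node)
                if len(ce) != 2 or ce[0][1] == ce[1][1]:
                    continue
                u, w = ce[0][1], ce[1][1]
                G.add_edge(u, w, style="dashed")
                orphans = [
                    m
                    for m in G.neighbors(node)
                    if G.nodes[m].get("instance_of") is not None
                    and set(G.neighbors(m)) == {node}
                ]
                G.remove_node(node)
                G.remove_nodes_from(orphans)
                break
            else:
                break

        # step 4: prune beyond max_distance (every edge one hop, min over hubs)
        if max_distance is not None:
            dist = nx.multi_source_dijkstra_path_length(
                G, hubs & set(G.nodes), weight=lambda *a: 1
            )
            G.remove_nodes_from(
                [n for n in list(G.nodes) if dist.get(n, np.inf) > max_distance]
            )

        # step 5: largest connected component, ties by total flux sum then id
        comps = list(nx.connected_components(G))
        if len(comps) > 1:
            best = min(
                comps,
                key=lambda comp: (
                    -len(comp),
                    -sum(
                        G.nodes[n].get("flux_sum", 0.0)
                        for n in comp
                        if G.nodes[n].get("kind") == "metabolite"
                    ),
                    min(comp),
                ),
            )
            G.remove_nodes_from(set(G.nodes) - best)
        if (G.number_of_nodes(), G.number_of_edges()) == size:
            return G


def canonical_graph(G):
    """Name-independent canonical form for comparing condensed graphs.

    Instances are identified by (parent, far endpoint); edges by their
    canonical endpoints and style, ignoring direction.
    """
    def far(n):
        out = set()
        for u, w in G.edges(n):
            out.add(u if w == n else w)
        if G.is_directed():
            for u, w in G.in_edges(n):
                out.add(u if w == n else w)
        out.discard(n)
        return {G.nodes[m].get("instance_of") or m for m in out}

    def canon(n, d):
        parent = d.get("instance_of")
        if parent is None:
            return n
        return ("instance", parent, tuple(sorted(far(n))))

    names = {n: canon(n, d) for n, d in G.nodes(data=True)}
    nodes = sorted(map(repr, names.values()))
    edges = sorted(
        repr(
            (
                *sorted((repr(names[u]), repr(names[w]))),
                d.get("style", "solid"),
            )
        )
        for u, w, d in G.edges(data=True)
    )
    return nodes, edges
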