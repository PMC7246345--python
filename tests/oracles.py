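"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, explicit graph isomorphism) without calling the corresponding
library code paths.
"""

from itertools import permutations

import networkx as nx

from enznet.chem import Molecule


def molecule_to_nx(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(
            a.index,
            element=a.element,
            charge=a.formal_charge,
            h=a.n_hydrogens,
            stereo=a.stereo.value,
        )
    for b in mol.bonds:
        g.add_edge(*b.endpoints, order=b.order.value, bstereo=b.stereo.value)
    return g


def molecules_isomorphic(m1: Molecule, m2: Molecule) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge", "h", "stereo"], [None] * 4
    )
    em = nx.algorithms.isomorphism.categorical_edge_match(
        ["order", "bstereo"], [None, None]
    )
    return nx.is_isomorphic(
        molecule_to_nx(m1), molecule_to_nx(m2), node_match=nm, edge_match=em
    )


def environment_graph(mol: Molecule, seed: int, radius: int) -> nx.Graph:
    """The rooted ball of given radius around a seed atom, BFS-enumerated."""
    dist = {seed: 0}
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            if dist[v] == radius:
                continue
            for u, _ in mol.neighbors(v):
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    g = molecule_to_nx(mol).subgraph(dist).copy()
    for v, d in dist.items():
        g.nodes[v]["dist"] = d  # distance-from-seed layering is part of identity
    return g


def environments_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge", "h", "stereo", "dist"], [None] * 5
    )
    em = nx.algorithms.isomorphism.categorical_edge_match(
        ["order", "bstereo"], [None, None]
    )
    return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


def brute_force_min_mapping_cost(reaction) -> int:
    """Exhaustive minimum bond-change count over element-respecting bijections.

    Independent of the library's search: flattens both sides, enumerates all
    per-element permutations, and counts formed/cleaved/order/stereo changes
    with a direct double loop.  Only feasible for <= ~8 heavy atoms a side.
    """
    subs = [
        (mi, a)
        for mi, m in enumerate(reaction.substrates)
        for a in m.atoms
    ]
    prods = [
        (mi, a)
        for mi, m in enumerate(reaction.products)
        for a in m.atoms
    ]
    by_el_s: dict[str, list] = {}
    by_el_p: dict[str, list] = {}
    for mi, a in subs:
        by_el_s.setdefault(a.element, []).append((mi, a.index))
    for mi, a in prods:
        by_el_p.setdefault(a.element, []).append((mi, a.index))
    assert sorted(by_el_s) == sorted(by_el_p)

    def atom(side, coord):
        mols = reaction.substrates if side == "s" else reaction.products
        return mols[coord[0]].atoms[coord[1]]

    def bonds(side):
        mols = reaction.substrates if side == "s" else reaction.products
        out = {}
        for mi, m in enumerate(mols):
            for b in m.bonds:
                key = ((mi, b.endpoints[0]), (mi, b.endpoints[1]))
                out[key] = b
        return out

    sub_bonds = bonds("s")
    prod_bonds = bonds("p")

    def cost_of(mapping: dict) -> int:
        cost = 0
        for (s1, s2), b in sub_bonds.items():
            p1, p2 = mapping[s1], mapping[s2]
            key = tuple(sorted((p1, p2)))
            pb = prod_bonds.get(key)
            if pb is None or p1[0] != p2[0]:
                cost += 1
            elif pb.order is not b.order:
                cost += 1
            else:
                st1 = b.stereo.value if b.stereo.value in ("E", "Z") else "none"
                st2 = pb.stereo.value if pb.stereo.value in ("E", "Z") else "none"
                if st1 != st2:
                    cost += 1
        inv = {p: s for s, p in mapping.items()}
        for (p1, p2), _pb in prod_bonds.items():
            s1, s2 = inv[p1], inv[p2]
            key = tuple(sorted((s1, s2)))
            if key not in sub_bonds or s1[0] != s2[0]:
                cost += 1
        for s, p in mapping.items():
            fs = atom("s", s).stereo.value
            fp = atom("p", p).stereo.value
            fs = fs if fs in ("R", "S") else "none"
            fp = fp if fp in ("R", "S") else "none"
            if fs != fp:
                cost += 1
        return cost

    elements = sorted(by_el_s)
    best = None

    def recurse(k: int, mapping: dict) -> None:
        nonlocal best
        if k == len(elements):
            c = cost_of(mapping)
            if best is None or c < best:
                best = c
            return
        el = elements[k]
        source = by_el_s[el]
        for perm in permutations(by_el_p[el]):
            mapping.update(zip(source, perm))
            recurse(k + 1, mapping)
        return

    recurse(0, {})
    return best


def brute_force_edges(pairs, threshold):
    """Double-loop threshold filter over (id1, id2, score) triples."""
    return {tuple(sorted((a, b))) for a, b, s in pairs if s >= threshold}
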