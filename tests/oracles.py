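"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — explicit path enumeration, direct
formula evaluation, exhaustive combinatorics — and shares no code with the
package under test.
"""

from itertools import combinations
from math import comb, inf


def adjacency(net):
    """Plain dict-of-sets adjacency from a ProteinNetwork."""
    adj = {n: set() for n in net.graph.nodes}
    for u, v in net.graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, src):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def all_simple_paths(adj, src, dst, max_len):
    """All simple src->dst paths up to max_len edges, by explicit DFS."""
    paths = []
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            paths.append(path)
            continue
        if len(path) > max_len:
            continue
        for w in adj[node]:
            if w not in path:
                stack.append((w, path + [w]))
    return paths


def shortest_paths(adj, src, dst):
    """All shortest src->dst paths via enumeration of simple paths."""
    dist = bfs_distances(adj, src)
    if dst not in dist:
        return []
    d = dist[dst]
    return [p for p in all_simple_paths(adj, src, dst, d) if len(p) - 1 == d]


def brute_betweenness(net, v):
    """Sum over unordered pairs of the fraction of shortest paths through v."""
    adj = adjacency(net)
    total = 0.0
    others = [n for n in adj if n != v]
    for i, j in combinations(others, 2):
        paths = shortest_paths(adj, i, j)
        if not paths:
            continue
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


def brute_closeness(net, v):
    """r / sum(d) over the r nodes reachable from v; None if isolated."""
    adj = adjacency(net)
    dist = bfs_distances(adj, v)
    del dist[v]
    if not dist:
        return None
    return len(dist) / sum(dist.values())


def brute_degree(net, v):
    return len(adjacency(net)[v])


def brute_constraint(net, v):
    """Direct evaluation of the constraint double sum with p_ij = 1/deg(i)."""
    adj = adjacency(net)
    neighbors = adj[v]
    if not neighbors:
        return None
    total = 0.0
    for j in neighbors:
        p_ij = 1.0 / len(neighbors)
        indirect = 0.0
        for q in neighbors:
            if q in (v, j):
                continue
            if j in adj[q]:
                indirect += (1.0 / len(neighbors)) * (1.0 / len(adj[q]))
        total += (p_ij + indirect) ** 2
    return total


def kn_constraint_closed_form(n):
    """Constraint of any node of the complete graph K_n: (2n-3)^2/(n-1)^3."""
    return (2 * n - 3) ** 2 / (n - 1) ** 3


def flood_fill_components(net):
    """Connected-component count by explicit flood fill."""
    adj = adjacency(net)
    seen = set()
    count = 0
    for start in adj:
        if start in seen:
            continue
        count += 1
        stack = [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u] - seen)
    return count


def bidirectional_edges(ordered_pairs):
    """Brute-force intersection of a directed relation with its transpose."""
    pairs = set(ordered_pairs)
    return {frozenset((a, b)) for a, b in pairs if (b, a) in pairs and a != b}


def fisher_two_sided(table):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > n - row1:
            return 0.0
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(col1 + 1) if prob(x) <= p_obs * (1 + 1e-9))


def brute_auc(labels, scores, positive):
    """Concordant/tied pair counting over all positive-negative pairs."""
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_tomek_links(X, y):
    """Mutual-nearest-neighbour opposite-class pairs, O(n^2) by hand."""
    n = len(X)

    def nn(i):
        best, best_d = None, inf
        for j in range(n):
            if j == i:
                continue
            d = sum((a - b) ** 2 for a, b in zip(X[i], X[j])) ** 0.5
            if d < best_d:
                best, best_d = j, d
        return best

    nns = [nn(i) for i in range(n)]
    links = set()
    for i in range(n):
        j = nns[i]
        if nns[j] == i and y[i] != y[j]:
            links.add((min(i, j), max(i, j)))
    return sorted(links)
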