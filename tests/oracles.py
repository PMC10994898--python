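"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from first principles (plain loops and
set algebra over Python objects) without touching the package's vectorized
code paths, so agreement is a meaningful cross-check.
"""

from __future__ import annotations

from collections import deque


def brute_force_rbh(sets_a: list[set], sets_b: list[set]) -> set[tuple[int, int]]:
    """Reciprocal best hits by double loop over explicit Jaccard values.

    Ties keep all tied mutual bests; zero-similarity candidates are ignored.
    """

    def jac(x: set, y: set) -> float:
        return len(x & y) / len(x | y)

    J = [[jac(a, b) for b in sets_b] for a in sets_a]
    best_a = [max(row) for row in J]
    best_b = [max(J[i][j] for i in range(len(sets_a))) for j in range(len(sets_b))]
    edges = set()
    for i in range(len(sets_a)):
        for j in range(len(sets_b)):
            if J[i][j] > 0 and J[i][j] == best_a[i] and J[i][j] == best_b[j]:
                edges.add((i, j))
    return edges


def brute_force_bfs_nodes(adjacency: dict, seeds: list, max_depth: int) -> set:
    """Nodes within max_depth hops of any seed, by plain queue BFS."""
    reached = set()
    for seed in seeds:
        dist = {seed: 0}
        queue = deque([seed])
        while queue:
            u = queue.popleft()
            if dist[u] == max_depth:
                continue
            for v in adjacency.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        reached |= set(dist)
    return reached


def brute_force_shortest_path_nodes(adjacency: dict, source, target) -> set:
    """Nodes lying on at least one shortest source->target path.

    Uses the distance identity d(s, v) + d(v, t) = d(s, t), with distances
    from two independent BFS sweeps.
    """

    def bfs(start) -> dict:
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adjacency.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist

    d_s = bfs(source)
    if target not in d_s:
        return set()
    d_t = bfs(target)
    total = d_s[target]
    return {v for v in d_s if v in d_t and d_s[v] + d_t[v] == total}


def brute_force_gene_categories(
    comorbid: set, in_a: set, in_b: set
) -> dict[str, str]:
    """Set-algebra gene labeling done gene by gene."""
    out = {}
    for g in comorbid:
        if g in in_a and g in in_b:
            out[g] = "shared"
        elif g in in_a:
            out[g] = "disease_a_specific"
        elif g in in_b:
            out[g] = "disease_b_specific"
        else:
            out[g] = "distinct"
    return out


def brute_force_gwas_labels(genes: list, set_a: set, set_b: set) -> list[str]:
    out = []
    for g in genes:
        a, b = g in set_a, g in set_b
        out.append("gwas_shared" if a and b else "gwas_a" if a else "gwas_b" if b else "none")
    return out
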