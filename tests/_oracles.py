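"""Shared brute-force oracles for graph and swarm checks."""

import itertools


def brute_force_edge_betweenness(graph) -> dict:
    """Fractional shortest-path counts by exhaustive simple-path enumeration."""
    n = graph.n_nodes
    nodes = list(range(n))
    adj = {i: [] for i in nodes}
    for i, j, w in graph.edges():
        adj[i].append(j)
        adj[j].append(i)

    def all_simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    counts: dict = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        lengths = [
            sum(1.0 / graph.weights[a, b] for a, b in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if l <= best + 1e-9]
        for p in shortest:
            for a, b in zip(p, p[1:]):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0.0) + 1.0 / len(shortest)
    n_pairs = n * (n - 1) / 2
    return {k: v / n_pairs for k, v in counts.items()}
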