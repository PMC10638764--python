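"""Independent brute-force oracles used by unit and acceptance tests."""

import itertools


def bruteforce_dual_clusters(pairs, halfwidth):
    """O(n^2) single-linkage clustering of discordant pairs.

    Edge between two pairs iff same chromosome pair AND their a-side
    seed intervals overlap AND their b-side seed intervals overlap.
    Returns sorted cluster tuples comparable with the implementation's
    (chrom_a, start_a, end_a, chrom_b, start_b, end_b, support).
    """
    hw = halfwidth
    n = len(pairs)

    def a_iv(p):
        return (p.start_a - hw, p.start_a + hw + 1)

    def b_iv(p):
        return (p.start_b - hw, p.start_b + hw + 1)

    def linked(p, q):
        if (p.chrom_a, p.chrom_b) != (q.chrom_a, q.chrom_b):
            return False
        pa, qa = a_iv(p), a_iv(q)
        pb, qb = b_iv(p), b_iv(q)
        return pa[0] < qa[1] and qa[0] < pa[1] and pb[0] < qb[1] and qb[0] < pb[1]

    adjacency = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if linked(pairs[i], pairs[j]):
            adjacency[i].add(j)
            adjacency[j].add(i)

    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, component = [i], set()
        while stack:
            k = stack.pop()
            if k in component:
                continue
            component.add(k)
            stack.extend(adjacency[k] - component)
        seen |= component
        members = [pairs[k] for k in component]
        clusters.append(
            (
                members[0].chrom_a,
                min(a_iv(p)[0] for p in members),
                max(a_iv(p)[1] for p in members),
                members[0].chrom_b,
                min(b_iv(p)[0] for p in members),
                max(b_iv(p)[1] for p in members),
                len(members),
            )
        )
    return sorted(clusters)


def bruteforce_simple_cycles(graph):
    """All simple cycles (length >= 3) of an undirected networkx graph,
    as a set of rotation/reflection-canonical node tuples. Exhaustive
    DFS over simple paths; fine for <= 8 nodes."""
    cycles = set()

    def canonical(nodes):
        best = None
        for seq in (list(nodes), list(nodes)[::-1]):
            for i in range(len(seq)):
                rot = tuple(seq[i:] + seq[:i])
                if best is None or rot < best:
                    best = rot
        return best

    def dfs(path):
        head = path[-1]
        for nxt in graph.neighbors(head):
            if nxt == path[0] and len(path) >= 3:
                cycles.add(canonical(path))
            elif nxt not in path:
                dfs(path + [nxt])

    for start in graph.nodes:
        dfs([start])
    return cycles
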