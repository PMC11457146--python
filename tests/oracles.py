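"""Independent reference implementations used only to check the package.

Everything here is deliberately written without importing alkatherm
internals: labelled-tree enumeration via Pruefer sequences, an iterative
tree-isomorphism certificate, and brute-force path/pair counters.  These are
the oracles the enumeration and interaction modules are compared against.
"""

from __future__ import annotations

from itertools import product


def prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence (length n-2) into the edges of a labelled tree."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    seq_iter = list(seq)
    import heapq

    heap = leaves[:]
    heapq.heapify(heap)
    for v in seq_iter:
        leaf = heapq.heappop(heap)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(heap, v)
    u, w = heapq.heappop(heap), heapq.heappop(heap)
    edges.append((u, w))
    return edges


def tree_certificate(edges: list[tuple[int, int]], n: int) -> str:
    """Canonical certificate of an unlabelled free tree (centroid + AHU).

    Independent re-derivation used to bucket labelled trees into isomorphism
    classes without quadratic pairwise isomorphism tests.
    """
    if n == 1:
        return "()"
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    # find centroid(s) by leaf stripping
    deg = [len(a) for a in adj]
    layer = [i for i in range(n) if deg[i] == 1]
    remaining = n
    removed = [False] * n
    while remaining > 2:
        remaining -= len(layer)
        nxt = []
        for leaf in layer:
            removed[leaf] = True
            for w in adj[leaf]:
                if not removed[w]:
                    deg[w] -= 1
                    if deg[w] == 1:
                        nxt.append(w)
        layer = nxt

    def rooted(v: int, parent: int) -> str:
        subs = sorted(rooted(w, v) for w in adj[v] if w != parent)
        return "(" + "".join(subs) + ")"

    return min(rooted(c, -1) for c in layer)


def count_alkane_isomers_brute(n: int) -> int:
    """Number of degree-<=4 free trees on n vertices by exhaustive Pruefer
    enumeration (practical for n <= 8)."""
    if n == 1:
        return 1
    if n == 2:
        return 1
    certs = set()
    for seq in product(range(n), repeat=n - 2):
        # degree of v in the tree is 1 + multiplicity in the sequence
        if max(seq.count(v) for v in set(seq)) > 3:
            continue
        edges = prufer_to_edges(seq, n)
        certs.add(tree_certificate(edges, n))
    return len(certs)


def count_paths_of_length(edges: list[tuple[int, int]], n: int, k: int) -> int:
    """Simple paths with k edges, counted by brute force over vertex tuples."""
    adj = [set() for _ in range(n)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    count = 0
    for tup in product(range(n), repeat=k + 1):
        if len(set(tup)) != k + 1:
            continue
        if all(tup[i + 1] in adj[tup[i]] for i in range(k)):
            count += 1
    return count // 2  # each path counted in both directions


def pairs_at_distance_at_least(
    edges: list[tuple[int, int]], n: int, min_dist: int
) -> int:
    """Unordered vertex pairs with graph distance >= min_dist (BFS oracle)."""
    from collections import deque

    adj = [set() for _ in range(n)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    total = 0
    for s in range(n):
        dist = {s: 0}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    q.append(w)
        total += sum(1 for t in range(s + 1, n) if dist[t] >= min_dist)
    return total


def random_alkane_tree(rng, n: int) -> list[tuple[int, int]]:
    """Random labelled tree with max degree 4 by degree-capped attachment."""
    edges = []
    degree = [0] * n
    for v in range(1, n):
        candidates = [u for u in range(v) if degree[u] < 4]
        u = candidates[rng.integers(len(candidates))]
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    return edges
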