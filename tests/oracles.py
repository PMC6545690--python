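"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the overlap
aligner is checked against exhaustive suffix/prefix enumeration with a
plain Needleman-Wunsch scorer, and Louvain against exhaustive modularity
maximization over every partition of a small node set.
"""

from itertools import product


def nw_score(a, b, match, mismatch, gap):
    """Plain global alignment score (linear gaps)."""
    prev = [j * gap for j in range(len(b) + 1)]
    for i in range(1, len(a) + 1):
        cur = [i * gap] + [0.0] * len(b)
        for j in range(1, len(b) + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[-1]


def overlap_score_brute(a, b, match=1.0, mismatch=-1.0, gap=-3.0):
    """Max over every suffix-of-one vs prefix-of-the-other global
    alignment, and the empty overlap."""
    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, nw_score(a[i:], b[:j], match, mismatch, gap))
    for i in range(len(b) + 1):
        for j in range(len(a) + 1):
            best = max(best, nw_score(b[i:], a[:j], match, mismatch, gap))
    return best


def all_strings(alphabet, max_len):
    for n in range(1, max_len + 1):
        for tup in product(alphabet, repeat=n):
            yield "".join(tup)


def all_partitions(items):
    """Every partition of a list, via restricted-growth enumeration."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_modularity_partition(nodes, edges):
    """Exhaustive weighted-modularity maximization.

    edges: {(u, v): weight}.  Returns (best modularity, partition as a
    sorted list of sorted node lists).
    """
    nodes = sorted(nodes)
    w = {}
    deg = {u: 0.0 for u in nodes}
    two_m = 0.0
    for (u, v), wt in edges.items():
        w[frozenset((u, v))] = wt
        deg[u] += wt
        deg[v] += wt
        two_m += 2 * wt

    def modularity(part):
        q = 0.0
        for block in part:
            for i, u in enumerate(block):
                for v in block[i + 1 :]:
                    q += 2 * w.get(frozenset((u, v)), 0.0)
                q += 2 * w.get(frozenset((u, u)), 0.0)
            s = sum(deg[u] for u in block)
            q -= s * s / two_m
        return q / two_m

    best_q, best_p = float("-inf"), None
    for part in all_partitions(nodes):
        q = modularity(part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, sorted(sorted(b) for b in best_p)
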