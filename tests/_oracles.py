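"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own code paths: the MSN oracle
enumerates every labelled spanning tree via Pruefer sequences, and the
island oracle counts every window naively with string operations.
"""

import heapq
import itertools


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_force_msn(haps):
    """Union of all minimum spanning trees over distinct haplotypes."""
    haps = sorted(set(haps))
    n = len(haps)
    if n == 1:
        return set()
    if n == 2:
        return {(haps[0], haps[1])}
    D = [[hamming(a, b) for b in haps] for a in haps]
    best = None
    best_edges = set()
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Pruefer sequence into its unique labelled tree
        deg = [1] * n
        for x in seq:
            deg[x] += 1
        edges = []
        heap = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(heap)
        for x in seq:
            leaf = heapq.heappop(heap)
            edges.append((min(leaf, x), max(leaf, x)))
            deg[x] -= 1
            if deg[x] == 1:
                heapq.heappush(heap, x)
        a = heapq.heappop(heap)
        b = heapq.heappop(heap)
        edges.append((min(a, b), max(a, b)))
        w = sum(D[i][j] for i, j in edges)
        if best is None or w < best:
            best, best_edges = w, set(edges)
        elif w == best:
            best_edges |= set(edges)
    return {(haps[i], haps[j]) for i, j in best_edges}


def brute_force_islands(seq, min_len=200, gc_min=0.50, oe_min=0.60):
    """All-windows island reference: naive counting, merge, then trim."""

    def ok(s, e):
        win = seq[s:e]
        n_c, n_g = win.count("C"), win.count("G")
        if (n_c + n_g) / len(win) <= gc_min:
            return False
        exp = n_c * n_g / len(win)
        if exp == 0:
            return False
        n_cpg = sum(1 for i in range(len(win) - 1) if win[i : i + 2] == "CG")
        return n_cpg / exp > oe_min

    starts = [s for s in range(len(seq) - min_len + 1) if ok(s, s + min_len)]
    merged = []
    for s in starts:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = s + min_len
        else:
            merged.append([s, s + min_len])
    out = []
    for s, e in merged:
        while e - s >= min_len and not ok(s, e):
            e -= 1
        if e - s >= min_len:
            out.append((s, e))
    return out


def random_island_construct(rng, max_len=1000):
    """A mosaic of AT-rich, uniform and CpG-enriched blocks."""
    blocks = []
    for _ in range(rng.integers(2, 6)):
        kind = rng.integers(0, 3)
        n = int(rng.integers(50, 250))
        if kind == 0:
            blocks.append("".join(rng.choice(list("ATAT") + ["C", "G"], size=n)))
        elif kind == 1:
            blocks.append("".join(rng.choice(list("ACGT"), size=n)))
        else:
            blocks.append("CG" * (n // 2))
    return "".join(blocks)[:max_len]
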