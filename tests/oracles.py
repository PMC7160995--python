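"""Independent oracles used by the test suite.

These deliberately avoid the library's own algorithms: reversal distances
come from breadth-first search over the reversal Cayley graph, repeat
families from a naive exact-extension scan, and expected statistics from
closed forms or direct resampling.
"""

from collections import deque


def bfs_reversal_table(n: int) -> dict:
    """Exact reversal distance for every signed permutation of size n (BFS)."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    dq = deque([ident])
    while dq:
        p = dq.popleft()
        d = dist[p]
        for i in range(n):
            for j in range(i, n):
                q = p[:i] + tuple(-x for x in reversed(p[i : j + 1])) + p[j + 1 :]
                if q not in dist:
                    dist[q] = d + 1
                    dq.append(q)
    return dist


def brute_force_repeat_pairs(seq: str, min_len: int) -> set:
    """Maximal exact repeated pairs >= min_len in a linear sequence.

    Naive: seed every k-mer pair (k = min_len), extend exactly left/right,
    record maximal (startA, startB, length, strand).  Suitable only for
    tiny genomes.
    """
    from mitovar.genome import revcomp

    k = min_len
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    def extend(a, b, strand):
        if strand == "+":
            while a > 0 and b > 0 and seq[a - 1] == seq[b - 1]:
                a -= 1
                b -= 1
            ln = k
            while a + ln < len(seq) and b + ln < len(seq) and seq[a + ln] == seq[b + ln]:
                ln += 1
            ln = min(ln, b - a) if b > a else ln  # avoid self-overlap runaway
            return a, b, ln
        return a, b, k

    pairs = set()
    for positions in index.values():
        for x in positions:
            for y in positions:
                if y <= x:
                    continue
                a, b, ln = extend(x, y, "+")
                pairs.add((a, b, ln, "+"))
    rc = revcomp(seq)
    n = len(seq)
    for i in range(len(rc) - k + 1):
        km = rc[i : i + k]
        if km in index:
            for x in index[km]:
                # rc window i..i+k maps to forward window n-i-k..n-i
                b = n - i - k
                if b == x:
                    continue
                a, bb = min(x, b), max(x, b)
                # exact inverted extension
                ln = k
                while (
                    a + ln < len(seq)
                    and bb > 0
                    and a + ln < bb
                    and seq[a + ln] == revcomp(seq[bb - 1])
                ):
                    ln += 1
                    bb -= 1
                pairs.add((a, bb, ln, "-"))
    # keep only maximal pairs (drop ones contained in a longer same-strand pair)
    maximal = set()
    for a, b, ln, s in pairs:
        contained = any(
            s == s2 and a >= a2 and b >= b2 and a + ln <= a2 + ln2 and b + ln <= b2 + ln2
            and (a, b, ln) != (a2, b2, ln2)
            for a2, b2, ln2, s2 in pairs
        )
        if not contained:
            maximal.add((a, b, ln, s))
    return maximal


def binomial_ci_halfwidth(p: float, n: int, z: float = 1.96) -> float:
    return z * (p * (1 - p) / n) ** 0.5
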