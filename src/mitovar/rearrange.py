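"""Genome rearrangement: synteny blocks, reversal distance, events, HRBs.

The comparison of a derived mitogenome against its maternal parent runs in
four stages:

1. **Synteny blocks** — maximal collinear chains of unique exact anchor
   matches (>= 30 bp, unique in both genomes counting both strands), merged
   along diagonals, boundary-extended by direct base comparison, trimmed of
   mutual overlaps and filtered to a minimum block length (default 500 bp,
   the locally-collinear-block cutoff conventional for organelle
   comparisons).
2. **Signed permutation** — blocks numbered 1..n by their order in genome
   A; genome B is then an ordered list of signed block ids per scaffold.
3. **Reversal distance / scenario** — the exact Hannenhalli–Pevzner
   distance d = (n+1) − c + h + f on the breakpoint graph (c cycles,
   h hurdles, f fortress), and a minimal reversal scenario found by
   greedily applying distance-reducing reversals (deterministic
   tie-break: smallest left endpoint).
4. **Events, HRBs and mechanism** — reversal / translocation /
   fusion / fission tallies from strip structure and scaffold counts;
   homologous-region boundaries (HRBs) are interior block edges in genome
   A; an event is attributed to repeat-mediated recombination iff all its
   usable boundaries lie within a window (default 50 bp) of a repeat copy,
   and to non-homologous end joining (NHEJ) otherwise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .genome import AnnotatedGenome
from .repeats import RepeatFamily

__all__ = [
    "SyntenyBlock",
    "SignedPermutation",
    "HRB",
    "RearrangementEvent",
    "RearrangementScenario",
    "build_synteny_blocks",
    "blocks_to_signed_permutation",
    "reversal_distance",
    "sort_by_reversals",
    "apply_reversal",
    "classify_events",
    "extract_hrbs",
    "hrb_repeat_proximity",
    "attribute_mechanism",
]


# --------------------------------------------------------------------------
# data types


@dataclass
class SyntenyBlock:
    block_id: int
    scaffold_a: str
    start_a: int
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    sign: int  # +1 / -1: orientation of the B interval relative to A

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


@dataclass
class SignedPermutation:
    """Order of genome-A block ids (signed) along each genome-B scaffold."""

    scaffolds: dict[str, list[int]]

    @property
    def flat(self) -> list[int]:
        return [x for order in self.scaffolds.values() for x in order]

    @property
    def n_blocks(self) -> int:
        return len(self.flat)


@dataclass(frozen=True)
class HRB:
    """Homologous-region boundary: a block edge in genome-A coordinates."""

    scaffold: str
    position: int
    at_scaffold_end: bool


@dataclass
class RearrangementEvent:
    kind: str  # reversal | translocation | fusion | fission
    block_ids: tuple[int, ...]
    boundaries: tuple[HRB, ...] = ()
    mechanism: str | None = None  # filled by attribute_mechanism


@dataclass
class RearrangementScenario:
    events: list  # reversal steps (i, j) or RearrangementEvent list
    distance: int


# --------------------------------------------------------------------------
# Hannenhalli–Pevzner reversal distance (breakpoint graph)


def _breakpoint_graph(perm: tuple[int, ...]):
    """Cycles and gray-edge geometry of the breakpoint graph of ``perm``.

    The permutation is framed with 0 and 2n+1; each signed element x maps
    to the ordered endpoint pair (2x-1, 2x), negated elements to (2x,
    2x-1).  Black edges join consecutive endpoints across gaps, gray edges
    join 2i and 2i+1.  Returns (cycles, pos) where cycles are lists of
    endpoint values and pos maps endpoint -> index in the framed sequence.
    """
    n = len(perm)
    seq = [0]
    for x in perm:
        seq += [2 * x - 1, 2 * x] if x > 0 else [-2 * x, -2 * x - 1]
    seq.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(seq)}

    black = {}  # endpoint -> endpoint across a gap
    for i in range(0, 2 * n + 2, 2):
        black[seq[i]] = seq[i + 1]
        black[seq[i + 1]] = seq[i]
    gray = {}
    for i in range(0, 2 * n + 2, 2):
        gray[i] = i + 1
        gray[i + 1] = i

    seen = set()
    cycles = []
    for start in seq:
        if start in seen:
            continue
        cyc = []
        v, on_black = start, True
        while True:
            cyc.append(v)
            seen.add(v)
            v = black[v] if on_black else gray[v]
            on_black = not on_black
            if v == start and on_black:
                break
        cycles.append(cyc)
    return cycles, pos


def _components(perm: tuple[int, ...]):
    """Unoriented components of the breakpoint graph.

    Returns a list of (span_lo, span_hi, oriented) for every non-trivial
    component (a trivial cycle is a 2-endpoint adjacency and belongs to no
    component).  Two cycles are in the same component iff any of their gray
    edges interleave on the framed sequence; a component is oriented iff it
    contains an oriented gray edge (endpoints at positions of equal
    parity-sum, i.e. pos(2i) + pos(2i+1) even).
    """
    cycles, pos = _breakpoint_graph(perm)
    nontrivial = [c for c in cycles if len(c) > 2]
    if not nontrivial:
        return []

    edges_of = []  # per cycle: list of gray edges as (lo, hi) positions
    oriented_of = []
    for cyc in nontrivial:
        edges = []
        oriented = False
        for v in cyc:
            w = v + 1 if v % 2 == 0 else v - 1  # gray partner
            p, q = pos[v], pos[w]
            if p < q:
                edges.append((p, q))
                if (p + q) % 2 == 0:
                    oriented = True
        edges_of.append(edges)
        oriented_of.append(oriented)

    k = len(nontrivial)
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def cross(e, f):
        return e[0] < f[0] < e[1] < f[1] or f[0] < e[0] < f[1] < e[1]

    for i in range(k):
        for j in range(i + 1, k):
            if find(i) != find(j) and any(
                cross(e, f) for e in edges_of[i] for f in edges_of[j]
            ):
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(k):
        comps.setdefault(find(i), []).append(i)

    out = []
    for members in comps.values():
        lo = min(e[0] for m in members for e in edges_of[m])
        hi = max(e[1] for m in members for e in edges_of[m])
        oriented = any(oriented_of[m] for m in members)
        out.append((lo, hi, oriented))
    return out


def _hurdles(spans: list[tuple[int, int]]) -> list[int]:
    """Indices of hurdles among unoriented component spans.

    Component spans nest or are disjoint.  A hurdle is a *minimal*
    unoriented component (containing no other) or the *greatest* one
    (strictly containing every other unoriented component).
    """

    def contains(outer, inner):
        return outer[0] <= inner[0] and inner[1] <= outer[1] and outer != inner

    hurdles = []
    for i, s in enumerate(spans):
        others = [t for j, t in enumerate(spans) if j != i]
        if not any(contains(s, t) for t in others):
            hurdles.append(i)  # minimal
        elif all(contains(s, t) for t in others):
            hurdles.append(i)  # greatest, contains all others
    return hurdles


def _hurdle_fortress(perm: tuple[int, ...]) -> tuple[int, int]:
    comps = _components(perm)
    spans = [(lo, hi) for lo, hi, oriented in comps if not oriented]
    if not spans:
        return 0, 0
    hs = _hurdles(spans)
    h = len(hs)
    if h % 2 == 0:
        return h, 0
    # fortress iff every hurdle is a superhurdle: removing it does not
    # reduce the hurdle count (its guardian component becomes a new hurdle)
    for i in hs:
        remaining = [s for j, s in enumerate(spans) if j != i]
        if len(_hurdles(remaining)) < h:
            return h, 0
    return h, 1


def reversal_distance(perm) -> int:
    """Exact signed reversal distance d = (n+1) − c + h + f.

    ``perm`` is a single-scaffold signed permutation (sequence of distinct
    signed ints with magnitudes 1..n) or a :class:`SignedPermutation` with
    one scaffold.
    """
    p = _as_tuple(perm)
    n = len(p)
    if n == 0:
        return 0
    cycles, _ = _breakpoint_graph(p)
    c = len(cycles)
    h, f = _hurdle_fortress(p)
    return (n + 1) - c + h + f


def _as_tuple(perm) -> tuple[int, ...]:
    if isinstance(perm, SignedPermutation):
        if len(perm.scaffolds) != 1:
            raise ValueError("reversal distance is defined per scaffold")
        p = tuple(next(iter(perm.scaffolds.values())))
    else:
        p = tuple(perm)
    mags = sorted(abs(x) for x in p)
    if mags != list(range(1, len(p) + 1)):
        raise ValueError(f"not a signed permutation of 1..n: {p}")
    return p


def apply_reversal(perm: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse (and negate) the segment at 0-based positions i..j inclusive."""
    return perm[:i] + tuple(-x for x in reversed(perm[i : j + 1])) + perm[j + 1 :]


def sort_by_reversals(perm) -> RearrangementScenario:
    """A minimal reversal scenario transforming ``perm`` into identity.

    At every step all candidate reversals are scanned in order of (left
    endpoint, right endpoint) and the first one that decreases the exact
    distance is applied, so the output is deterministic and has exactly
    ``reversal_distance(perm)`` steps.
    """
    p = _as_tuple(perm)
    steps: list[tuple[int, int]] = []
    d = reversal_distance(p)
    while d > 0:
        found = False
        for i in range(len(p)):
            for j in range(i, len(p)):
                q = apply_reversal(p, i, j)
                if reversal_distance(q) == d - 1:
                    steps.append((i, j))
                    p, d = q, d - 1
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - contradicts HP theory
            raise RuntimeError("no distance-reducing reversal found")
    return RearrangementScenario(events=steps, distance=len(steps))


# --------------------------------------------------------------------------
# synteny blocks


def _unique_kmer_positions(genome: AnnotatedGenome, k: int) -> dict[str, tuple[str, int]]:
    """k-mers occurring exactly once genome-wide, counting both strands."""
    from .genome import revcomp

    counts: dict[str, int] = {}
    first: dict[str, tuple[str, int]] = {}
    for name, sc in genome.scaffolds.items():
        seq = sc.seq
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            counts[km] = counts.get(km, 0) + 1
            if km not in first:
                first[km] = (name, i)
        rc = revcomp(seq)
        for i in range(len(rc) - k + 1):
            km = rc[i : i + k]
            counts[km] = counts.get(km, 0) + 1
    # a strand-symmetric k-mer can never reach count 1, so forward-unique
    # k-mers here are unique over both strands of all scaffolds
    return {km: first[km] for km, c in counts.items() if c == 1 and km in first}


def build_synteny_blocks(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    min_block: int = 500,
    anchor_k: int = 30,
    max_gap: int = 5000,
    diag_tol: int = 30,
) -> list[SyntenyBlock]:
    """Homologous blocks between two genomes (treated as linear scaffolds).

    Anchors are ``anchor_k``-mers unique in both genomes (both strands
    counted); anchors sharing a strand and diagonal (within ``diag_tol``,
    gaps up to ``max_gap``) are chained, chain boundaries are extended by
    direct base comparison, overlaps between neighbouring blocks are split
    at the midpoint, and blocks shorter than ``min_block`` are dropped.
    """
    from .genome import revcomp

    blocks: list[SyntenyBlock] = []
    ua = _unique_kmer_positions(genome_a, anchor_k)
    ub = _unique_kmer_positions(genome_b, anchor_k)

    per_pair: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for km, (nb, bpos) in ub.items():
        hit = ua.get(km)
        strand = "+"
        if hit is None:
            hit = ua.get(revcomp(km))
            strand = "-"
        if hit is not None:
            na, apos = hit
            per_pair.setdefault((na, nb), []).append((apos, bpos, strand))

    for (na, nb), anchors in per_pair.items():
        sa, sb = genome_a.scaffolds[na], genome_b.scaffolds[nb]
        anchors.sort()
        chains = _chain_anchors(anchors, anchor_k, max_gap, diag_tol)
        for (a0, a1, b0, b1, strand) in chains:
            a0, a1, b0, b1 = _extend_chain(sa.seq, sb.seq, a0, a1, b0, b1, strand)
            blocks.append(
                SyntenyBlock(0, na, a0, a1, nb, b0, b1, +1 if strand == "+" else -1)
            )

    _trim_overlaps(blocks, axis="a")
    _trim_overlaps(blocks, axis="b")
    blocks = [b for b in blocks if b.length >= min_block and (b.end_b - b.start_b) >= min_block]
    blocks.sort(key=lambda b: (b.scaffold_a, b.start_a))
    for i, b in enumerate(blocks):
        b.block_id = i + 1
    return blocks


def _chain_anchors(anchors, k, max_gap, diag_tol):
    """Group anchors into collinear chains; returns (a0, a1, b0, b1, strand)."""
    chains = []  # open chains: [a_last, b_last, diag, strand, a0, b_min, b_max]
    done = []
    for a, b, strand in anchors:
        diag = a - b if strand == "+" else a + b
        placed = False
        for ch in chains:
            if (
                ch[3] == strand
                and abs(diag - ch[2]) <= diag_tol
                and a - ch[0] <= max_gap
            ):
                ch[0], ch[1] = a, b
                ch[5], ch[6] = min(ch[5], b), max(ch[6], b)
                placed = True
                break
        if not placed:
            chains.append([a, b, diag, strand, a, b, b])
        # retire chains too far behind to ever extend (keeps the scan linear)
        still = []
        for ch in chains:
            if a - ch[0] > max_gap:
                done.append(ch)
            else:
                still.append(ch)
        chains = still
    done.extend(chains)
    out = []
    for a_last, b_last, diag, strand, a0, b_min, b_max in done:
        out.append((a0, a_last + k, b_min, b_max + k, strand))
    return out


def _extend_chain(seq_a, seq_b, a0, a1, b0, b1, strand):
    """Extend chain boundaries base-by-base while the sequences agree."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    la, lb = len(seq_a), len(seq_b)
    if strand == "+":
        while a0 > 0 and b0 > 0 and seq_a[a0 - 1] == seq_b[b0 - 1]:
            a0 -= 1
            b0 -= 1
        while a1 < la and b1 < lb and seq_a[a1] == seq_b[b1]:
            a1 += 1
            b1 += 1
    else:
        # A left end pairs with B right end
        while a0 > 0 and b1 < lb and seq_a[a0 - 1] == comp[seq_b[b1]]:
            a0 -= 1
            b1 += 1
        while a1 < la and b0 > 0 and seq_a[a1] == comp[seq_b[b0 - 1]]:
            a1 += 1
            b0 -= 1
    return a0, a1, b0, b1


def _trim_overlaps(blocks: list[SyntenyBlock], axis: str) -> None:
    """Split overlap between neighbouring blocks at the midpoint (in place)."""
    if axis == "a":
        key = lambda b: (b.scaffold_a, b.start_a)
    else:
        key = lambda b: (b.scaffold_b, b.start_b)
    blocks.sort(key=key)
    for prev, cur in zip(blocks, blocks[1:]):
        if axis == "a":
            if prev.scaffold_a != cur.scaffold_a:
                continue
            over = prev.end_a - cur.start_a
            if over > 0:
                cut = over // 2
                _shrink(prev, "right_a", over - cut)
                _shrink(cur, "left_a", cut)
        else:
            if prev.scaffold_b != cur.scaffold_b:
                continue
            over = prev.end_b - cur.start_b
            if over > 0:
                cut = over // 2
                _shrink(prev, "right_b", over - cut)
                _shrink(cur, "left_b", cut)


def _shrink(b: SyntenyBlock, side: str, amount: int) -> None:
    """Trim ``amount`` bases off one side of a block, keeping A/B consistent."""
    if amount <= 0:
        return
    if side == "right_a":
        b.end_a -= amount
        if b.sign == +1:
            b.end_b -= amount
        else:
            b.start_b += amount
    elif side == "left_a":
        b.start_a += amount
        if b.sign == +1:
            b.start_b += amount
        else:
            b.end_b -= amount
    elif side == "right_b":
        b.end_b -= amount
        if b.sign == +1:
            b.end_a -= amount
        else:
            b.start_a += amount
    elif side == "left_b":
        b.start_b += amount
        if b.sign == +1:
            b.start_a += amount
        else:
            b.end_a -= amount


def blocks_to_signed_permutation(blocks: list[SyntenyBlock]) -> SignedPermutation:
    """Number blocks by A order; list B order with signs per B scaffold."""
    in_a = sorted(blocks, key=lambda b: (b.scaffold_a, b.start_a))
    for prev, cur in zip(in_a, in_a[1:]):
        if prev.scaffold_a == cur.scaffold_a and prev.end_a > cur.start_a:
            raise ValueError("overlapping blocks in genome A")
    ids = {id(b): i + 1 for i, b in enumerate(in_a)}
    in_b = sorted(blocks, key=lambda b: (b.scaffold_b, b.start_b))
    for prev, cur in zip(in_b, in_b[1:]):
        if prev.scaffold_b == cur.scaffold_b and prev.end_b > cur.start_b:
            raise ValueError("overlapping blocks in genome B")
    scaffolds: dict[str, list[int]] = {}
    for b in in_b:
        scaffolds.setdefault(b.scaffold_b, []).append(ids[id(b)] * b.sign)
    return SignedPermutation(scaffolds=scaffolds)


# --------------------------------------------------------------------------
# event classification (strip analysis)


def _strips(order: list[int]) -> list[list[int]]:
    """Maximal strips: runs +i,+(i+1),... or −i,−(i−1),... (consecutive ids)."""
    strips: list[list[int]] = []
    for x in order:
        if strips:
            last = strips[-1][-1]
            if x == last + 1 and x > 0 and last > 0:
                strips[-1].append(x)
                continue
            if x == last + 1 and x < 0 and last < 0:
                strips[-1].append(x)
                continue
        strips.append([x])
    return strips


def _lis_length(seq: list[int]) -> int:
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def classify_events(
    blocks: list[SyntenyBlock],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    end_tol: int = 50,
) -> tuple[dict[str, int], list[RearrangementEvent]]:
    """Tally rearrangement events and attach their boundary coordinates.

    Scaffold-count changes give fusion/fission counts.  Within the
    concatenated B order (scaffolds ordered by their A content), maximal
    negative strips are reversals and displaced strips (those outside a
    longest increasing subsequence of strip order) are translocations.
    For well-separated events this equals the multichromosomal minimum
    event count; heavily overlapping events may be summarised more
    coarsely (see the methods note).

    Returns ({kind: count}, [RearrangementEvent with A-coordinate
    boundaries for reversal/translocation/fission]).
    """
    perm = blocks_to_signed_permutation(blocks)
    by_id = {b.block_id: b for b in blocks}

    tally = {"reversal": 0, "translocation": 0, "fusion": 0, "fission": 0}
    events: list[RearrangementEvent] = []

    n_a = len(genome_a.scaffolds)
    n_b = len(genome_b.scaffolds)
    tally["fission"] = max(0, n_b - n_a)
    tally["fusion"] = max(0, n_a - n_b)

    def a_edge_hrb(coord: int, scaffold: str) -> HRB:
        L = len(genome_a.scaffolds[scaffold])
        return HRB(scaffold, coord, coord <= end_tol or coord >= L - end_tol)

    # fission boundaries: B-scaffold extremities mapping to A interior
    if tally["fission"]:
        cut_coords = []
        for sb, order in perm.scaffolds.items():
            for end_id in (order[0], order[-1]):
                blk = by_id[abs(end_id)]
                is_left_end = end_id == order[0]
                # which A coordinate is exposed at this B scaffold end?
                if (end_id > 0) == is_left_end:
                    coord = blk.start_a
                else:
                    coord = blk.end_a
                hrb = a_edge_hrb(coord, blk.scaffold_a)
                if not hrb.at_scaffold_end:
                    cut_coords.append(hrb)
        # one cut exposes two ends at ~the same A coordinate: merge
        cut_coords.sort(key=lambda h: (h.scaffold, h.position))
        merged: list[list[HRB]] = []
        for h in cut_coords:
            if (
                merged
                and merged[-1][-1].scaffold == h.scaffold
                and h.position - merged[-1][-1].position <= 2 * end_tol
            ):
                merged[-1].append(h)
            else:
                merged.append([h])
        for group in merged[: tally["fission"]]:
            events.append(
                RearrangementEvent("fission", (), tuple(group))
            )
        # pad if merging was too aggressive
        while sum(1 for e in events if e.kind == "fission") < tally["fission"]:
            events.append(RearrangementEvent("fission", (), ()))

    # order B scaffolds by their bulk A content (median block start — robust
    # to the occasional translocated block), then analyse strips
    def _median_start(order):
        starts = sorted(by_id[abs(x)].start_a for x in order)
        return starts[len(starts) // 2]

    scaffold_orders = sorted(perm.scaffolds.values(), key=_median_start)
    flat = [x for order in scaffold_orders for x in order]
    strips = _strips(flat)

    def strip_interval(strip: list[int]):
        bs = [by_id[abs(x)] for x in strip]
        scaffold = bs[0].scaffold_a
        return scaffold, min(b.start_a for b in bs), max(b.end_a for b in bs)

    # reversals: negative strips
    rev_strip_idx = [i for i, s in enumerate(strips) if s[0] < 0]
    for i in rev_strip_idx:
        scaffold, lo, hi = strip_interval(strips[i])
        boundaries = (a_edge_hrb(lo, scaffold), a_edge_hrb(hi, scaffold))
        events.append(
            RearrangementEvent(
                "reversal", tuple(abs(x) for x in strips[i]), boundaries
            )
        )
    tally["reversal"] = len(rev_strip_idx)

    # translocations: after conceptually undoing reversals in place (strips
    # whose ids continue their neighbour merge back), strips outside a
    # longest increasing subsequence are the displaced segments
    merged_keys: list[list[int]] = []
    for s in strips:
        ids = sorted(abs(x) for x in s)
        if merged_keys and ids[0] == merged_keys[-1][-1] + 1:
            merged_keys[-1] = merged_keys[-1] + ids
        else:
            merged_keys.append(ids)
    seq_keys = [ids[0] for ids in merged_keys]
    lis = _lis_length(seq_keys)
    n_trans = len(merged_keys) - lis if len(merged_keys) > 1 else 0
    tally["translocation"] = n_trans

    if n_trans:
        moved = _displaced_strips(merged_keys)
        for ids in moved:
            bs = [by_id[i] for i in ids]
            scaffold = bs[0].scaffold_a
            lo = min(b.start_a for b in bs)
            hi = max(b.end_a for b in bs)
            # insertion point: facing edge of the B-neighbouring block
            ins = _insertion_edge(flat, ids, by_id)
            boundaries = [a_edge_hrb(lo, scaffold), a_edge_hrb(hi, scaffold)]
            if ins is not None:
                boundaries.append(a_edge_hrb(ins[1], ins[0]))
            events.append(
                RearrangementEvent("translocation", tuple(ids), tuple(boundaries))
            )

    if tally["fusion"]:
        for _ in range(tally["fusion"]):
            events.append(RearrangementEvent("fusion", (), ()))

    return tally, events


def _displaced_strips(merged_keys: list[list[int]]) -> list[list[int]]:
    """The strips outside one longest increasing subsequence of strip keys."""
    keys = [ids[0] for ids in merged_keys]
    n = len(keys)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if keys[j] < keys[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: best_len[i])
    in_lis = set()
    while end != -1:
        in_lis.add(end)
        end = prev[end]
    return [merged_keys[i] for i in range(n) if i not in in_lis]


def _insertion_edge(flat: list[int], moved_ids: list[int], by_id):
    """A-coordinate of the block edge facing the moved strip's position in B."""
    moved = set(moved_ids)
    idxs = [i for i, x in enumerate(flat) if abs(x) in moved]
    if not idxs:
        return None
    left = idxs[0] - 1
    right = idxs[-1] + 1
    if left >= 0 and abs(flat[left]) not in moved:
        blk = by_id[abs(flat[left])]
        return blk.scaffold_a, blk.end_a if flat[left] > 0 else blk.start_a
    if right < len(flat) and abs(flat[right]) not in moved:
        blk = by_id[abs(flat[right])]
        return blk.scaffold_a, blk.start_a if flat[right] > 0 else blk.end_a
    return None


# --------------------------------------------------------------------------
# HRBs and mechanism


def extract_hrbs(
    blocks: list[SyntenyBlock],
    genome_a: AnnotatedGenome,
    end_tol: int = 50,
    merge_tol: int = 50,
) -> list[HRB]:
    """Block edges in genome A, interior ones usable as rearrangement proxies.

    Edges at scaffold extremities are flagged ``at_scaffold_end`` (and
    excluded from proximity statistics); edges of adjacent blocks closer
    than ``merge_tol`` are merged into one boundary.
    """
    edges: list[tuple[str, int]] = []
    for b in blocks:
        edges.append((b.scaffold_a, b.start_a))
        edges.append((b.scaffold_a, b.end_a))
    edges.sort()
    hrbs: list[HRB] = []
    for scaffold, pos in edges:
        if hrbs and hrbs[-1].scaffold == scaffold and pos - hrbs[-1].position <= merge_tol:
            continue
        L = len(genome_a.scaffolds[scaffold])
        hrbs.append(HRB(scaffold, pos, pos <= end_tol or pos >= L - end_tol))
    return hrbs


def _near_repeat(
    scaffold: str, pos: int, families: list[RepeatFamily], window: int
) -> bool:
    for fam in families:
        for c in fam.copies:
            if c.scaffold != scaffold:
                continue
            if c.start - window <= pos <= c.end + window:
                return True
    return False


def hrb_repeat_proximity(
    hrbs: list[HRB], families: list[RepeatFamily], window: int = 50
) -> float | None:
    """Proportion of usable HRBs within ``window`` bp of any repeat copy."""
    usable = [h for h in hrbs if not h.at_scaffold_end]
    if not usable:
        return None
    near = sum(1 for h in usable if _near_repeat(h.scaffold, h.position, families, window))
    return near / len(usable)


def attribute_mechanism(
    events: list[RearrangementEvent],
    hrbs: list[HRB],
    families: list[RepeatFamily],
    window: int = 50,
) -> list[RearrangementEvent]:
    """Attribute each event to repeat-mediated recombination or NHEJ.

    An event is ``repeat_mediated`` iff *all* of its boundaries not at
    scaffold ends lie within ``window`` bp of a repeat copy; events with no
    usable boundary are ``undetermined``.  (``hrbs`` is accepted for
    interface symmetry; boundary/scaffold-end information travels on the
    events themselves.)
    """
    for ev in events:
        usable = [b for b in ev.boundaries if not b.at_scaffold_end]
        if not usable:
            ev.mechanism = "undetermined"
        elif all(
            _near_repeat(b.scaffold, b.position, families, window) for b in usable
        ):
            ev.mechanism = "repeat_mediated"
        else:
            ev.mechanism = "nhej"
    return events
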