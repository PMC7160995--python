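"""Repeat detection and two-copy repeat configuration analysis.

Repeated sequence >= 50 bp is the raw material for homologous recombination
in plant mitogenomes.  Detection here is exact-seed + ungapped X-drop
extension with explicit length/identity thresholds (a reproducible,
parameter-transparent replacement for E-value based self-BLAST).  Families
are built by single linkage over mutual matches; size classes follow the
field convention: *intermediate* 50–1000 bp, *large* > 1000 bp.

A two-copy family defines four junction *configurations*: label the flanks
of copy 1 ``a`` (upstream) and ``b`` (downstream), and of copy 2 ``c`` / ``d``
— both read in the copy's own orientation, so the labels are orientation
independent.  ``a-b`` and ``c-d`` are the parental junctions; crossover
between the copies produces the recombinant junctions ``a-d`` and ``c-b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import AnnotatedGenome, circ_slice, interval_union_length, revcomp

__all__ = [
    "RepeatCopy",
    "RepeatFamily",
    "RepeatConfiguration",
    "find_repeats",
    "repeat_coverage",
    "classify_families",
    "make_configurations",
    "ConfigurationError",
]

PARENTAL_LABELS = ("a-b", "c-d")
RECOMBINANT_LABELS = ("a-d", "c-b")
ALL_LABELS = PARENTAL_LABELS + RECOMBINANT_LABELS


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatCopy:
    scaffold: str
    start: int
    end: int  # half-open; may exceed scaffold length when wrapping the origin
    strand: str
    identity: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self, L: int) -> tuple[int, int]:
        return (self.start % L, self.end % L if self.end % L else self.end)


@dataclass
class RepeatFamily:
    name: str
    copies: list[RepeatCopy] = field(default_factory=list)

    @property
    def consensus_length(self) -> int:
        lens = sorted(c.length for c in self.copies)
        return lens[len(lens) // 2]

    @property
    def size_class(self) -> str:
        return "large" if self.consensus_length > 1000 else "intermediate"

    @property
    def copy_class(self) -> str:
        n = len(self.copies)
        return {2: "two-copy", 3: "three-copy"}.get(n, "multi-copy")


@dataclass(frozen=True)
class RepeatConfiguration:
    family: str
    label: str  # a-b | c-d | a-d | c-b
    junction_seq: str
    flank_len: int

    @property
    def kind(self) -> str:
        return "parental" if self.label in PARENTAL_LABELS else "recombinant"


# --------------------------------------------------------------------------
# detection


def _seed_matches(seq: str, k: int) -> list[tuple[int, int, str]]:
    """Maximal exact pairwise matches from shared k-mers (circular genome).

    Returns (posA, posB, strand) seed diagonals merged into maximal runs;
    positions refer to the doubled sequence and are reduced modulo L later.
    """
    L = len(seq)
    doubled = seq + seq
    index: dict[str, list[int]] = {}
    for i in range(L):  # index forward k-mers starting in the first copy
        index.setdefault(doubled[i : i + k], []).append(i)

    fwd_pairs: set[tuple[int, int]] = set()
    rev_pairs: set[tuple[int, int]] = set()
    for kmer, positions in index.items():
        if len(positions) > 1:
            for x in positions:
                for y in positions:
                    if x < y and y - x != L:
                        fwd_pairs.add((x, y))
        rc = revcomp(kmer)
        if rc in index and rc != kmer:
            for x in positions:
                for y in index[rc]:
                    if x < y:
                        rev_pairs.add((x, y))
        elif rc == kmer:
            for x in positions:
                for y in positions:
                    if x < y:
                        rev_pairs.add((x, y))
    return fwd_pairs, rev_pairs


def _merge_diagonal_runs(
    pairs: set[tuple[int, int]], k: int, strand: str
) -> list[tuple[int, int, int]]:
    """Merge seed pairs on a shared diagonal into maximal runs.

    Returns (startA, startB, length) in doubled-sequence coordinates.  For
    '-' matches the diagonal is posA + posB (B start is the *left* end of
    the reverse-complement window).
    """
    by_diag: dict[int, list[int]] = {}
    for a, b in pairs:
        d = a - b if strand == "+" else a + b
        by_diag.setdefault(d, []).append(a)
    runs = []
    for d, xs in by_diag.items():
        xs.sort()
        run_start, run_end = xs[0], xs[0] + k
        for a in xs[1:]:
            if a <= run_end:  # overlapping/adjacent seed extends the run
                run_end = max(run_end, a + k)
            else:
                runs.append((run_start, d, run_end - run_start))
                run_start, run_end = a, a + k
        runs.append((run_start, d, run_end - run_start))
    out = []
    for a0, d, ln in runs:
        # '+': b = a - d throughout the run; '-': the B window left end
        # pairs with the *right* end of the A run (antidiagonal a + b = d)
        b0 = a0 - d if strand == "+" else d - (a0 + ln - k)
        out.append((a0, b0, ln))
    return out


def _xdrop_extend(
    seq: str,
    a0: int,
    b0: int,
    length: int,
    strand: str,
    min_identity: float,
    xdrop: int = 15,
):
    """Extend an exact run in both directions allowing mismatches (ungapped).

    Match +1, mismatch -3; extension in a direction stops when the running
    score drops ``xdrop`` below its maximum, and is trimmed back to the
    maximum.  The extension works on the doubled sequence; the caller is
    responsible for mapping coordinates back modulo the genome length.
    """
    doubled = seq + seq
    n2 = len(doubled)

    def base_b(off: int) -> str:
        if strand == "+":
            p = b0 + off
            return doubled[p] if 0 <= p < n2 else "?"
        # '-' : B window [b0, b0+len) pairs reverse-complemented with A
        p = b0 + length - 1 - off
        return {"A": "T", "C": "G", "G": "C", "T": "A"}.get(doubled[p], "?") if 0 <= p < n2 else "?"

    # right extension
    best, score, ext_r = 0, 0, 0
    i = 0
    while True:
        pa = a0 + length + i
        if pa >= n2:
            break
        cb = base_b(length + i) if strand == "+" else None
        if strand == "-":
            p = b0 - 1 - i
            cb = (
                {"A": "T", "C": "G", "G": "C", "T": "A"}[doubled[p]]
                if 0 <= p < n2
                else "?"
            )
        score += 1 if doubled[pa] == cb else -3
        if score > best:
            best, ext_r = score, i + 1
        if score < best - xdrop:
            break
        i += 1
    # left extension
    best, score, ext_l = 0, 0, 0
    i = 0
    while True:
        pa = a0 - 1 - i
        if pa < 0:
            break
        if strand == "+":
            p = b0 - 1 - i
            cb = doubled[p] if p >= 0 else "?"
        else:
            p = b0 + length + i
            cb = (
                {"A": "T", "C": "G", "G": "C", "T": "A"}[doubled[p]]
                if p < n2
                else "?"
            )
        score += 1 if doubled[pa] == cb else -3
        if score > best:
            best, ext_l = score, i + 1
        if score < best - xdrop:
            break
        i += 1

    new_a0 = a0 - ext_l
    new_len = length + ext_l + ext_r
    if strand == "+":
        new_b0 = b0 - ext_l
    else:
        new_b0 = b0 - ext_r
    # identity over the extended match
    mism = 0
    for off in range(new_len):
        ca = doubled[new_a0 + off]
        if strand == "+":
            cb = doubled[new_b0 + off]
        else:
            cb = {"A": "T", "C": "G", "G": "C", "T": "A"}[doubled[new_b0 + new_len - 1 - off]]
        if ca != cb:
            mism += 1
    ident = 1.0 - mism / new_len if new_len else 0.0
    if ident < min_identity:
        return a0, b0, length, 1.0  # fall back to the exact core
    return new_a0, new_b0, new_len, ident


def find_repeats(
    genome: AnnotatedGenome,
    min_len: int = 50,
    seed_size: int = 50,
    min_identity: float = 0.9,
    scaffold: str | None = None,
) -> list[RepeatFamily]:
    """Detect repeat families within one (circular) scaffold.

    Every maximal repeated region >= ``min_len`` at >= ``min_identity`` is
    reported once per copy; trivial self-matches are excluded; copies are
    grouped into families by single linkage over mutual matches.
    """
    if min_len < seed_size:
        raise ConfigurationError(
            f"min_len {min_len} < seed_size {seed_size}: such repeats are "
            "undetectable with exact seeds"
        )
    sc = genome.scaffolds[scaffold] if scaffold else next(iter(genome.scaffolds.values()))
    seq = sc.seq
    L = len(seq)
    if L == 0:
        raise ValueError("empty genome")

    fwd_pairs, rev_pairs = _seed_matches(seq, seed_size)

    matches = []  # (a0, b0, length, strand, identity) in doubled coords
    for pairs, strand in ((fwd_pairs, "+"), (rev_pairs, "-")):
        for a0, b0, ln in _merge_diagonal_runs(pairs, seed_size, strand):
            if min_identity < 1.0:
                a0, b0, ln, ident = _xdrop_extend(seq, a0, b0, ln, strand, min_identity)
            else:
                ident = 1.0
            if ln < min_len:
                continue
            # trivial / heavily self-overlapping matches
            ia = (a0 % L, (a0 % L) + ln)
            ib = (b0 % L, (b0 % L) + ln)
            if _circ_overlap(ia, ib, L) > 0.5 * ln:
                continue
            matches.append((ia, ib, strand, ident))

    # deduplicate matches seen from both the original and the doubled copy
    canon = {}
    for ia, ib, strand, ident in matches:
        key = tuple(sorted([ia, ib])) + (strand,)
        canon[key] = (ia, ib, strand, ident)
    matches = list(canon.values())

    # cluster copy intervals (reciprocal overlap >= 50%) into copy ids
    intervals: list[tuple[int, int]] = []

    def copy_id(iv: tuple[int, int]) -> int:
        for i, known in enumerate(intervals):
            o = _circ_overlap(iv, known, L)
            if o >= 0.5 * (iv[1] - iv[0]) and o >= 0.5 * (known[1] - known[0]):
                # keep the longer extent
                if iv[1] - iv[0] > known[1] - known[0]:
                    intervals[i] = iv
                return i
        intervals.append(iv)
        return len(intervals) - 1

    parent: dict[int, int] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    edges = []  # (copyA, copyB, strand, identity)
    for ia, ib, strand, ident in matches:
        ca, cb = copy_id(ia), copy_id(ib)
        if ca == cb:
            continue
        union(ca, cb)
        edges.append((ca, cb, strand, ident))

    groups: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)

    families: list[RepeatFamily] = []
    for fi, (root, members) in enumerate(sorted(groups.items())):
        if len(members) < 2:
            continue
        # assign strands by BFS over match edges from the first member
        strand_of = {members[0]: "+"}
        ident_of = {members[0]: 1.0}
        adj: dict[int, list[tuple[int, str, float]]] = {}
        for ca, cb, strand, ident in edges:
            if find(ca) == root:
                adj.setdefault(ca, []).append((cb, strand, ident))
                adj.setdefault(cb, []).append((ca, strand, ident))
        queue = [members[0]]
        while queue:
            cur = queue.pop()
            for nb, strand, ident in adj.get(cur, []):
                if nb not in strand_of:
                    strand_of[nb] = (
                        strand_of[cur]
                        if strand == "+"
                        else ("-" if strand_of[cur] == "+" else "+")
                    )
                    ident_of[nb] = min(ident_of[cur], ident)
                    queue.append(nb)
        fam = RepeatFamily(name=f"F{fi + 1}")
        for m in sorted(members, key=lambda m: intervals[m][0]):
            s, e = intervals[m]
            fam.copies.append(
                RepeatCopy(sc.name, s, e, strand_of.get(m, "+"), ident_of.get(m, 1.0))
            )
        if fam.consensus_length >= min_len:
            families.append(fam)
    families.sort(key=lambda f: f.copies[0].start)
    for i, fam in enumerate(families):
        fam.name = f"F{i + 1}"
    return families


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    """Number of shared positions between two circular intervals.

    Intervals are given "unrolled" (end may exceed L when wrapping the
    origin) and are each at most L long.
    """
    s1, e1 = a
    s2, e2 = b
    total = 0
    for shift in (-L, 0, L):
        lo, hi = max(s1, s2 + shift), min(e1, e2 + shift)
        if hi > lo:
            total += hi - lo
    return total


# --------------------------------------------------------------------------
# summaries


def repeat_coverage(families: list[RepeatFamily], genome: AnnotatedGenome) -> float:
    """Fraction of the genome covered by the union of all repeat copies."""
    total = genome.length
    if not families:
        return 0.0
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for fam in families:
        for c in fam.copies:
            by_scaffold.setdefault(c.scaffold, []).append((c.start, c.end))
    covered = 0
    for name, ivs in by_scaffold.items():
        covered += interval_union_length(ivs, len(genome.scaffolds[name]))
    return covered / total


def classify_families(families: list[RepeatFamily]) -> dict[str, dict[str, int]]:
    """Tally families by size class and by copy class."""
    size = {"intermediate": 0, "large": 0}
    copies = {"two-copy": 0, "three-copy": 0, "multi-copy": 0}
    for fam in families:
        size[fam.size_class] += 1
        copies[fam.copy_class] += 1
    return {"size_class": size, "copy_class": copies}


# --------------------------------------------------------------------------
# configurations


def _occurrences(genome_seq: str, probe: str) -> int:
    doubled = genome_seq + genome_seq
    count = 0
    for hay in (doubled, revcomp(doubled)):
        start = 0
        while True:
            i = hay.find(probe, start)
            if i == -1 or i >= len(genome_seq):
                break
            count += 1
            start = i + 1
    return count


def make_configurations(
    family: RepeatFamily, genome: AnnotatedGenome, flank_len: int = 500
) -> list[RepeatConfiguration]:
    """Build the four junction configurations of a two-copy family.

    Flanks are read in each copy's own orientation so that crossover between
    the copies always swaps downstream flanks: parental ``a-b`` / ``c-d``,
    recombinant ``a-d`` / ``c-b``.  A configuration set is rejected
    (``ConfigurationError``) when a flank is not unique in the genome or a
    copy sits at a linear scaffold end with insufficient flank.
    """
    if len(family.copies) != 2:
        raise ConfigurationError("configurations are defined for two-copy families")
    if flank_len <= 0:
        raise ConfigurationError("flank_len must be positive")
    c1, c2 = family.copies
    sc = genome.scaffolds[c1.scaffold]
    seq, L = sc.seq, len(sc.seq)

    def flanks(c: RepeatCopy) -> tuple[str, str, str]:
        """(upstream, repeat, downstream) in the copy's own orientation."""
        if sc.circular:
            up = circ_slice(seq, c.start - flank_len, flank_len)
            rep = circ_slice(seq, c.start, c.length)
            down = circ_slice(seq, c.end, flank_len)
        else:
            if c.start - flank_len < 0 or c.end + flank_len > L:
                raise ConfigurationError(
                    f"copy at scaffold end lacks {flank_len} bp flank; "
                    "configuration undetectable"
                )
            up, rep, down = (
                seq[c.start - flank_len : c.start],
                seq[c.start : c.end],
                seq[c.end : c.end + flank_len],
            )
        if c.strand == "-":
            up, rep, down = revcomp(down), revcomp(rep), revcomp(up)
        return up, rep, down

    a, rep1, b = flanks(c1)
    c, rep2, d = flanks(c2)

    for probe, label in ((a, "a"), (b, "b"), (c, "c"), (d, "d")):
        if _occurrences(seq, probe) != 1:
            raise ConfigurationError(
                f"flank {label} of family {family.name} is not unique in the "
                "genome; configuration rejected as undetectable"
            )

    return [
        RepeatConfiguration(family.name, "a-b", a + rep1 + b, flank_len),
        RepeatConfiguration(family.name, "c-d", c + rep2 + d, flank_len),
        RepeatConfiguration(family.name, "a-d", a + rep1 + d, flank_len),
        RepeatConfiguration(family.name, "c-b", c + rep2 + b, flank_len),
    ]
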