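"""Gene-level comparison across mitogenome lines.

Covers four observables the structural analysis feeds into: per-gene copy
number (and which genes gained copies in a derived line), changed gene
clusters (k-gene windows of the circular gene order present in one line
but not the other), the fraction of genes lying within a window of repeat
sequence (a proxy for recombination exposure of promoters), and
paternal-specific sequence screening (does any sequence private to the
paternal genome show up in a derived line — the maternal-inheritance
check).
"""

from __future__ import annotations

import re

import edlib
import pandas as pd

from .genome import AnnotatedGenome, GeneFeature, circ_interval_distance, revcomp
from .repeats import RepeatFamily

__all__ = [
    "normalize_gene_name",
    "gene_order",
    "copy_number_table",
    "detect_cluster_changes",
    "repeat_proximity_fraction",
    "detect_specific_sequences",
    "screen_for_fragments",
]


def normalize_gene_name(name: str) -> str:
    """Canonical gene name: case-folded, anticodon qualifier as a suffix.

    ``trnE (TTC)`` and ``trnE-TTC`` both normalise to ``trne-ttc``.
    """
    m = re.match(r"^\s*(\S+)\s*\(([^)]+)\)\s*$", name)
    if m:
        name = f"{m.group(1)}-{m.group(2)}"
    return name.strip().lower()


def gene_order(genes: list[GeneFeature]) -> dict[str, list[str]]:
    """Per-scaffold circular order of signed, normalised gene names."""
    out: dict[str, list[str]] = {}
    by_scaffold: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for name, gs in by_scaffold.items():
        gs.sort(key=lambda g: g.start)
        out[name] = [
            ("+" if g.strand == "+" else "-") + normalize_gene_name(g.name) for g in gs
        ]
    return out


# --------------------------------------------------------------------------
# copy number


def copy_number_table(
    annotations: dict[str, list[GeneFeature]], maternal: str
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene x line copy-number table plus the increased-copy gene lists.

    ``annotations`` maps line name to its gene features; ``maternal`` names
    the reference line.  A gene is *increased* in a line when its count
    exceeds the maternal count.
    """
    if maternal not in annotations:
        raise ValueError(f"maternal line {maternal!r} missing from annotations")
    lines = list(annotations)
    names = sorted(
        {normalize_gene_name(g.name) for gs in annotations.values() for g in gs}
    )
    table = pd.DataFrame(0, index=names, columns=lines, dtype=int)
    for line, gs in annotations.items():
        for g in gs:
            table.loc[normalize_gene_name(g.name), line] += 1
    increased = {
        line: sorted(table.index[table[line] > table[maternal]])
        for line in lines
        if line != maternal
    }
    return table, increased


# --------------------------------------------------------------------------
# gene clusters


def _windows(order: list[str], k: int, circular: bool = True) -> set[tuple[str, ...]]:
    n = len(order)
    wins: set[tuple[str, ...]] = set()
    idx_range = range(n) if circular else range(n - k + 1)
    for i in idx_range:
        w = tuple(order[(i + j) % n] for j in range(k))
        wins.add(_canonical_window(w))
    return wins


def _flip(name: str) -> str:
    return ("-" if name.startswith("+") else "+") + name[1:]


def _canonical_window(w: tuple[str, ...]) -> tuple[str, ...]:
    rc = tuple(_flip(x) for x in reversed(w))
    return min(w, rc)


def detect_cluster_changes(
    order_a: list[str] | dict[str, list[str]],
    order_b: list[str] | dict[str, list[str]],
    k: int = 4,
    circular: bool = True,
) -> list[tuple[str, ...]]:
    """k-gene clusters of order B absent from order A (strand-symmetric).

    Orders are signed gene-name lists (or per-scaffold dicts of them),
    compared as circular sequences; a window and its reverse complement
    are the same cluster.  Returns the novel clusters of B, sorted.
    """

    def as_lists(o):
        return list(o.values()) if isinstance(o, dict) else [o]

    lists_a, lists_b = as_lists(order_a), as_lists(order_b)
    if any(len(o) < k for o in lists_b):
        raise ValueError(f"fewer than k={k} genes in an order")
    wins_a: set[tuple[str, ...]] = set()
    for o in lists_a:
        wins_a |= _windows(o, k, circular)
    novel: set[tuple[str, ...]] = set()
    for o in lists_b:
        novel |= _windows(o, k, circular) - wins_a
    return sorted(novel)


# --------------------------------------------------------------------------
# repeat proximity


def repeat_proximity_fraction(
    genes: list[GeneFeature],
    families: list[RepeatFamily],
    genome: AnnotatedGenome,
    window: int = 2000,
) -> float | None:
    """Fraction of genes within ``window`` bp (edge-to-edge, circular) of a repeat."""
    if not genes:
        return None
    near = 0
    for g in genes:
        L = len(genome.scaffolds[g.scaffold])
        circular = genome.scaffolds[g.scaffold].circular
        for fam in families:
            hit = False
            for c in fam.copies:
                if c.scaffold != g.scaffold:
                    continue
                d = circ_interval_distance(
                    (g.start, g.end), (c.start, c.end), L, circular
                )
                if d <= window:
                    near += 1
                    hit = True
                    break
            if hit:
                break
    return near / len(genes)


# --------------------------------------------------------------------------
# paternal-specific sequence


def detect_specific_sequences(
    reference: AnnotatedGenome,
    other: AnnotatedGenome,
    word: int = 20,
    min_len: int = 100,
) -> list[tuple[str, int, int]]:
    """Maximal intervals of ``other`` with no exact match >= ``word`` in ``reference``.

    A position of ``other`` is *shared* iff it lies inside some exact common
    substring of length >= ``word`` (equivalently: covered by a common
    ``word``-mer window, either strand, circular reference).  Returns the
    complementary intervals of length >= ``min_len``.
    """
    import numpy as np

    ref_kmers: set[str] = set()
    for sc in reference.scaffolds.values():
        seq = sc.seq + (sc.seq[: word - 1] if sc.circular else "")
        for i in range(len(seq) - word + 1):
            ref_kmers.add(seq[i : i + word])
        rc = revcomp(seq)
        for i in range(len(rc) - word + 1):
            ref_kmers.add(rc[i : i + word])

    out: list[tuple[str, int, int]] = []
    for name, sc in other.scaffolds.items():
        L = len(sc.seq)
        covered = np.zeros(L, dtype=bool)
        seq = sc.seq + (sc.seq[: word - 1] if sc.circular else "")
        for i in range(len(seq) - word + 1):
            if seq[i : i + word] in ref_kmers:
                for p in range(i, i + word):
                    covered[p % L] = True
        # maximal uncovered runs
        start = None
        for p in range(L + 1):
            un = p < L and not covered[p]
            if un and start is None:
                start = p
            elif not un and start is not None:
                if p - start >= min_len:
                    out.append((name, start, p))
                start = None
    return out


def screen_for_fragments(
    query: AnnotatedGenome,
    fragments: list[tuple[str, str]],
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> dict[str, bool]:
    """Presence/absence of each (name, sequence) fragment in ``query``.

    A fragment is present iff >= ``min_coverage`` of its length aligns
    somewhere in the query (either strand, circular-aware) at >=
    ``min_identity``; tested by semi-global alignment of the fragment —
    and, to honour the coverage allowance, of its central
    ``min_coverage``-fraction — against the query.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    targets = []
    for sc in query.scaffolds.values():
        seq = sc.seq + (sc.seq if sc.circular else "")
        targets.append(seq)
        targets.append(revcomp(seq))

    out: dict[str, bool] = {}
    for name, frag in fragments:
        if len(frag) == 0:
            raise ValueError(f"fragment {name!r} has zero length")
        trim = int(len(frag) * (1 - min_coverage) / 2)
        core = frag[trim : len(frag) - trim] if trim else frag
        present = False
        for probe in (frag, core):
            k = int(len(probe) * (1 - min_identity))
            for t in targets:
                if len(t) < len(probe):
                    continue
                r = edlib.align(probe, t, mode="HW", task="distance", k=k)
                if r["editDistance"] != -1:
                    present = True
                    break
            if present:
                break
        out[name] = present
    return out
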