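"""Synthetic circular mitogenomes with planted, ledger-recorded ground truth.

This module generates the substrate every other analysis stage is exercised
on: a random circular genome carrying planted repeat families (two size
classes, direct or inverted copies), gene annotations, derived genomes
produced by repeat-mediated or NHEJ rearrangement events, long reads drawn
from mixtures of genome variants, strand-aware RNA pileups with planted
C-to-U editing rates, and binary marker matrices with group structure.

Every planted feature is recorded in a JSON-serialisable *ledger*; the
ledger alone is sufficient to compute the expected output of every
downstream module, which is what makes end-to-end recovery tests possible.

Randomness: one RNG stream per output artifact, derived from the master
seed together with a stable per-artifact label, so that adding one output
does not perturb the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import AnnotatedGenome, GeneFeature, Scaffold, circ_slice, revcomp

__all__ = [
    "RepeatPlan",
    "GenePlan",
    "PlannedEvent",
    "ReadPlan",
    "EditingPlan",
    "SimSpec",
    "PackingError",
    "generate_genome",
    "apply_event",
    "apply_events",
    "simulate_long_reads",
    "write_fastq",
    "simulate_editing_pileup",
    "simulate_marker_matrix",
    "ledger_repeat_coverage",
]

BASES = "ACGT"

# stable per-artifact RNG stream labels (see module docstring)
_STREAM = {"genome": 11, "events": 23, "reads": 37, "pileup": 53, "markers": 71}


class PackingError(ValueError):
    """Planted features cannot be placed without overlap."""


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAM[label]])


# --------------------------------------------------------------------------
# plan dataclasses


@dataclass(frozen=True)
class RepeatPlan:
    """One repeat family to plant: ``copies`` near-identical copies.

    ``orientation`` applies to every copy after the first; ``identity`` is
    the fraction of bases each later copy shares with the first.  With
    ``spacing`` set, the copies are placed as one compact group with that
    many bases of background sequence between consecutive copies — used to
    keep the genomic span affected by a recombination event between the
    copies small, so that several planted events stay well separated.
    """

    length: int
    copies: int = 2
    orientation: str = "direct"  # direct | inverted
    identity: float = 1.0
    name: str | None = None
    spacing: int | None = None

    def __post_init__(self):
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.copies < 2:
            raise ValueError("a repeat family needs >= 2 copies")
        if self.spacing is not None and self.spacing < 0:
            raise ValueError("spacing must be >= 0")


@dataclass(frozen=True)
class GenePlan:
    name: str
    length: int
    strand: str = "+"
    type: str = "protein"


@dataclass(frozen=True)
class PlannedEvent:
    """A rearrangement event to apply to a genome.

    kind       reversal | translocation | fusion | fission
    mechanism  repeat_mediated | nhej
    anchor     repeat family name (repeat_mediated) or tuple of coordinates
               (nhej); coordinates refer to the genome the event is applied
               to (scaffold, position) or bare positions on a single
               scaffold.
    insert     insertion target for translocations: a repeat family name
               (repeat_mediated; the excised segment reintegrates inside a
               copy of that family) or a coordinate.
    recombinant_fraction   heteroplasmy level used by read simulation.
    microhomology          bases duplicated at an NHEJ junction (default 0
               keeps mechanism ground truth unambiguous).
    """

    kind: str
    mechanism: str
    anchor: object = None
    insert: object = None
    recombinant_fraction: float = 0.0
    microhomology: int = 0

    def __post_init__(self):
        if self.kind not in ("reversal", "translocation", "fusion", "fission"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.mechanism not in ("repeat_mediated", "nhej"):
            raise ValueError(f"bad mechanism {self.mechanism!r}")
        if not 0.0 <= self.recombinant_fraction <= 1.0:
            raise ValueError("recombinant_fraction must be in [0, 1]")
        if not 0 <= self.microhomology <= 10:
            raise ValueError("microhomology must be in [0, 10]")


@dataclass(frozen=True)
class ReadPlan:
    n_reads: int = 2000
    mean_length: float = 8000.0
    sigma_log: float = 0.45
    min_length: int = 1000
    max_length: int = 20000
    error_rate: float = 0.0


@dataclass(frozen=True)
class EditingPlan:
    """Plant a C-to-U (or U-to-C) site at a 0-based offset within a gene CDS."""

    gene: str
    cds_offset: int
    rate: float
    edit_type: str = "C-to-U"

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("editing rate must be in [0, 1]")
        if self.edit_type not in ("C-to-U", "U-to-C"):
            raise ValueError(f"bad edit type {self.edit_type!r}")


@dataclass
class SimSpec:
    genome_length: int
    repeat_plan: list[RepeatPlan] = field(default_factory=list)
    gene_plan: list[GenePlan] = field(default_factory=list)
    event_plan: list[PlannedEvent] = field(default_factory=list)
    read_plan: ReadPlan = field(default_factory=ReadPlan)
    editing_plan: list[EditingPlan] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        total = sum(r.length * r.copies for r in self.repeat_plan)
        total += sum(g.length for g in self.gene_plan)
        if total > self.genome_length:
            raise PackingError(
                f"planted features total {total} bp > genome length "
                f"{self.genome_length} bp"
            )


# --------------------------------------------------------------------------
# genome generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute bases so the result matches ``seq`` at ~``identity`` fraction."""
    n_mut = round(len(seq) * (1.0 - identity))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def _place_features(
    rng: np.random.Generator,
    genome_length: int,
    sizes: list[int],
    min_separation: int,
) -> list[int]:
    """Choose non-overlapping start positions (random order, random gaps).

    The features are laid out in a random order with at least
    ``min_separation`` bp between consecutive features (and from the
    origin), the remaining slack distributed randomly among the gaps.
    Features are kept clear of the origin so no planted feature wraps,
    which keeps ledger intervals simple; the genome is still treated as
    circular downstream.  Works at any feasible density.
    """
    n = len(sizes)
    if n == 0:
        return []
    slack = genome_length - sum(sizes) - (n + 1) * min_separation
    if slack < 0:
        raise PackingError(
            f"features totalling {sum(sizes)} bp (+ separations) do not fit "
            f"in a {genome_length} bp genome"
        )
    order = rng.permutation(n)
    gaps = rng.multinomial(slack, np.ones(n + 1) / (n + 1))
    starts = [0] * n
    cursor = min_separation + int(gaps[0])
    for k, fi in enumerate(order):
        starts[fi] = cursor
        cursor += sizes[fi] + min_separation + int(gaps[k + 1])
    return starts


def generate_genome(
    spec: SimSpec, *, scaffold_name: str = "mt1", min_separation: int = 700
) -> tuple[AnnotatedGenome, dict]:
    """Generate a circular genome per ``spec`` plus its ground-truth ledger.

    Repeat copies and genes are placed uniformly at random with at least
    ``min_separation`` bp between features, so that every repeat copy has
    unique flanking sequence (a prerequisite for configuration analysis)
    and no gene straddles a planted repeat.
    """
    spec.validate()
    rng = _rng(spec.seed, "genome")
    seq = list(_random_seq(rng, spec.genome_length))

    # grouped families (spacing set) are placed as one super-feature
    sizes: list[int] = []
    for r in spec.repeat_plan:
        if r.spacing is None:
            sizes += [r.length] * r.copies
        else:
            sizes.append(r.length * r.copies + r.spacing * (r.copies - 1))
    sizes += [g.length for g in spec.gene_plan]
    group_starts = _place_features(rng, spec.genome_length, sizes, min_separation)
    starts: list[int] = []
    gi = 0
    for r in spec.repeat_plan:
        if r.spacing is None:
            starts += group_starts[gi : gi + r.copies]
            gi += r.copies
        else:
            base = group_starts[gi]
            gi += 1
            starts += [base + ci * (r.length + r.spacing) for ci in range(r.copies)]
    starts += group_starts[gi:]

    ledger: dict = {
        "genome_length": spec.genome_length,
        "scaffold": scaffold_name,
        "seed": int(spec.seed),
        "repeat_families": [],
        "genes": [],
        "events": [],
        "editing_sites": [],
    }

    idx = 0
    for fi, fam in enumerate(spec.repeat_plan):
        name = fam.name or f"R{fi + 1}"
        core = _random_seq(rng, fam.length)
        copies = []
        for ci in range(fam.copies):
            start = starts[idx]
            idx += 1
            if ci == 0:
                copy_seq, strand = core, "+"
            else:
                mutated = _mutate(rng, core, fam.identity)
                if fam.orientation == "inverted":
                    copy_seq, strand = revcomp(mutated), "-"
                else:
                    copy_seq, strand = mutated, "+"
            seq[start : start + fam.length] = copy_seq
            copies.append(
                {"start": start, "end": start + fam.length, "strand": strand}
            )
        ledger["repeat_families"].append(
            {
                "name": name,
                "consensus_length": fam.length,
                "orientation": fam.orientation,
                "identity": fam.identity,
                "copies": copies,
            }
        )

    for gp in spec.gene_plan:
        start = starts[idx]
        idx += 1
        ledger["genes"].append(
            {
                "name": gp.name,
                "type": gp.type,
                "start": start,
                "end": start + gp.length,
                "strand": gp.strand,
            }
        )

    genome = AnnotatedGenome(
        scaffolds={scaffold_name: Scaffold(scaffold_name, "".join(seq), circular=True)},
        genes=[
            GeneFeature(g["name"], g["type"], scaffold_name, g["start"], g["end"], g["strand"])
            for g in ledger["genes"]
        ],
    )

    # force planted editing sites to the required reference base on the
    # coding strand (C for C-to-U, T for U-to-C)
    if spec.editing_plan:
        _plant_editing_refs(genome, ledger, spec.editing_plan)

    return genome, ledger


def _cds_offset_to_genomic(gene: dict, offset: int) -> int:
    if not 0 <= offset < gene["end"] - gene["start"]:
        raise ValueError(
            f"CDS offset {offset} outside gene {gene['name']} "
            f"({gene['end'] - gene['start']} bp)"
        )
    if gene["strand"] == "+":
        return gene["start"] + offset
    return gene["end"] - 1 - offset


def _plant_editing_refs(
    genome: AnnotatedGenome, ledger: dict, plan: list[EditingPlan]
) -> None:
    scaffold = ledger["scaffold"]
    seq = list(genome.scaffolds[scaffold].seq)
    by_name = {g["name"]: g for g in ledger["genes"]}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for ep in plan:
        if ep.gene not in by_name:
            raise ValueError(f"editing plan names unknown gene {ep.gene!r}")
        gene = by_name[ep.gene]
        pos = _cds_offset_to_genomic(gene, ep.cds_offset)
        coding_ref = "C" if ep.edit_type == "C-to-U" else "T"
        seq[pos] = coding_ref if gene["strand"] == "+" else comp[coding_ref]
        ledger["editing_sites"].append(
            {
                "gene": ep.gene,
                "cds_offset": ep.cds_offset,
                "position": pos,
                "strand": gene["strand"],
                "rate": ep.rate,
                "edit_type": ep.edit_type,
            }
        )
    genome.scaffolds[scaffold].seq = "".join(seq)


# --------------------------------------------------------------------------
# rearrangement events (fragment algebra over the parent genome)
#
# A derived genome is represented while under construction as, per scaffold,
# an ordered list of signed fragments (start, end, sign) of the *parent*
# sequence.  Event anchors are therefore always resolved in parent
# coordinates, which is exactly the coordinate system the ledger and every
# downstream oracle use.  Events must not interact (each breakpoint must
# fall inside a still-forward, still-uncut region); overlapping event plans
# raise.


class _FragScaffolds:
    def __init__(self, genome: AnnotatedGenome):
        self.parent = genome
        self.names = list(genome.scaffolds)
        self.frags: dict[str, list[tuple[str, int, int, int]]] = {
            n: [(n, 0, len(s), +1)] for n, s in genome.scaffolds.items()
        }
        self.circular = {n: s.circular for n, s in genome.scaffolds.items()}
        self._counter = 0

    def _split_at(self, coord: tuple[str, int], overhang: int = 0) -> str:
        """Split the fragment containing parent coordinate ``coord``.

        The coordinate must lie strictly inside (or at the start of) a
        forward-oriented fragment, i.e. in a region untouched by previous
        events — otherwise the planned events interact and we refuse.
        ``overhang`` duplicates that many bases on the right-hand piece
        (NHEJ microhomology).  Returns the scaffold holding the split.
        """
        src, pos = coord
        for name, frags in self.frags.items():
            for i, (fsrc, s, e, sign) in enumerate(frags):
                if fsrc == src and s < pos < e:
                    if sign != +1:
                        raise ValueError(
                            "event breakpoint falls in a region already "
                            "rearranged; planned events interact"
                        )
                    frags[i : i + 1] = [
                        (fsrc, s, pos, +1),
                        (fsrc, max(s, pos - overhang), e, +1),
                    ]
                    return name
                if fsrc == src and pos == s and sign == +1:
                    return name
        raise ValueError(f"breakpoint {coord} not found in any unrearranged region")

    def _index_of_start(self, coord: tuple[str, int]) -> tuple[str, int]:
        src, pos = coord
        for name, frags in self.frags.items():
            for i, (fsrc, s, e, sign) in enumerate(frags):
                if fsrc == src and sign == +1 and s in (pos, *range(pos - 10, pos)):
                    # microhomology may have shifted the start back a few bp
                    if s == pos or frags[max(i - 1, 0)][2] == pos:
                        return name, i
        raise ValueError(f"no fragment starts at {coord}")

    def reversal(self, c1: tuple[str, int], c2: tuple[str, int]) -> None:
        self._split_at(c1)
        self._split_at(c2)
        name1, i1 = self._index_of_start(c1)
        name2, i2 = self._index_of_start(c2)
        if name1 != name2:
            raise ValueError("reversal endpoints on different scaffolds")
        if i1 > i2:
            i1, i2 = i2, i1
        seg = self.frags[name1][i1:i2]
        self.frags[name1][i1:i2] = [
            (fsrc, s, e, -sign) for fsrc, s, e, sign in reversed(seg)
        ]

    def translocation(
        self,
        c1: tuple[str, int],
        c2: tuple[str, int],
        c3: tuple[str, int],
        overhang: int = 0,
    ) -> None:
        self._split_at(c1)
        self._split_at(c2)
        name1, i1 = self._index_of_start(c1)
        name2, i2 = self._index_of_start(c2)
        if name1 != name2 or i1 >= i2:
            raise ValueError("bad translocation excision interval")
        seg = self.frags[name1][i1:i2]
        del self.frags[name1][i1:i2]
        self._split_at(c3, overhang=overhang)
        name3, i3 = self._index_of_start(c3)
        self.frags[name3][i3:i3] = seg

    def fission(self, c: tuple[str, int], overhang: int = 0) -> tuple[str, str]:
        self._split_at(c, overhang=overhang)
        name, i = self._index_of_start(c)
        left = self.frags[name][:i]
        right = self.frags[name][i:]
        self._counter += 1
        n1, n2 = f"{name}a{self._counter}", f"{name}b{self._counter}"
        del self.frags[name]
        self.frags[n1], self.frags[n2] = left, right
        self.circular[n1] = self.circular[n2] = False  # products are linear
        self.circular.pop(name, None)
        return n1, n2

    def fusion(self, name1: str, name2: str) -> str:
        if name1 not in self.frags or name2 not in self.frags:
            raise ValueError("fusion scaffold not found")
        self._counter += 1
        merged = f"{name1}+{name2}"
        self.frags[merged] = self.frags.pop(name1) + self.frags.pop(name2)
        self.circular[merged] = False
        self.circular.pop(name1, None)
        self.circular.pop(name2, None)
        return merged

    def render(self, microhomology: dict | None = None) -> AnnotatedGenome:
        out = AnnotatedGenome()
        for name, frags in self.frags.items():
            parts = []
            for fsrc, s, e, sign in frags:
                sub = self.parent.scaffolds[fsrc].seq[s:e]
                parts.append(sub if sign == +1 else revcomp(sub))
            out.scaffolds[name] = Scaffold(
                name, "".join(parts), circular=self.circular.get(name, False)
            )
            # map genes wholly contained in a fragment
            offset = 0
            for fsrc, s, e, sign in frags:
                for g in self.parent.genes:
                    if g.scaffold == fsrc and s <= g.start and g.end <= e:
                        if sign == +1:
                            ns, st = offset + (g.start - s), g.strand
                        else:
                            ns = offset + (e - g.end)
                            st = "-" if g.strand == "+" else "+"
                        out.genes.append(
                            GeneFeature(g.name, g.type, name, ns, ns + g.length, st)
                        )
                offset += e - s
        return out


def _resolve_anchor_coords(
    event: PlannedEvent, ledger: dict, default_scaffold: str
) -> list[tuple[str, int]]:
    """Translate an event's anchors into parent-genome coordinates."""

    def as_coord(x) -> tuple[str, int]:
        if isinstance(x, tuple) and len(x) == 2 and isinstance(x[0], str):
            return x
        return (default_scaffold, int(x))

    fams = {f["name"]: f for f in ledger["repeat_families"]}

    if event.mechanism == "repeat_mediated":
        if event.anchor not in fams:
            raise ValueError(f"repeat family {event.anchor!r} not in ledger")
        fam = fams[event.anchor]
        if len(fam["copies"]) != 2:
            raise ValueError("repeat-mediated events need a two-copy family anchor")
        need = "inverted" if event.kind == "reversal" else "direct"
        if event.kind in ("reversal", "translocation") and fam["orientation"] != need:
            raise ValueError(
                f"repeat_mediated {event.kind} requires a {need} two-copy anchor"
            )
        mids = [
            (default_scaffold, (c["start"] + c["end"]) // 2) for c in fam["copies"]
        ]
        coords = sorted(mids, key=lambda c: c[1])
        if event.kind == "translocation":
            if event.insert in fams:
                ins_copy = fams[event.insert]["copies"][0]
                coords.append(
                    (default_scaffold, (ins_copy["start"] + ins_copy["end"]) // 2)
                )
            else:
                raise ValueError(
                    "repeat_mediated translocation needs a repeat-family insert anchor"
                )
        return coords

    # NHEJ: explicit coordinates, rejected if they fall inside a repeat copy
    raw = event.anchor if isinstance(event.anchor, (list, tuple)) else (event.anchor,)
    if event.kind == "fusion":
        return []  # anchor carries scaffold names, handled by caller
    coords = [as_coord(x) for x in raw]
    if event.kind == "translocation" and event.insert is not None:
        coords.append(as_coord(event.insert))
    for sc, pos in coords:
        for fam in fams.values():
            for c in fam["copies"]:
                if c["start"] <= pos < c["end"]:
                    raise ValueError(
                        f"NHEJ coordinate {pos} lies inside repeat copy of "
                        f"{fam['name']}; would contaminate mechanism ground truth"
                    )
    return coords


def apply_events(
    genome: AnnotatedGenome, events: list[PlannedEvent], ledger: dict
) -> tuple[AnnotatedGenome, dict]:
    """Apply planned events to ``genome``; return derived genome + new ledger.

    All anchors are resolved in the input genome's coordinates; events must
    be mutually non-interacting (distinct, non-nested breakpoint regions).
    The returned ledger extends the input ledger with one record per event
    carrying true breakpoints and, for repeat-mediated events, the repeat
    copy intervals within which the junctions are molecularly seamless.
    """
    new_ledger = json.loads(json.dumps(ledger))  # deep copy, JSON-safe
    default_scaffold = next(iter(genome.scaffolds))
    frag = _FragScaffolds(genome)
    fams = {f["name"]: f for f in ledger["repeat_families"]}

    for event in events:
        coords = _resolve_anchor_coords(event, ledger, default_scaffold)
        record = {
            "kind": event.kind,
            "mechanism": event.mechanism,
            "breakpoints": [{"scaffold": sc, "pos": pos} for sc, pos in coords],
            "recombinant_fraction": event.recombinant_fraction,
        }
        if event.mechanism == "repeat_mediated":
            fam = fams[event.anchor]
            ivs = [dict(c) for c in fam["copies"]]
            if event.kind == "translocation" and event.insert in fams:
                ivs.append(dict(fams[event.insert]["copies"][0]))
            record["anchor_family"] = event.anchor
            record["breakpoint_regions"] = ivs
        else:
            record["breakpoint_regions"] = [
                {"start": pos, "end": pos} for _, pos in coords
            ]

        mh = event.microhomology if event.mechanism == "nhej" else 0
        if event.kind == "reversal":
            frag.reversal(coords[0], coords[1])
        elif event.kind == "translocation":
            frag.translocation(coords[0], coords[1], coords[2], overhang=mh)
        elif event.kind == "fission":
            frag.fission(coords[0], overhang=mh)
        elif event.kind == "fusion":
            a, b = event.anchor
            frag.fusion(a, b)
            record["breakpoints"] = []
        new_ledger["events"].append(record)

    return frag.render(), new_ledger


def apply_event(
    genome: AnnotatedGenome, event: PlannedEvent, ledger: dict
) -> tuple[AnnotatedGenome, dict]:
    """Apply a single planned event (see :func:`apply_events`)."""
    return apply_events(genome, [event], ledger)


# --------------------------------------------------------------------------
# long reads


def _draw_lengths(rng: np.random.Generator, plan: ReadPlan, n: int) -> np.ndarray:
    mu = math.log(plan.mean_length) - plan.sigma_log**2 / 2.0
    lengths = rng.lognormal(mu, plan.sigma_log, size=n)
    return np.clip(lengths, plan.min_length, plan.max_length).astype(int)


def simulate_long_reads(
    variants: dict[str, AnnotatedGenome | str],
    fractions: dict[str, float],
    plan: ReadPlan,
    seed: int,
    span: tuple[int, int] | None = None,
    min_overhang: int = 200,
) -> list[tuple[str, str]]:
    """Draw long reads from a mixture of genome variants.

    ``variants`` maps variant name to a single-scaffold genome (or raw
    sequence); ``fractions`` must sum to 1 and per-variant read counts are
    multinomial.  Reads are drawn from circular coordinates and may wrap the
    origin.  If ``span`` is given, every read fully covers that interval
    with at least ``min_overhang`` bases on each side (used to generate
    junction-informative reads).  Substitution errors are injected at
    ``plan.error_rate``.  Returns (read id, sequence) pairs.
    """
    names = list(variants)
    fr = np.array([fractions[n] for n in names], dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    rng = _rng(seed, "reads")
    counts = rng.multinomial(plan.n_reads, fr)

    reads: list[tuple[str, str]] = []
    for name, count in zip(names, counts):
        v = variants[name]
        seq = v if isinstance(v, str) else v.sequence()
        circ = True if isinstance(v, str) else next(iter(v.scaffolds.values())).circular
        L = len(seq)
        if plan.min_length > L:
            raise ValueError("read length exceeds genome length")
        lengths = _draw_lengths(rng, plan, count)
        for ri, rl in enumerate(lengths):
            rl = int(min(rl, L))
            if span is not None:
                s0, s1 = span
                need = (s1 - s0) + 2 * min_overhang
                if need > L:
                    raise ValueError("required read length exceeds genome length")
                rl = max(rl, need)
                lo, hi = s1 + min_overhang - rl, s0 - min_overhang
                start = int(rng.integers(lo, hi + 1)) % L
            else:
                start = int(rng.integers(0, L if circ else max(1, L - rl + 1)))
            read = circ_slice(seq, start, rl) if circ else seq[start : start + rl]
            if plan.error_rate > 0:
                read = _inject_errors(rng, read, plan.error_rate)
            # half the molecules are sequenced from the other strand
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append((f"{name}_{ri}", read))
    return reads


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        reads.append((lines[i][1:].split()[0], lines[i + 1]))
    return reads


# --------------------------------------------------------------------------
# RNA editing pileups


def simulate_editing_pileup(
    genome: AnnotatedGenome,
    ledger: dict,
    depth: int = 200,
    error_rate: float = 0.0,
    seed: int = 0,
    depth_overrides: dict[int, int] | None = None,
):
    """Strand-aware per-site pileup over all annotated gene regions.

    Reads are modelled on each gene's sense strand (an rRNA-depleted,
    strand-resolved protocol abstraction).  At each planted site the
    edited-read count is Binomial(depth, rate): a C on the coding strand
    read as T (reported on the + strand as T for +-strand genes and A for
    −-strand genes).  All other positions carry only background errors.
    Returns a pandas DataFrame with 1-based positions.
    """
    import pandas as pd

    rng = _rng(seed, "pileup")
    scaffold = next(iter(genome.scaffolds))
    seq = genome.scaffolds[scaffold].seq
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    planted = {s["position"]: s for s in ledger.get("editing_sites", [])}
    gene_names = {g.name for g in genome.genes}
    for s in ledger.get("editing_sites", []):
        if s["gene"] not in gene_names:
            raise ValueError(f"editing site gene {s['gene']!r} not annotated (outside CDS)")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    rows = []
    for g in genome.genes:
        for pos in range(g.start, g.end):
            d = (depth_overrides or {}).get(pos, depth)
            ref_plus = seq[pos]
            coding_ref = ref_plus if g.strand == "+" else comp[ref_plus]
            site = planted.get(pos)
            edited = 0
            if site is not None:
                edited = int(rng.binomial(d, site["rate"]))
            # remaining reads: reference base, with background substitution errors
            base_counts = {b: 0 for b in BASES}  # counts on the coding strand
            if site is not None:
                target = "T" if site["edit_type"] == "C-to-U" else "C"
                base_counts[target] += edited
            n_ref = d - edited
            if error_rate > 0 and n_ref:
                n_err = int(rng.binomial(n_ref, error_rate))
                n_ref -= n_err
                for _ in range(n_err):
                    base_counts[rng.choice([b for b in BASES if b != coding_ref])] += 1
            base_counts[coding_ref] += n_ref

            row = {
                "scaffold": scaffold,
                "pos": pos + 1,
                "ref": ref_plus,
                "depth": d,
            }
            for b in BASES:
                row[f"{b}_fwd"] = 0
                row[f"{b}_rev"] = 0
            if g.strand == "+":
                for b in BASES:
                    row[f"{b}_fwd"] = base_counts[b]
            else:
                # sense reads are on the minus strand; report plus-strand base
                for b in BASES:
                    row[f"{comp[b]}_rev"] = base_counts[b]
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# marker matrices


def simulate_marker_matrix(
    groups: dict[str, int],
    n_markers: int = 32,
    flip_rate: float = 0.0,
    seed: int = 0,
    min_prototype_distance: int | None = None,
):
    """Binary marker-band matrix with planted group structure.

    Each group has a random prototype profile; group prototypes are
    resampled until every pair differs at >= ``min_prototype_distance``
    markers (default: a quarter of the markers, the separation a real
    mitotype panel is designed for).  Each line's profile is its prototype
    with independent bit flips at ``flip_rate``.  Returns (DataFrame
    lines x markers, ledger dict).
    """
    import pandas as pd

    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    if min_prototype_distance is None:
        min_prototype_distance = max(4, n_markers // 4)
    rng = _rng(seed, "markers")

    names = list(groups)
    for _ in range(1000):
        protos = {n: rng.integers(0, 2, size=n_markers) for n in names}
        ok = all(
            (protos[a] != protos[b]).sum() >= min_prototype_distance
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
        if ok:
            break
    else:  # pragma: no cover - essentially impossible for sane inputs
        raise ValueError("could not sample sufficiently distinct prototypes")

    rows, labels, group_of = [], [], {}
    for gname in names:
        for i in range(groups[gname]):
            line = f"{gname}_{i + 1}"
            flips = rng.random(n_markers) < flip_rate
            rows.append(np.where(flips, 1 - protos[gname], protos[gname]))
            labels.append(line)
            group_of[line] = gname
    df = pd.DataFrame(
        np.array(rows, dtype=int),
        index=labels,
        columns=[f"M{i + 1}" for i in range(n_markers)],
    )
    ledger = {
        "groups": group_of,
        "prototypes": {n: protos[n].tolist() for n in names},
        "flip_rate": flip_rate,
    }
    return df, ledger


# --------------------------------------------------------------------------
# ledger helpers


def ledger_repeat_coverage(ledger: dict) -> float:
    """Fraction of the genome covered by planted repeat copies (interval union)."""
    from .genome import interval_union_length

    ivs = [
        (c["start"], c["end"])
        for fam in ledger["repeat_families"]
        for c in fam["copies"]
    ]
    if not ivs:
        return 0.0
    return interval_union_length(ivs, ledger["genome_length"]) / ledger["genome_length"]


def write_ground_truth_gff(ledger: dict, path: str | Path) -> None:
    """Planted genes and repeat copies as GFF3 features (1-based inclusive).

    Repeat copies carry ``Parent`` pointing at their family feature so the
    family structure survives the flat format.
    """
    scaffold = ledger["scaffold"]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {scaffold} 1 {ledger['genome_length']}\n")
        for i, g in enumerate(ledger["genes"]):
            fh.write(
                f"{scaffold}\tmitovar\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID=gene{i};Name={g['name']};gene_type={g['type']}\n"
            )
        for fam in ledger["repeat_families"]:
            lo = min(c["start"] for c in fam["copies"])
            hi = max(c["end"] for c in fam["copies"])
            fh.write(
                f"{scaffold}\tmitovar\trepeat_family\t{lo + 1}\t{hi}\t.\t.\t.\t"
                f"ID={fam['name']};consensus_length={fam['consensus_length']};"
                f"orientation={fam['orientation']}\n"
            )
            for j, c in enumerate(fam["copies"]):
                fh.write(
                    f"{scaffold}\tmitovar\trepeat_region\t{c['start'] + 1}\t{c['end']}\t.\t"
                    f"{c['strand']}\t.\tID={fam['name']}.{j + 1};Parent={fam['name']}\n"
                )


def save_ledger(ledger: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)


def load_ledger(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
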