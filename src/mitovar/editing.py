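"""C-to-U (and U-to-C) RNA-editing site calling and cross-line comparison.

Plant mitochondrial transcripts are post-transcriptionally edited,
overwhelmingly C→U on the coding strand.  Sites are called from a
strand-aware per-position pileup restricted to annotated CDS: a position
is a C-to-U site when the coding-strand reference is C, the coding-strand
T support reaches both a minimum read count and a minimum rate, and the
total depth is at least ``min_depth`` (default 50 — shallower sites are
unreliable and are removed outright).  U-to-C is the mirror case
(reference T, C support).

Rates are edited reads over total depth; the rate-change threshold between
lines is absolute percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .genome import AnnotatedGenome, GeneFeature

__all__ = ["EditingSite", "LineComparison", "call_sites", "annotate_site", "compare_lines"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class EditingSite:
    scaffold: str
    position: int  # 1-based, as reported
    gene: str
    strand: str
    edit_type: str  # C-to-U | U-to-C
    depth: int
    edited_count: int
    codon_position: int | None = None
    aa_change: str | None = None  # "P->S" or "synonymous"
    warning: str | None = None

    @property
    def editing_rate(self) -> float:
        return self.edited_count / self.depth

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.scaffold, self.position, self.edit_type)


@dataclass
class LineComparison:
    status: dict[tuple, str]  # site key -> shared | new_in_line | lost_in_line
    rate_delta: dict[tuple, float]  # shared sites only
    changed: set  # shared site keys with |delta| > threshold
    summary: dict


def _strand_counts(row: pd.Series, gene_strand: str) -> dict[str, int]:
    """Base counts on the gene's coding strand from a plus-strand pileup row.

    Sense reads of a minus-strand gene are recorded in the ``*_rev``
    columns with plus-strand base identities; complementing them recovers
    the coding-strand alphabet.
    """
    if gene_strand == "+":
        return {b: int(row[f"{b}_fwd"]) for b in "ACGT"}
    return {b: int(row[f"{_COMP[b]}_rev"]) for b in "ACGT"}


def call_sites(
    pileup: pd.DataFrame,
    genes: list[GeneFeature],
    genome: AnnotatedGenome | None = None,
    min_depth: int = 50,
    min_rate: float = 0.05,
    min_edited: int = 5,
    denominator: str = "total",
) -> list[EditingSite]:
    """Call editing sites within annotated CDS from a strand-aware pileup.

    The pileup needs columns scaffold, pos (1-based), ref, depth and
    ``{A,C,G,T}_{fwd,rev}`` counts; missing strand columns raise.  With
    ``denominator="ct"`` the rate uses C+T support instead of total depth.
    If ``genome`` is given, sites are annotated with codon position and
    amino-acid change.
    """
    needed = {"scaffold", "pos", "ref", "depth"} | {
        f"{b}_{s}" for b in "ACGT" for s in ("fwd", "rev")
    }
    missing = needed - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup missing columns (strand info?): {sorted(missing)}")

    by_pos = {(r.scaffold, r.pos): r for r in pileup.itertuples(index=False)}
    sites: list[EditingSite] = []
    for g in genes:
        for gpos in range(g.start, g.end):
            row = by_pos.get((g.scaffold, gpos + 1))
            if row is None:
                continue
            row = pd.Series(row._asdict())
            depth = int(row["depth"])
            if depth < min_depth:
                continue
            coding_ref = row["ref"] if g.strand == "+" else _COMP[row["ref"]]
            counts = _strand_counts(row, g.strand)
            for ref_base, alt_base, etype in (
                ("C", "T", "C-to-U"),
                ("T", "C", "U-to-C"),
            ):
                if coding_ref != ref_base:
                    continue
                edited = counts[alt_base]
                denom = depth if denominator == "total" else counts["C"] + counts["T"]
                if denom == 0:
                    continue
                rate = edited / denom
                if edited >= min_edited and rate >= min_rate:
                    site = EditingSite(
                        scaffold=g.scaffold,
                        position=gpos + 1,
                        gene=g.name,
                        strand=g.strand,
                        edit_type=etype,
                        depth=denom,
                        edited_count=edited,
                    )
                    if genome is not None:
                        annotate_site(site, g, genome)
                    sites.append(site)
    return sites


def annotate_site(
    site: EditingSite, gene: GeneFeature, genome: AnnotatedGenome
) -> EditingSite:
    """Fill codon position and amino-acid change for a site inside ``gene``.

    Codon position is 1..3 from the strand-aware CDS offset.  The standard
    genetic code is used (plant mitochondria translate with the standard
    code); a CDS whose length is not a multiple of 3 is flagged and gets
    no amino-acid call.
    """
    gpos = site.position - 1
    if not gene.start <= gpos < gene.end:
        raise ValueError("site outside the given CDS")
    seq = genome.scaffolds[gene.scaffold].seq
    if gene.strand == "+":
        offset = gpos - gene.start
    else:
        offset = gene.end - 1 - gpos
    site.codon_position = offset % 3 + 1
    if gene.length % 3 != 0:
        site.warning = "CDS length not divisible by 3; no amino-acid call"
        return site
    cds = seq[gene.start : gene.end]
    if gene.strand == "-":
        from .genome import revcomp

        cds = revcomp(cds)
    codon_start = offset - offset % 3
    codon = list(cds[codon_start : codon_start + 3])
    ref_aa = str(Seq("".join(codon)).translate())
    codon[offset % 3] = "T" if site.edit_type == "C-to-U" else "C"
    alt_aa = str(Seq("".join(codon)).translate())
    site.aa_change = "synonymous" if ref_aa == alt_aa else f"{ref_aa}->{alt_aa}"
    return site


def compare_lines(
    maternal_sites: list[EditingSite],
    line_sites: list[EditingSite],
    rate_change_threshold: float = 0.10,
) -> LineComparison:
    """Compare a derived line's editing sites against the maternal line.

    Sites are keyed by (scaffold, position, edit type).  ``changed`` holds
    shared sites whose rate moved by more than the threshold in absolute
    percentage points.  The summary mirrors a per-line comparison table:
    edited genes/sites in the line, newly detected sites, lost sites, and
    rate-changed sites.
    """
    mat = {s.key: s for s in maternal_sites}
    lin = {s.key: s for s in line_sites}
    status: dict[tuple, str] = {}
    delta: dict[tuple, float] = {}
    changed = set()
    for key in mat.keys() | lin.keys():
        if key in mat and key in lin:
            status[key] = "shared"
            delta[key] = lin[key].editing_rate - mat[key].editing_rate
            if abs(delta[key]) > rate_change_threshold:
                changed.add(key)
        elif key in lin:
            status[key] = "new_in_line"
        else:
            status[key] = "lost_in_line"
    summary = {
        "edited_genes": len({s.gene for s in line_sites}),
        "edited_sites": len(lin),
        "new_sites": sum(1 for v in status.values() if v == "new_in_line"),
        "lost_sites": sum(1 for v in status.values() if v == "lost_in_line"),
        "changed_sites": len(changed),
    }
    return LineComparison(status=status, rate_delta=delta, changed=changed, summary=summary)
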