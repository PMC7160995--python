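"""Quantify repeat-mediated recombination from long reads.

For a two-copy repeat the four junction configurations (parental ``a-b``,
``c-d``; recombinant ``a-d``, ``c-b``) are distinguishable only by reads
that span the full repeat plus enough unique flank on both sides.  A read
is assigned to the configuration whose junction sequence it matches best
(semi-global alignment of the junction core into the read, both read
orientations), and only when the assignment is unambiguous: the best
alignment must beat the runner-up by a clear edit-distance margin and stay
under a relative error ceiling.  Everything downstream is arithmetic on
the resulting counts:

    content(config)   = reads(config) / sum over configs
    relative content  = content in derived line / content in maternal line
    recombination rate = (a-d + c-b) / total
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from .genome import revcomp
from .repeats import ALL_LABELS, RECOMBINANT_LABELS, RepeatConfiguration

__all__ = [
    "ConfigurationCounts",
    "count_configuration_reads",
    "configuration_content",
    "relative_content",
    "recombination_rate",
    "NOVEL_CONFIGURATION",
]

#: sentinel ratio for a configuration absent in the maternal line but
#: present in a derived line (a newly arisen junction)
NOVEL_CONFIGURATION = math.inf


@dataclass
class ConfigurationCounts:
    family: str
    counts: dict[str, int] = field(default_factory=lambda: {l: 0 for l in ALL_LABELS})
    ambiguous: int = 0
    uninformative: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _junction_core(conf: RepeatConfiguration, min_anchor: int) -> str:
    """Trim a junction to repeat + ``min_anchor`` bp of each flank."""
    f = conf.flank_len
    if min_anchor > f:
        raise ValueError("min_anchor exceeds flank length")
    seq = conf.junction_seq
    return seq[f - min_anchor : len(seq) - (f - min_anchor)]


def count_configuration_reads(
    reads: list[tuple[str, str]],
    configurations: list[RepeatConfiguration],
    min_anchor: int = 200,
    max_error_frac: float = 0.25,
    margin: int = 20,
) -> ConfigurationCounts:
    """Assign reads to repeat configurations of one family.

    A read is counted for a configuration iff the configuration's junction
    core (repeat + ``min_anchor`` bp of each flank) aligns inside the read
    — in either read orientation — with edit distance at most
    ``max_error_frac`` of the core length, and the runner-up configuration
    is at least ``margin`` edits worse.  Reads matching no core are
    *uninformative* (too short, or not from this locus); reads matching
    two cores within the margin are *ambiguous*.  Each read increments at
    most one counter.
    """
    if not configurations:
        raise ValueError("empty configuration set")
    fam = configurations[0].family
    cores = {c.label: _junction_core(c, min_anchor) for c in configurations}
    out = ConfigurationCounts(family=fam)

    for _, seq in reads:
        rc = revcomp(seq)
        dists = {}
        for label, core in cores.items():
            k = int(max_error_frac * len(core))
            best = math.inf
            for target in (seq, rc):
                if len(target) < len(core):
                    continue
                r = edlib.align(core, target, mode="HW", task="distance", k=k)
                if r["editDistance"] != -1:
                    best = min(best, r["editDistance"])
            dists[label] = best
        ranked = sorted(dists.items(), key=lambda kv: kv[1])
        best_label, best_d = ranked[0]
        second_d = ranked[1][1]
        if best_d is math.inf:
            out.uninformative += 1
        elif second_d - best_d < margin:
            out.ambiguous += 1
        else:
            out.counts[best_label] += 1
    return out


def configuration_content(counts: ConfigurationCounts) -> dict[str, float] | None:
    """Per-configuration proportions; ``None`` (missing) when no reads mapped."""
    total = counts.total
    if total == 0:
        return None
    return {label: c / total for label, c in counts.counts.items()}


def relative_content(
    bil_content: dict[str, float], maternal_content: dict[str, float]
) -> dict[str, float | None]:
    """Ratio of configuration content, derived line over maternal.

    A configuration absent in the maternal line but present in the derived
    line is a newly arisen junction and reported as ``NOVEL_CONFIGURATION``
    (infinity); absent in both is ``None`` (missing).
    """
    if set(bil_content) != set(maternal_content):
        raise ValueError("configuration labels differ between lines")
    out: dict[str, float | None] = {}
    for label in bil_content:
        b, m = bil_content[label], maternal_content[label]
        if m == 0:
            out[label] = NOVEL_CONFIGURATION if b > 0 else None
        else:
            out[label] = b / m
    return out


def recombination_rate(counts: ConfigurationCounts) -> float | None:
    """Fraction of informative reads carrying a recombinant junction."""
    total = counts.total
    if total == 0:
        return None
    rec = sum(counts.counts[l] for l in RECOMBINANT_LABELS)
    return rec / total
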