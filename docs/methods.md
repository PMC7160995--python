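# Methods

This note documents the models and procedures implemented in `mitovar`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical/design choices made
where several reasonable options existed.

## Repeat detection and configurations

Detection is exact-seed matching (default seed = 50 bp, equal to the
reporting floor `min_len = 50`) with seeds on a shared diagonal merged
into maximal runs, followed — when `min_identity < 1` — by ungapped X-drop
extension (match +1, mismatch −3, drop 15) and an identity check over the
extended match.  Copies are clustered at ≥ 50% reciprocal overlap and
families built by single linkage over pairwise matches; a family's
consensus length is the median copy length, its size class *large*
(> 1000 bp) or *intermediate* (50–1000 bp), its copy class two-/three-/
multi-copy.  Circularity is handled by scanning the doubled sequence and
mapping hits back modulo the genome length.

Explicit length/identity thresholds replace E-value criteria deliberately:
E-values depend on database size and are not reproducible parameters.
With exact 50 bp seeds, copies below ~90% identity can escape detection
when no clean 50-mer survives; planted-truth validation uses identity 1.0
and a spot check at 0.97.  Tandem arrays and microsatellites are out of
scope.

A two-copy family defines four junction configurations.  Flanks are read
in each copy's own orientation (for an inverted copy the genomic
downstream flank, reverse-complemented, is its upstream flank), so
crossover between the copies always swaps downstream flanks: parental
`a-b`/`c-d`, recombinant `a-d`/`c-b`, for direct and inverted families
alike.  Default flank length 500 bp — junction sequences must be long
enough that a long read can anchor on both sides, short enough that
typical reads span them.  A configuration set is rejected when a flank is
not unique in the genome or a copy sits at a linear scaffold end with
insufficient flank; such repeats are reported undetectable rather than
silently assayed.

## Read assignment and recombination statistics

A read supports a configuration if the configuration's *core* — the
repeat plus `min_anchor` (default 200) bp of each flank — aligns inside
the read, in either read orientation, with edit distance at most 25% of
the core length (semi-global alignment, edlib).  The winning configuration
must beat the runner-up by ≥ 20 edits; otherwise the read is counted
*ambiguous*.  Reads matching no core are *uninformative*.  Each read
increments exactly one counter.  The 200 bp anchor tolerates ragged read
ends while excluding repeat-only reads; the margin of 20 edits is far
smaller than the distance between junctions that differ by a whole flank,
so assignment is effectively exact for reads at ≤ a few percent error.

Content, relative content and recombination rate are ratios of these
counts.  A configuration with zero maternal content but positive derived
content is reported as a *novel configuration* (infinite relative
content) rather than an arbitrary large number; a family with zero
informative reads is reported *missing*, never as rate 0.  Long reads are
counted as single molecules; no read-pair mode is implemented.

## Synteny blocks and rearrangement

Anchors are 30-mers unique in both genomes counting both strands.
Anchors sharing a strand and a diagonal (tolerance 30 bp, positional gaps
up to 5 kb — enough to bridge anchor deserts caused by two-copy repeats up
to that size) are chained; chain ends are extended base-by-base while the
sequences agree, overlaps between neighbouring blocks are split at the
midpoint, and blocks shorter than 500 bp (the conventional
locally-collinear-block cutoff for organelle comparisons) are dropped.
Scaffolds are treated as linear for alignment, matching how assembly
scaffolds are compared in practice.  The chaining assumes essentially
indel-free homologous segments, which holds for assemblies of the same
pedigree and for the simulator; a diverged-species comparison would need a
gapped aligner in front.

Blocks numbered by genome-A order give genome B as a signed permutation.
Reversal distance is the exact Hannenhalli–Pevzner formula
`d = (n+1) − c + h + f` computed on the breakpoint graph: `c` cycles;
hurdles `h` = unoriented components minimal under span containment, plus
the greatest component if it strictly contains all other unoriented
components; a superhurdle's removal does not reduce the hurdle count, and
`f = 1` iff `h` is odd and every hurdle is a superhurdle.  The
implementation is validated exhaustively against breadth-first search over
the reversal Cayley graph for *every* signed permutation of n ≤ 6 and
against random n = 7 permutations.  `sort_by_reversals` finds a minimal
scenario by scanning candidate reversals in (left, right) endpoint order
and applying the first that reduces the exact distance — deterministic,
and guaranteed to terminate in exactly `d` steps.

Event classification is strip-based: scaffold-count differences give
fission/fusion counts; B scaffolds are ordered by the median A-position of
their blocks (robust to the occasional translocated block) and
concatenated; maximal negative strips are reversals; after conceptually
re-inverting them in place, strips outside a longest increasing
subsequence are translocations.  For mutually non-interacting events this
equals the minimum event count in a reversal + translocation +
fission/fusion model and each inferred event's boundaries coincide with
the planted junctions.  **Limitation:** heavily interacting events (one
event's breakpoints inside another's affected span) can be summarised
more coarsely than a minimal multichromosomal scenario; the package does
not implement the full capped-concatenate multichromosomal construction.

HRBs are block edges in genome-A coordinates; edges at scaffold
extremities are flagged and excluded from statistics, and edges of
adjacent blocks within 50 bp merge into one boundary.  HRB–repeat
proximity uses a 50 bp window, and mechanism attribution calls an event
repeat-mediated iff *all* its usable boundaries lie within that window of
a repeat copy — NHEJ otherwise, *undetermined* if no boundary is usable.
Junctions created inside repeat copies are molecularly seamless, so block
edges land inside or at the edge of the copy; the ±50 bp window and the
ledger's breakpoint *regions* (the anchoring copy intervals) account for
this irreducible localisation limit.

## Gene-level comparisons

Gene names are case-folded with anticodon qualifiers normalised
(`trnE (TTC)` → `trne-ttc`).  Copy number is feature count per name;
"increased" means strictly above the maternal count.  Gene-cluster change
uses k = 4 windows (the span of the documented cluster conversions) of
the circular signed gene order, with a window and its reverse complement
identified; what constitutes a "cluster" has no field-standard definition,
so the k-window operationalisation is exposed as a parameter.  Gene–repeat
proximity is edge-to-edge circular distance with a 2 kb window.
Paternal-specific sequence is the complement of 20-mer-level sharing
(maximal intervals ≥ `min_len` containing no exact ≥ 20 bp match to the
reference, either strand); fragment screening requires ≥ 95% identity over
≥ 90% of the fragment via semi-global alignment of the fragment and of
its central 90%.

## Mitotype clustering

Marker bands are unit characters (1/0).  The default distance is simple
matching — dominant agarose-band markers make shared absence informative —
with Jaccard as an alternative.  Neighbour joining is delegated to
scikit-bio; negative branch lengths (an NJ artefact on non-additive
matrices) are clamped to zero; the tree is rerooted at the neighbour of
the alphabetically first tip and children sorted by smallest tip label,
so identical matrices yield byte-identical Newick.  On additive matrices
NJ path lengths reproduce the input distances exactly (tested to 1e-6).
No bootstrap support is computed.

## RNA editing

A CDS position is a C-to-U site iff the coding-strand reference is C and
coding-strand T support has ≥ `min_edited` = 5 reads and rate ≥
`min_rate` = 0.05, with total depth ≥ `min_depth` = 50; positions below
the depth floor are removed outright.  U-to-C is symmetric.  The rate
denominator is total depth by default (`denominator="ct"` switches to
C+T support).  The 5-read/5% floors make "newly detected site" a
well-defined event rather than noise; they are exposed in the API.  Codon
position is the strand-aware CDS offset mod 3 + 1; amino-acid changes use
the standard genetic code (plant mitochondria translate with the standard
code); CDS lengths not divisible by 3 are flagged and get no amino-acid
call.  Line comparison keys sites by (scaffold, position, edit type);
"changed" means the rate moved by more than 10 absolute percentage
points.  The caller takes the line's own genome as reference, so
DNA-level variants do not masquerade as editing.

## The synthetic-data generator

`simgen` emulates the study design the analyses are built for: a ~50–400
kb circular genome (default scale in tests 40–120 kb to keep suites
fast), planted repeat families in both size classes with controllable
orientation, identity and intra-family spacing, genes kept ≥ 700 bp from
other features so flanks stay unique, derived genomes produced by
fragment-algebra events whose breakpoints are recorded in maternal
coordinates, log-normal long reads (mean ≈ 8 kb, truncated to 1–20 kb)
drawn from circular coordinates with uniform substitution errors,
strand-aware editing pileups with binomial edited counts, and binary
marker matrices with group prototypes and independent bit flips.  One RNG
stream per artifact is derived from the master seed and a stable label,
so outputs are byte-reproducible and adding one artifact does not shift
another.

Deliberate idealisations: substitution-only errors (no indels, no PacBio
error kinetics), uniform read start positions, sense-strand-only RNA
reads, no chimeric reads, no nuclear genome.  Consequently, passing tests
demonstrate the *logic* of the pipeline — not robustness to indel-heavy
raw long reads or to assembly errors, which real applications must bring
from their assembler/aligner.  Repeat-mediated translocations are
modelled as excision between direct-repeat copy midpoints with
reintegration at the midpoint of a third repeat copy: all three junctions
lie in repeat sequence, which is the defining observable of a
repeat-mediated event here; the two-step molecular mechanism itself is
abstracted.  NHEJ junctions carry 0 bp microhomology by default
(configurable 0–10 bp) so mechanism ground truth stays unambiguous.
Heteroplasmy (`recombinant_fraction`) is a free parameter with no
asserted biological default.

## Validation scales

The test suite and `scripts/acceptance.py` use: all 46,080 signed
permutations of n = 6 (and everything below) plus 200 random n = 7 for
distance verification; 1000 random permutations n ≤ 8 for scenario
replay; 20 simulations with 1–6 planted events on 120 kb genomes for
event/mechanism recovery; 3 × 20 recombination assays at 2000 reads for
rate recovery plus a 20-seed error-bearing null; 50 planted editing sites
at depth 200; 20-seed marker-matrix monophyly; and a 3-fragment,
2-derived-line specificity screen.  These sizes were chosen as the
smallest at which the binomial/combinatorial guarantees being tested are
sharp.
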