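"""Reversal distance, scenarios, synteny blocks, events, HRBs, mechanisms."""

import numpy as np
import pytest

from mitovar import simgen
from mitovar.genome import AnnotatedGenome, Scaffold, revcomp
from mitovar.rearrange import (
    apply_reversal,
    attribute_mechanism,
    blocks_to_signed_permutation,
    build_synteny_blocks,
    classify_events,
    extract_hrbs,
    hrb_repeat_proximity,
    reversal_distance,
    sort_by_reversals,
)
from mitovar.repeats import find_repeats

from conftest import pick_nhej_sites
from oracles import bfs_reversal_table


# ---------------------------------------------------------------- distance


def test_identity_has_distance_zero():
    assert reversal_distance((1, 2, 3)) == 0
    assert reversal_distance(()) == 0


def test_single_reversal_cases():
    assert reversal_distance((-2, -1)) == 1
    assert reversal_distance((-1, 2, 3)) == 1
    assert reversal_distance((1, -3, -2, 4)) == 1


def test_transposed_pair_needs_three_reversals():
    # BFS over all n=2 signed permutations confirms there is no 2-step path
    table = bfs_reversal_table(2)
    assert table[(2, 1)] == 3
    assert reversal_distance((2, 1)) == 3


@pytest.mark.parametrize("n", [3, 4, 5])
def test_distance_matches_bfs_for_all_small_permutations(n):
    table = bfs_reversal_table(n)
    for p, d in table.items():
        assert reversal_distance(p) == d, p


def test_distance_properties_on_random_permutations():
    rng = np.random.default_rng(50)
    table = bfs_reversal_table(5)
    for _ in range(100):
        n = 5
        mags = rng.permutation(n) + 1
        signs = rng.choice([-1, 1], n)
        p = tuple(int(m * s) for m, s in zip(mags, signs))
        d = reversal_distance(p)
        # d(pi) == d(pi^-1)
        inv = [0] * n
        for i, x in enumerate(p):
            inv[abs(x) - 1] = (i + 1) * (1 if x > 0 else -1)
        assert reversal_distance(tuple(inv)) == d
        # agreement with BFS and breakpoint lower bound
        assert d == table[p]
        assert (d == 0) == (p == tuple(range(1, n + 1)))


def test_duplicate_block_ids_rejected():
    with pytest.raises(ValueError):
        reversal_distance((1, 1, 2))


# ---------------------------------------------------------------- scenarios


def test_identity_scenario_is_empty():
    sc = sort_by_reversals((1, 2, 3, 4))
    assert sc.distance == 0 and sc.events == []


def test_negative_pair_sorted_in_one_step():
    sc = sort_by_reversals((-2, -1))
    assert sc.distance == 1 and sc.events == [(0, 1)]


def test_scenarios_replay_to_identity_with_minimal_length():
    rng = np.random.default_rng(51)
    table = {n: bfs_reversal_table(n) for n in (4, 5)}
    for _ in range(60):
        n = int(rng.integers(4, 6))
        mags = rng.permutation(n) + 1
        signs = rng.choice([-1, 1], n)
        p = tuple(int(m * s) for m, s in zip(mags, signs))
        sc = sort_by_reversals(p)
        assert sc.distance == table[n][p]
        q = p
        for i, j in sc.events:
            q = apply_reversal(q, i, j)
        assert q == tuple(range(1, n + 1))


# ---------------------------------------------------------------- blocks


def _genome_from_seq(seq, name="mt1", circular=True):
    return AnnotatedGenome(scaffolds={name: Scaffold(name, seq, circular)})


def test_identical_genomes_give_one_full_length_block():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=20000, seed=60))
    blocks = build_synteny_blocks(g, g)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.sign == 1 and b.start_a == 0 and b.end_a == 20000
    perm = blocks_to_signed_permutation(blocks)
    assert perm.flat == [1]


def test_single_inverted_segment_gives_three_blocks_middle_negative():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=60000, seed=61))
    s = g.sequence()
    lo, hi = 20000, 50000  # 30 kb inversion
    derived = _genome_from_seq(s[:lo] + revcomp(s[lo:hi]) + s[hi:], "d1")
    blocks = build_synteny_blocks(g, derived)
    assert len(blocks) == 3
    assert [b.sign for b in blocks] == [1, -1, 1]
    assert abs(blocks[1].start_a - lo) <= 50 and abs(blocks[1].end_a - hi) <= 50
    perm = blocks_to_signed_permutation(blocks)
    assert perm.flat == [1, -2, 3]


def test_shared_segment_below_cutoff_gives_no_blocks():
    rng = np.random.default_rng(62)
    bases = np.array(list("ACGT"))
    a = "".join(bases[rng.integers(0, 4, 6000)])
    b = "".join(bases[rng.integers(0, 4, 6000)])
    shared = a[1000:1400]  # 400 bp < 500 cutoff
    gb = _genome_from_seq(b[:3000] + shared + b[3000:], "other")
    blocks = build_synteny_blocks(_genome_from_seq(a), gb, min_block=500)
    assert blocks == []
    # no shared sequence at all is also a valid empty result
    assert build_synteny_blocks(_genome_from_seq(a), _genome_from_seq(b, "b")) == []


def test_permutation_extraction_from_planted_translocation():
    spec = simgen.SimSpec(
        genome_length=60000,
        repeat_plan=[
            simgen.RepeatPlan(600, 2, "direct", name="RD", spacing=4000),
            simgen.RepeatPlan(400, 2, "direct", name="RI"),
        ],
        seed=63,
    )
    g, led = simgen.generate_genome(spec)
    d, _ = simgen.apply_events(
        g,
        [simgen.PlannedEvent("translocation", "repeat_mediated", anchor="RD", insert="RI")],
        led,
    )
    perm = blocks_to_signed_permutation(build_synteny_blocks(g, d))
    flat = perm.flat
    assert sorted(abs(x) for x in flat) == list(range(1, len(flat) + 1))
    assert flat != sorted(flat)  # order actually changed
    assert all(x > 0 for x in flat)  # translocation preserves orientation


def test_overlapping_blocks_rejected_in_permutation():
    from mitovar.rearrange import SyntenyBlock

    blocks = [
        SyntenyBlock(1, "a", 0, 1000, "b", 0, 1000, 1),
        SyntenyBlock(2, "a", 500, 1500, "b", 1500, 2500, 1),
    ]
    with pytest.raises(ValueError):
        blocks_to_signed_permutation(blocks)


# ---------------------------------------------------------------- events


def _sim_with_events(seed, kinds=("reversal", "translocation", "fission")):
    spec = simgen.SimSpec(
        genome_length=90000,
        repeat_plan=[
            simgen.RepeatPlan(900, 2, "inverted", name="RINV", spacing=5000),
            simgen.RepeatPlan(700, 2, "direct", name="RDIR", spacing=4000),
            simgen.RepeatPlan(400, 2, "direct", name="RINS"),
        ],
        seed=seed,
    )
    g, led = simgen.generate_genome(spec)
    rng = np.random.default_rng(seed + 7)
    nhej = pick_nhej_sites(led, 2, rng)
    events = []
    if "reversal" in kinds:
        events.append(simgen.PlannedEvent("reversal", "repeat_mediated", anchor="RINV"))
    if "translocation" in kinds:
        events.append(
            simgen.PlannedEvent(
                "translocation", "repeat_mediated", anchor="RDIR", insert="RINS"
            )
        )
    if "fission" in kinds:
        events.append(simgen.PlannedEvent("fission", "nhej", anchor=(nhej[0],)))
    d, led2 = simgen.apply_events(g, events, led)
    return g, d, led2


def test_single_planted_reversal_classified():
    g, d, led = _sim_with_events(70, kinds=("reversal",))
    blocks = build_synteny_blocks(g, d)
    tally, events = classify_events(blocks, g, d)
    assert tally == {"reversal": 1, "translocation": 0, "fusion": 0, "fission": 0}


def test_planted_fission_counted_from_scaffolds():
    g, d, led = _sim_with_events(71, kinds=("fission",))
    blocks = build_synteny_blocks(g, d)
    tally, events = classify_events(blocks, g, d)
    assert tally["fission"] == 1 and tally["reversal"] == 0


def test_mixed_events_tally_matches_plant():
    g, d, led = _sim_with_events(72)
    blocks = build_synteny_blocks(g, d)
    tally, events = classify_events(blocks, g, d)
    assert tally == {"reversal": 1, "translocation": 1, "fusion": 0, "fission": 1}


def test_fusion_detected_from_scaffold_count_drop():
    g, d, led = _sim_with_events(73, kinds=("fission",))
    names = list(d.scaffolds)
    fused, _ = simgen.apply_events(
        d, [simgen.PlannedEvent("fusion", "nhej", anchor=(names[1], names[0]))], led
    )
    blocks = build_synteny_blocks(d, fused)
    tally, _ = classify_events(blocks, d, fused)
    assert tally["fusion"] == 1


# ---------------------------------------------------------------- HRBs


def test_identity_alignment_has_no_interior_hrbs():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=20000, seed=74))
    blocks = build_synteny_blocks(g, g)
    hrbs = extract_hrbs(blocks, g)
    assert all(h.at_scaffold_end for h in hrbs)


def test_single_interior_inversion_yields_two_usable_hrbs():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=60000, seed=75))
    s = g.sequence()
    derived = _genome_from_seq(s[:20000] + revcomp(s[20000:45000]) + s[45000:], "d1")
    blocks = build_synteny_blocks(g, derived)
    hrbs = [h for h in extract_hrbs(blocks, g) if not h.at_scaffold_end]
    assert len(hrbs) == 2
    for h in hrbs:  # edges land at the cuts up to chance single-base matches
        assert min(abs(h.position - 20000), abs(h.position - 45000)) <= 5


def test_hrbs_fall_within_planted_breakpoint_regions():
    g, d, led = _sim_with_events(76)
    blocks = build_synteny_blocks(g, d)
    hrbs = [h for h in extract_hrbs(blocks, g) if not h.at_scaffold_end]
    regions = [
        (r["start"] - 50, r["end"] + 50)
        for e in led["events"]
        for r in e["breakpoint_regions"]
    ]
    for h in hrbs:
        assert any(lo <= h.position <= hi for lo, hi in regions), h


def test_hrb_proximity_fractions():
    g, d, led = _sim_with_events(77)
    blocks = build_synteny_blocks(g, d)
    hrbs = extract_hrbs(blocks, g)
    fams = find_repeats(g)
    prox = hrb_repeat_proximity(hrbs, fams, window=50)
    usable = [h for h in hrbs if not h.at_scaffold_end]
    # exactly the NHEJ fission cut (one merged boundary pair) is repeat-free
    assert prox is not None and 0.0 < prox < 1.0
    assert hrb_repeat_proximity([h for h in hrbs if h.at_scaffold_end], fams) is None


# ---------------------------------------------------------------- mechanism


def test_mechanism_attribution_on_mixed_events():
    g, d, led = _sim_with_events(78)
    blocks = build_synteny_blocks(g, d)
    tally, events = classify_events(blocks, g, d)
    fams = find_repeats(g)
    hrbs = extract_hrbs(blocks, g)
    attribute_mechanism(events, hrbs, fams, window=50)
    got = {e.kind: e.mechanism for e in events}
    assert got["reversal"] == "repeat_mediated"
    assert got["translocation"] == "repeat_mediated"
    assert got["fission"] == "nhej"


def test_nhej_reversal_attributed_nhej():
    g, led = simgen.generate_genome(
        simgen.SimSpec(
            genome_length=60000,
            repeat_plan=[simgen.RepeatPlan(600, 2, "direct", name="R")],
            seed=79,
        )
    )
    rng = np.random.default_rng(80)
    c1, c2 = pick_nhej_sites(led, 2, rng, min_gap=8000)
    lo, hi = sorted((c1, c2))
    ev = simgen.PlannedEvent("reversal", "nhej", anchor=(lo, hi))
    d, led2 = simgen.apply_events(g, [ev], led)
    blocks = build_synteny_blocks(g, d)
    tally, events = classify_events(blocks, g, d)
    attribute_mechanism(events, extract_hrbs(blocks, g), find_repeats(g))
    assert tally["reversal"] == 1
    assert [e.mechanism for e in events if e.kind == "reversal"] == ["nhej"]
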