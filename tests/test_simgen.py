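"""Synthetic-data generator: determinism, planted ground truth, conservation."""

import numpy as np
import pytest

from mitovar import simgen
from mitovar.genome import revcomp


def test_identical_spec_and_seed_give_identical_outputs():
    spec = lambda: simgen.SimSpec(
        genome_length=20000,
        repeat_plan=[simgen.RepeatPlan(500, 2, "inverted")],
        gene_plan=[simgen.GenePlan("atp6", 600)],
        editing_plan=[simgen.EditingPlan("atp6", 10, 0.5)],
        seed=77,
    )
    g1, l1 = simgen.generate_genome(spec())
    g2, l2 = simgen.generate_genome(spec())
    assert g1.sequence() == g2.sequence()
    assert l1 == l2
    r1 = simgen.simulate_long_reads({"p": g1}, {"p": 1.0}, simgen.ReadPlan(50, 3000), 5)
    r2 = simgen.simulate_long_reads({"p": g2}, {"p": 1.0}, simgen.ReadPlan(50, 3000), 5)
    assert r1 == r2
    p1 = simgen.simulate_editing_pileup(g1, l1, depth=60, seed=5)
    p2 = simgen.simulate_editing_pileup(g2, l2, depth=60, seed=5)
    assert p1.equals(p2)


def test_empty_plan_gives_random_genome_and_empty_ledger():
    g, led = simgen.generate_genome(simgen.SimSpec(genome_length=10000, seed=1))
    assert g.length == 10000
    assert led["repeat_families"] == [] and led["genes"] == []


def test_planted_inverted_pair_recorded_in_ledger():
    spec = simgen.SimSpec(
        genome_length=20000,
        repeat_plan=[simgen.RepeatPlan(1200, 2, "inverted")],
        seed=3,
    )
    g, led = simgen.generate_genome(spec)
    fam = led["repeat_families"][0]
    assert len(fam["copies"]) == 2
    assert fam["orientation"] == "inverted"
    c1, c2 = fam["copies"]
    s = g.sequence()
    assert s[c2["start"] : c2["end"]] == revcomp(s[c1["start"] : c1["end"]])


def test_repeat_plan_reaching_24_percent_coverage():
    # mirrors the repeat load of a real rice mitogenome at reduced scale
    plan = [simgen.RepeatPlan(1200, 2, "direct") for _ in range(8)]
    plan += [simgen.RepeatPlan(400, 2, "direct") for _ in range(18)]
    spec = simgen.SimSpec(genome_length=140000, repeat_plan=plan, seed=4)
    g, led = simgen.generate_genome(spec)
    cov = simgen.ledger_repeat_coverage(led)
    want = (8 * 2 * 1200 + 18 * 2 * 400) / 140000
    assert cov == pytest.approx(want, abs=1e-9)
    assert cov == pytest.approx(0.24, abs=0.01)


def test_infeasible_packing_raises():
    spec = simgen.SimSpec(
        genome_length=5000, repeat_plan=[simgen.RepeatPlan(2000, 3)], seed=0
    )
    with pytest.raises(simgen.PackingError):
        simgen.generate_genome(spec)


# ---------------------------------------------------------------- events


def test_reversal_reverse_complements_segment_between_copy_midpoints():
    spec = simgen.SimSpec(
        genome_length=30000,
        repeat_plan=[simgen.RepeatPlan(1000, 2, "inverted", name="R", spacing=5000)],
        seed=6,
    )
    g, led = simgen.generate_genome(spec)
    ev = simgen.PlannedEvent("reversal", "repeat_mediated", anchor="R")
    d, led2 = simgen.apply_events(g, [ev], led)
    m1, m2 = (b["pos"] for b in led2["events"][0]["breakpoints"])
    s, ds = g.sequence(), d.sequence()
    assert ds == s[:m1] + revcomp(s[m1:m2]) + s[m2:]
    assert len(ds) == len(s)


def test_reversal_applied_twice_is_involution():
    spec = simgen.SimSpec(
        genome_length=25000,
        repeat_plan=[simgen.RepeatPlan(800, 2, "inverted", name="R", spacing=4000)],
        seed=8,
    )
    g, led = simgen.generate_genome(spec)
    ev = simgen.PlannedEvent("reversal", "repeat_mediated", anchor="R")
    d, led2 = simgen.apply_events(g, [ev], led)
    dd, _ = simgen.apply_events(d, [ev], led2)
    assert dd.sequence() == g.sequence()


def test_nhej_fission_conserves_total_length():
    g, led = simgen.generate_genome(simgen.SimSpec(genome_length=15000, seed=9))
    ev = simgen.PlannedEvent("fission", "nhej", anchor=(7000,))
    d, led2 = simgen.apply_events(g, [ev], led)
    assert len(d.scaffolds) == 2
    assert sum(len(s) for s in d.scaffolds.values()) == 15000
    assert all(not s.circular for s in d.scaffolds.values())


def test_nhej_breakpoint_inside_repeat_rejected():
    spec = simgen.SimSpec(
        genome_length=20000, repeat_plan=[simgen.RepeatPlan(1000, 2, name="R")], seed=2
    )
    g, led = simgen.generate_genome(spec)
    inside = led["repeat_families"][0]["copies"][0]["start"] + 10
    with pytest.raises(ValueError, match="inside repeat"):
        simgen.apply_events(
            g, [simgen.PlannedEvent("fission", "nhej", anchor=(inside,))], led
        )


def test_repeat_mediated_reversal_requires_inverted_anchor():
    spec = simgen.SimSpec(
        genome_length=20000, repeat_plan=[simgen.RepeatPlan(800, 2, "direct", name="R")], seed=2
    )
    g, led = simgen.generate_genome(spec)
    with pytest.raises(ValueError, match="inverted"):
        simgen.apply_events(
            g, [simgen.PlannedEvent("reversal", "repeat_mediated", anchor="R")], led
        )


def test_genes_carried_through_events_with_strand_flip():
    spec = simgen.SimSpec(
        genome_length=30000,
        repeat_plan=[simgen.RepeatPlan(800, 2, "inverted", name="R", spacing=6000)],
        gene_plan=[simgen.GenePlan("atp6", 700)],
        seed=12,
    )
    g, led = simgen.generate_genome(spec)
    ev = simgen.PlannedEvent("reversal", "repeat_mediated", anchor="R")
    d, led2 = simgen.apply_events(g, [ev], led)
    m1, m2 = (b["pos"] for b in led2["events"][0]["breakpoints"])
    (g0,) = g.genes
    (g1,) = d.genes
    ds = d.sequence()
    sub = ds[g1.start : g1.end]
    orig = g.sequence()[g0.start : g0.end]
    if m1 <= g0.start and g0.end <= m2:  # gene inside the inverted segment
        assert g1.strand != g0.strand and sub == revcomp(orig)
    else:
        assert g1.strand == g0.strand and sub == orig


# ---------------------------------------------------------------- reads


def test_error_free_reads_are_circular_substrings():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=12000, seed=13))
    plan = simgen.ReadPlan(n_reads=40, mean_length=3000, min_length=1000)
    reads = simgen.simulate_long_reads({"p": g}, {"p": 1.0}, plan, seed=1)
    doubled = g.sequence() * 2
    for _, seq in reads:
        assert seq in doubled or revcomp(seq) in doubled


def test_reads_can_wrap_the_origin():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=5000, seed=14))
    plan = simgen.ReadPlan(n_reads=300, mean_length=2000, min_length=1500, max_length=2500)
    reads = simgen.simulate_long_reads({"p": g}, {"p": 1.0}, plan, seed=2)
    linear = g.sequence()
    wrapped = [
        s for _, s in reads if s not in linear and revcomp(s) not in linear
    ]
    assert wrapped  # some reads must cross the origin
    doubled = linear * 2
    assert all(s in doubled or revcomp(s) in doubled for s in wrapped)


def test_mixture_read_counts_are_binomial():
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=12000, seed=15))
    g2 = g.copy()
    n, p = 2000, 0.3
    plan = simgen.ReadPlan(n_reads=n, mean_length=2000)
    reads = simgen.simulate_long_reads({"par": g, "rec": g2}, {"par": 0.7, "rec": p}, plan, seed=3)
    n_rec = sum(1 for rid, _ in reads if rid.startswith("rec"))
    sigma = (n * p * (1 - p)) ** 0.5
    assert abs(n_rec - n * p) < 3 * sigma


def test_zero_reads_gives_empty_output(tmp_path):
    g, _ = simgen.generate_genome(simgen.SimSpec(genome_length=6000, seed=16))
    reads = simgen.simulate_long_reads(
        {"p": g}, {"p": 1.0}, simgen.ReadPlan(n_reads=0), seed=4
    )
    assert reads == []
    out = tmp_path / "empty.fastq"
    simgen.write_fastq(reads, out)
    assert out.read_text() == ""


# ---------------------------------------------------------------- pileups


def _editing_genome(seed=17):
    spec = simgen.SimSpec(
        genome_length=15000,
        gene_plan=[simgen.GenePlan("atp6", 600), simgen.GenePlan("nad5", 600, "-")],
        editing_plan=[
            simgen.EditingPlan("atp6", 50, 0.355),
            simgen.EditingPlan("nad5", 30, 1.0),
        ],
        seed=seed,
    )
    return simgen.generate_genome(spec)


def test_pileup_without_editing_or_errors_has_no_mismatches():
    spec = simgen.SimSpec(
        genome_length=10000, gene_plan=[simgen.GenePlan("atp6", 300)], seed=18
    )
    g, led = simgen.generate_genome(spec)
    pu = simgen.simulate_editing_pileup(g, led, depth=100, error_rate=0.0, seed=1)
    seq = g.sequence()
    for row in pu.itertuples(index=False):
        counts = {b: getattr(row, f"{b}_fwd") + getattr(row, f"{b}_rev") for b in "ACGT"}
        assert counts[seq[row.pos - 1]] == 100
        assert sum(counts.values()) == 100


def test_rate_one_site_fully_edited():
    g, led = _editing_genome()
    pu = simgen.simulate_editing_pileup(g, led, depth=100, seed=2)
    site = next(s for s in led["editing_sites"] if s["rate"] == 1.0)
    row = pu[pu["pos"] == site["position"] + 1].iloc[0]
    # minus-strand gene: edited base shows as A on the plus strand, rev reads
    assert row["A_rev"] == 100


def test_planted_rate_recovered_within_3_sigma():
    g, led = _editing_genome()
    pu = simgen.simulate_editing_pileup(g, led, depth=1000, seed=3)
    site = next(s for s in led["editing_sites"] if s["rate"] == 0.355)
    row = pu[pu["pos"] == site["position"] + 1].iloc[0]
    frac = row["T_fwd"] / 1000
    sigma = (0.355 * 0.645 / 1000) ** 0.5
    assert abs(frac - 0.355) < 3 * sigma


# ---------------------------------------------------------------- markers


def test_zero_flip_rate_reproduces_prototypes():
    df, led = simgen.simulate_marker_matrix({"A": 4, "B": 4}, 32, 0.0, seed=5)
    for line, grp in led["groups"].items():
        assert df.loc[line].tolist() == led["prototypes"][grp]


def test_within_group_hamming_matches_resampling_oracle():
    n_markers, flip = 32, 0.05
    df, led = simgen.simulate_marker_matrix({"A": 30, "B": 30}, n_markers, flip, seed=6)
    a_lines = [l for l, g in led["groups"].items() if g == "A"]
    dists = [
        (df.loc[x] != df.loc[y]).sum()
        for i, x in enumerate(a_lines)
        for y in a_lines[i + 1 :]
    ]
    observed = np.mean(dists)
    # resampling oracle: distance between two independently flipped copies
    rng = np.random.default_rng(0)
    sims = []
    for _ in range(3000):
        f1 = rng.random(n_markers) < flip
        f2 = rng.random(n_markers) < flip
        sims.append((f1 != f2).sum())
    expected = np.mean(sims)
    assert abs(observed - expected) < 0.6  # both ≈ 2·32·0.05·0.95 = 3.04


def test_marker_matrix_needs_two_groups():
    with pytest.raises(ValueError):
        simgen.simulate_marker_matrix({"A": 5}, 16, 0.0, seed=1)
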