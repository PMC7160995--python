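import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mitovar import simgen


@pytest.fixture(scope="session")
def basic_genome():
    """A 60 kb circular genome with mixed repeat families and genes."""
    spec = simgen.SimSpec(
        genome_length=60000,
        repeat_plan=[
            simgen.RepeatPlan(1200, 2, "inverted", name="RINV"),
            simgen.RepeatPlan(300, 2, "direct", name="RDIR"),
            simgen.RepeatPlan(600, 3, "direct", name="R3"),
        ],
        gene_plan=[
            simgen.GenePlan("atp6", 900),
            simgen.GenePlan("nad5", 1200, "-"),
            simgen.GenePlan("cox1", 1500),
        ],
        seed=101,
    )
    return simgen.generate_genome(spec)


def _blocked_intervals(ledger, margin=300):
    """Genome regions an NHEJ breakpoint must avoid: repeats (whole family
    span when the copies are a compact group, so event anchors between the
    copies stay untouched) and genes."""
    blocked = []
    for f in ledger["repeat_families"]:
        starts = [c["start"] for c in f["copies"]]
        ends = [c["end"] for c in f["copies"]]
        if max(ends) - min(starts) <= 25000:  # compact (grouped) family
            blocked.append((min(starts) - margin, max(ends) + margin))
        else:
            blocked += [(c["start"] - margin, c["end"] + margin) for c in f["copies"]]
    blocked += [(g["start"] - 150, g["end"] + 150) for g in ledger["genes"]]
    return blocked


def plan_free_regions(ledger, rng, points=0, intervals=(), margin=300, min_gap=3000):
    """Pick NHEJ breakpoints/excision intervals in unblocked background.

    Every chosen region additionally blocks ``min_gap`` around itself so
    the resulting planned events are mutually non-interacting (the regime
    the recovery guarantees are stated for).  Returns (points, intervals).
    """
    blocked = _blocked_intervals(ledger, margin)
    L = ledger["genome_length"]

    def free(a, b):
        return a >= 1500 and b <= L - 1500 and all(
            e <= a or b <= s for s, e in blocked
        )

    out_ivs = []
    for ln in intervals:
        for _ in range(20000):
            p = int(rng.integers(1500, L - ln - 1500))
            if free(p - margin, p + ln + margin):
                out_ivs.append((p, p + ln))
                blocked.append((p - min_gap, p + ln + min_gap))
                break
        else:
            raise RuntimeError("could not place a free interval")
    out_points = []
    for _ in range(points):
        for _ in range(20000):
            p = int(rng.integers(1500, L - 1500))
            if free(p - margin, p + margin):
                out_points.append(p)
                blocked.append((p - min_gap, p + min_gap))
                break
        else:
            raise RuntimeError("could not place a free site")
    return out_points, out_ivs


def pick_nhej_sites(ledger, n, rng, min_gap=3000, **_kw):
    """Repeat-free coordinates usable as unambiguous NHEJ breakpoints."""
    points, _ = plan_free_regions(ledger, rng, points=n, min_gap=min_gap)
    return points
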