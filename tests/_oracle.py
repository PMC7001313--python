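"""Independent brute-force oracles used only by the test suite.

Everything here is written from the model definitions directly — plain
loops and arithmetic, no imports from the package's selection code — so it
can stand as an independent check of the production implementations.
"""

from __future__ import annotations

from itertools import combinations


def brute_force_select(
    vaf: float,
    baf_upper: float,
    purity: float,
    totals: list[int],
    shortlist_size: int = 2,
):
    """Exhaustive two-stage selection over every allelic configuration.

    Returns (total, major, minor, phase) of the winner, or None when no
    shortlisted configuration can produce the observed VAF at any purity.
    """
    # enumerate (N, a, b, phase) with mutant copies >= 1
    cands = []
    for n in sorted(set(totals)):
        for a in range(n, -1, -1):
            b = n - a
            if a < b:
                continue
            for phase in ("major", "minor"):
                m = a if phase == "major" else b
                if m == 0:
                    continue
                if a == b and phase == "minor":
                    continue
                denom = purity * n + 2 * (1 - purity)
                e_baf = (purity * a + (1 - purity)) / denom
                e_vaf = purity * m / denom
                cands.append((n, a, b, phase, e_baf, e_vaf))

    # stage 1: shortlist distinct expected-BAF values
    distinct = {}
    for c in cands:
        distinct.setdefault(round(c[4], 9), []).append(c)
    ranked = sorted(
        distinct.items(),
        key=lambda kv: (
            abs(kv[0] - baf_upper),
            min((c[0], -(c[1] if c[3] == "major" else c[2])) for c in kv[1]),
        ),
    )
    shortlisted = [c for _, grp in ranked[:shortlist_size] for c in grp]

    # stage 2: feasibility then nearest expected VAF
    def feasible(c):
        n, a, b, phase, _, _ = c
        m = a if phase == "major" else b
        denom = m + 2 * vaf - vaf * n
        return denom > 0 and 2 * vaf / denom <= 1 + 1e-12

    if not any(feasible(c) for c in shortlisted):
        return None
    winner = min(
        shortlisted,
        key=lambda c: (
            abs(c[5] - vaf),
            c[0],
            -(c[1] if c[3] == "major" else c[2]),
        ),
    )
    return winner[0], winner[1], winner[2], winner[3]


def exact_ranksum_pvalue(a: list[float], b: list[float]) -> float:
    """Two-sided exact rank-sum p by enumerating every group assignment.

    Assumes no ties across the pooled sample.  Uses the Mann-Whitney U of
    the first group and doubles the smaller tail (with point mass at U
    counted once), the convention of the exact two-sided test.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    us = []
    for idx in combinations(range(n), na):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(n) if i not in idx]
        us.append(sum(1 for x in grp_a for y in grp_b if x > y))
    mean_u = na * (n - na) / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12)
    return extreme / len(us)


def hand_logrank(times_a, events_a, times_b, events_b):
    """Log-rank chi-square from the observed-minus-expected sums, by hand."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [r for r in records if r[0] >= t]
        n = len(at_risk)
        n_a = sum(1 for r in at_risk if r[2] == 0)
        d = sum(1 for r in at_risk if r[0] == t and r[1])
        d_a = sum(1 for r in at_risk if r[0] == t and r[1] and r[2] == 0)
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
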