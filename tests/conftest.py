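"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
import re

import numpy as np
import pytest

from polyest.sim import SimConfig, simulate_reads, simulate_transcriptome


# ---------------------------------------------------------------------------
# Independent oracles (brute force; never share code with the implementation)
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-9))


def alignment_score_oracle(read: str, target: str) -> int:
    """Best ungapped local alignment score (+1/-1) over every diagonal,
    by direct examination of all contiguous segments."""
    best = 0
    m, n = len(read), len(target)
    for diag in range(-m + 1, n):
        lo, hi = max(0, -diag), min(m, n - diag)
        if hi <= lo:
            continue
        vals = [1 if read[i] == target[i + diag] else -1 for i in range(lo, hi)]
        run = 0
        for v in vals:  # classic max-subarray
            run = max(v, run + v)
            best = max(best, run)
    return best


def ssr_oracle(seq: str, min_repeats: dict[int, int], max_interruption: int):
    """Regex brute force: maximal perfect primitive tandem runs, longest-span
    overlap resolution, then gap-based compound grouping. Returns a list of
    (start, end, motif_or_'compound', members) with 1-based inclusive spans."""
    runs = []
    for p, min_rep in min_repeats.items():
        pattern = re.compile(r"(?=(([ACGT]{%d})\2{%d,}))" % (p, min_rep - 1))
        for m in pattern.finditer(seq):
            whole, unit = m.group(1), m.group(2)
            # primitive unit only (shorter-unit priority)
            if any(len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d)
                   for d in range(1, len(unit))):
                continue
            start = m.start()
            # maximal on the left: cannot extend the run one unit leftwards
            if start >= 1 and seq[start - 1] == seq[start + p - 1]:
                continue
            reps = len(whole) // p
            runs.append((start + 1, start + p * reps, unit, p))
    # longest-span overlap resolution (tie: shorter unit, then leftmost)
    kept = []
    for run in sorted(runs, key=lambda r: (-(r[1] - r[0]), r[3], r[0])):
        if all(run[1] < k[0] or run[0] > k[1] for k in kept):
            kept.append(run)
    kept.sort()
    mono = [(s, e, u, []) for s, e, u, p in kept if p == 1]
    poly = [r for r in kept if r[3] > 1]
    out, group = [], []
    for r in poly:
        if group and r[0] - group[-1][1] - 1 <= max_interruption:
            group.append(r)
        else:
            if len(group) == 1:
                out.append((group[0][0], group[0][1], group[0][2], []))
            elif group:
                out.append((group[0][0], group[-1][1], "compound",
                            [(g[0], g[1], g[2]) for g in group]))
            group = [r]
    if len(group) == 1:
        out.append((group[0][0], group[0][1], group[0][2], []))
    elif group:
        out.append((group[0][0], group[-1][1], "compound",
                    [(g[0], g[1], g[2]) for g in group]))
    return sorted(out + mono)


# ---------------------------------------------------------------------------
# Shared simulated datasets (session-scoped; everything is seeded)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_sim():
    """Error-free mid-size dataset for pileup/SNP/tagging tests."""
    cfg = SimConfig(n_genes=20, reads_per_library=2000, read_error_rate=0.0, seed=3)
    truth = simulate_transcriptome(cfg)
    readset = simulate_reads(truth)
    return cfg, truth, readset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120948)
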