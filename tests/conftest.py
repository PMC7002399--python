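"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own interval machinery: they
paint bases into Python sets / numpy arrays, or enumerate tables and rank
assignments exhaustively, so agreement with the package is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cancerlnc.genome_model import Interval, IntervalSet


# ---------------------------------------------------------------------------
# per-base oracles


def bases(intervals) -> dict[str, set[int]]:
    """Paint every base of every interval into a per-chromosome set."""
    out: dict[str, set[int]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return out


def oracle_union_bp(intervals) -> int:
    return sum(len(s) for s in bases(intervals).values())


def oracle_subtract_bases(a, b) -> dict[str, set[int]]:
    a_b, b_b = bases(a), bases(b)
    return {c: s - b_b.get(c, set()) for c, s in a_b.items()}


def oracle_coverage_fraction(target, cover) -> float:
    t_b, c_b = bases(target), bases(cover)
    total = sum(len(s) for s in t_b.values())
    covered = sum(len(s & c_b.get(c, set())) for c, s in t_b.items())
    return covered / total


def oracle_nearest(query: dict, subjects: dict):
    """Exhaustive all-pairs nearest, ties to smaller subject id."""
    out = {}
    for qid, (qc, qp) in query.items():
        best = None
        for sid in sorted(subjects):
            sc, sp = subjects[sid]
            if sc != qc:
                continue
            d = abs(sp - qp)
            if best is None or d < best[0]:
                best = (d, sid)
        out[qid] = (float(best[0]), best[1]) if best else (math.nan, None)
    return out


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=500, label=""):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, min(start + length, max_pos), label=label))
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# exact-test oracles


def oracle_fisher_p(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all 2x2 tables with
    the observed margins, summing hypergeometric probabilities <= observed."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    N = n1 + n2
    rv = hypergeom(N, n1, k)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def oracle_wilcoxon_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all assignments of the
    pooled (distinct) values to the two groups."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# shared synthetic bundles (module scope: generated once per test run)


@pytest.fixture(scope="session")
def small_bundle():
    """A small strong-effect synthetic study used across test modules."""
    from cancerlnc.synthetic_data import SimulationConfig, generate_bundle

    cfg = SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chromosome_length=4_000_000,
        n_pc_genes=150,
        n_lnc_genes=150,
        pc_mean_length=10_000.0,
        lnc_mean_length=4_000.0,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The documented strong-effect configuration at its default sizes."""
    from cancerlnc.synthetic_data import SimulationConfig, generate_bundle

    return generate_bundle(SimulationConfig(seed=7))
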