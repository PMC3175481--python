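"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own fast paths: the
mapper oracle is a naive full scan, the coverage oracle re-enumerates
read-by-read, and the rank-test oracles enumerate sign patterns /
partitions exhaustively.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from pirte.synthetic_data import simulate, stock_run_config

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_map(genome: dict[str, str], seq: str):
    """All perfect matches of seq (both strands) by naive full scan."""
    hits = set()
    for strand, query in (("+", seq), ("-", oracle_revcomp(seq))):
        for chrom in sorted(genome):
            ref = genome[chrom]
            for i in range(len(ref) - len(query) + 1):
                if ref[i : i + len(query)] == query:
                    hits.add((chrom, i, strand))
    return sorted(hits)


def oracle_wilcoxon_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied absolute values.
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    counts: dict[int, int] = {}
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(range(1, n + 1), signs) if s)
        counts[w] = counts.get(w, 0) + 1
    total = 2**n
    cdf = sum(c for w, c in counts.items() if w <= w_obs) / total
    sf = sum(c for w, c in counts.items() if w >= w_obs) / total
    return min(1.0, 2 * min(cdf, sf))


def oracle_mwu_distribution(n_a: int, n_b: int):
    """Null distribution of the U statistic of the first group (no ties)."""
    pooled = list(range(n_a + n_b))
    counts: dict[int, int] = {}
    for comb in combinations(range(n_a + n_b), n_a):
        chosen = set(comb)
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(n_a + n_b) if i not in chosen]
        u = sum(1 for x in a for y in b if x > y)
        counts[u] = counts.get(u, 0) + 1
    return counts


def oracle_mwu_two_sided(u_obs: int, counts: dict[int, int]) -> float:
    total = sum(counts.values())
    cdf = sum(c for u, c in counts.items() if u <= u_obs) / total
    sf = sum(c for u, c in counts.items() if u >= u_obs) / total
    return min(1.0, 2 * min(cdf, sf))


def oracle_locus_raw(mappings_df, locus) -> float:
    """Per-locus weighted count by independent per-read re-enumeration."""
    total = 0.0
    for _, row in mappings_df.iterrows():
        if (
            row["chrom"] == locus.chrom
            and row["start"] >= locus.start
            and row["end"] <= locus.end
        ):
            total += 1.0 / row["multiplicity"]
    return total


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared by read-level and coverage tests."""
    cfg = stock_run_config("small", seed=7)
    bundle, libraries = simulate(cfg.sim)
    return cfg, bundle, libraries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
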