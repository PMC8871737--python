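"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
two-locus (and multi-locus) selfing Markov chains are exact linear-algebra
computations of single-seed-descent genetics, and the run-counting oracle
is brute-force enumeration.  They provide the reference values the
implementation is checked against.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, product

import numpy as np
import pandas as pd
import pytest

from trimap import coding
from trimap.simulate import (SimConfig, simulate_all_populations,
                             simulate_founders)

# ---------------------------------------------------------------------------
# exact selfing Markov chains (independent oracles)
# ---------------------------------------------------------------------------

def selfing_fixation_R(r: float, n_generations: int | None = None,
                       tol: float = 1e-15) -> float:
    """Two-locus selfing chain: fraction of recombinant homozygotes.

    Starts from the coupling heterozygote AB/ab and selfs to absorption
    (or for ``n_generations`` selfing rounds, conditioning on homozygosity
    at both loci).  Exact to numerical precision; the closed form at
    fixation is R = 2r/(1+2r).
    """
    haps = ["AB", "Ab", "aB", "ab"]

    def gametes(h1: str, h2: str) -> dict[str, float]:
        if h1 == h2:
            return {h1: 1.0}
        if h1[0] != h2[0] and h1[1] != h2[1]:  # doubly heterozygous
            return {h1: (1 - r) / 2, h2: (1 - r) / 2,
                    h1[0] + h2[1]: r / 2, h2[0] + h1[1]: r / 2}
        return {h1: 0.5, h2: 0.5}

    states = list(combinations_with_replacement(haps, 2))
    idx = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        g = gametes(*s)
        for ha, pa in g.items():
            for hb, pb in g.items():
                T[idx[s], idx[tuple(sorted((ha, hb)))]] += pa * pb
    p = np.zeros(len(states))
    p[idx[("AB", "ab")]] = 1.0
    if n_generations is None:
        while True:
            q = p @ T
            if np.abs(q - p).sum() < tol:
                p = q
                break
            p = q
    else:
        for _ in range(n_generations):
            p = p @ T
    hom = [idx[(h, h)] for h in haps]
    p_hom = sum(p[i] for i in hom)
    p_rec = p[idx[("Ab", "Ab")]] + p[idx[("aB", "aB")]]
    return p_rec / p_hom


def selfing_junction_moments(rs: list[float]) -> tuple[float, float]:
    """Multi-locus selfing chain: mean and variance of the junction count
    at fixation for loci separated by recombination fractions ``rs``
    (independent intervals, i.e. no interference)."""
    n_loci = len(rs) + 1
    haps = ["".join(p) for p in product("Aa", repeat=n_loci)]

    def gametes(h1: str, h2: str) -> dict[str, float]:
        if h1 == h2:
            return {h1: 1.0}
        out: dict[str, float] = {}
        for pat in product([0, 1], repeat=len(rs)):
            w = np.prod([rs[i] if pat[i] else 1 - rs[i] for i in range(len(rs))])
            for start in (0, 1):
                cur, g = start, []
                for i in range(n_loci):
                    if i > 0 and pat[i - 1]:
                        cur ^= 1
                    g.append((h1 if cur == 0 else h2)[i])
                key = "".join(g)
                out[key] = out.get(key, 0.0) + 0.5 * w
        return out

    states = list(combinations_with_replacement(haps, 2))
    idx = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        g = gametes(*s)
        for ha, pa in g.items():
            for hb, pb in g.items():
                T[idx[s], idx[tuple(sorted((ha, hb)))]] += pa * pb
    p = np.zeros(len(states))
    p[idx[tuple(sorted(("A" * n_loci, "a" * n_loci)))]] = 1.0
    for _ in range(4000):
        p = p @ T
    dist: dict[int, float] = {}
    for s, i in idx.items():
        if s[0] == s[1] and p[i] > 0:
            j = sum(1 for k in range(n_loci - 1) if s[0][k] != s[0][k + 1])
            dist[j] = dist.get(j, 0.0) + p[i]
    tot = sum(dist.values())
    mean = sum(k * v for k, v in dist.items()) / tot
    var = sum(k * k * v for k, v in dist.items()) / tot - mean ** 2
    return mean, var


def brute_force_short_runs(seq: list[str], window: int = 1) -> int:
    """Enumerate interior runs of length <= window in a code sequence
    (missing entries removed beforehand by the caller)."""
    runs = []
    for v in seq:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    return sum(1 for k in range(1, len(runs) - 1) if runs[k][1] <= window)


def haldane_r_from_cM(d: float) -> float:
    return 0.5 * (1.0 - np.exp(-d / 50.0))


# ---------------------------------------------------------------------------
# shared simulated datasets
# ---------------------------------------------------------------------------

def build_matrix(founders, populations) -> coding.IntegratedGenotypeMatrix:
    """Integrated matrix straight from the simulator's coded tables."""
    cms = {}
    for pop_name, pop in populations.items():
        struct = pd.Series((~founders.segregating(pop_name)).to_numpy(),
                           index=pop.genotypes.index)
        cms[pop_name] = coding.CodedMatrix(pop_name, pop.genotypes.copy(),
                                           struct, 0)
    anchors = founders.markers[["marker", "chrom", "bp"]]
    return coding.merge_populations(cms, anchors=anchors)


@pytest.fixture(scope="session")
def small_sim():
    """Two chromosomes, 120 lines/population, no IBD blocks, one QTL."""
    cfg = SimConfig(n_chromosomes=2, chrom_cM=(100.0, 120.0),
                    chrom_Mb=(300.0, 360.0), n_markers_per_chrom=120,
                    n_lines=120, generations=13, missing_rate=0.02,
                    qtl=(("M1_0060", 1.5),), pheno_sigma=1.0, seed=11)
    founders = simulate_founders(cfg)
    pops = simulate_all_populations(founders, cfg)
    return cfg, founders, pops


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    cfg, founders, pops = small_sim
    return build_matrix(founders, pops)


@pytest.fixture(scope="session")
def big_sim():
    """Seven pea-like chromosomes totalling 928 cM, 200 lines/population
    (600 RILs), plain Poisson crossovers so the nominal genetic lengths are
    also the realized expectations."""
    cfg = SimConfig(n_chromosomes=7,
                    chrom_cM=(110.0, 126.0, 151.0, 132.0, 126.0, 138.0, 145.0),
                    chrom_Mb=(342.0, 384.0, 463.0, 357.0, 438.0, 298.0, 393.0),
                    n_markers_per_chrom=300, n_lines=200, generations=13,
                    obligate_chiasma=False, missing_rate=0.02, seed=29)
    founders = simulate_founders(cfg)
    pops = simulate_all_populations(founders, cfg)
    return cfg, founders, pops


@pytest.fixture(scope="session")
def big_matrix(big_sim):
    cfg, founders, pops = big_sim
    return build_matrix(founders, pops)


@pytest.fixture(scope="session")
def big_map(big_sim, big_matrix):
    from trimap import mapping
    cfg, founders, pops = big_sim
    order = mapping.initial_order(founders.markers[["marker", "chrom", "bp"]])
    return mapping.assemble_map(order, big_matrix)
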