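"""Shared fixtures and oracle helpers for the test suite.

Scenario pipeline runs are expensive, so they are computed once per session
and shared between the unit tests and the acceptance tests.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from tlaphase.locus_model import NLAIII, digest
from tlaphase.pipeline import make_scenarios, run_pipeline
from tlaphase.split_mapper import LONG_MAPPER, build_index, map_reads
from tlaphase.tla_simulator import (ContactModel, ReadProfile, Viewpoint,
                                    digest_haplotypes, generate_reads,
                                    simulate_circle, synthesize_locus)

SCENARIO_SEED = 1


@lru_cache(maxsize=None)
def _scenario_result(name: str):
    return run_pipeline(make_scenarios(SCENARIO_SEED)[name])


@pytest.fixture(scope="session")
def scenario():
    """Factory returning (cached) pipeline results for a scenario preset."""
    return _scenario_result


@pytest.fixture(scope="session")
def small_locus():
    """A small diploid locus with het SNVs and indels (seeded)."""
    return synthesize_locus(8000, np.random.default_rng(42), n_het_snvs=8,
                            n_het_indels=2, n_hom_alt=1)


# ---------------------------------------------------------------------------
# independent oracles for the split mapper


def provenance_chains(rows, k=21, tol=4):
    """Expected mapped intervals from simulator provenance.

    Consecutive read fragments that are contiguous on the reference merge
    into chains (a ligation of genomic neighbours reconstructs contiguous
    sequence, leaving no junction to detect).  Chains shorter than the seed
    length are unmappable.  Each boundary carries a slack: the trimming
    allowance (the cut-convention offset) plus the length of any adjacent
    sub-k fragment, whose bases are unmappable by construction and may attach
    to either neighbouring segment or drop.
    Returns a list of (start, end, left_slack, right_slack).
    """
    rows = sorted(rows, key=lambda r: r.read_offset)
    chains: list[list] = []
    for r in rows:
        if chains and chains[-1][-1].fragment_ref_end == r.fragment_ref_start:
            chains[-1].append(r)
        else:
            chains.append([r])

    def rowlen(r):
        return r.fragment_ref_end - r.fragment_ref_start

    exp = []
    for ci, ch in enumerate(chains):
        start, end = ch[0].fragment_ref_start, ch[-1].fragment_ref_end
        if end - start < k:
            continue
        ls = rs = tol
        if rowlen(ch[0]) < k:
            ls += rowlen(ch[0])
        if rowlen(ch[-1]) < k:
            rs += rowlen(ch[-1])
        if ci > 0 and rowlen(chains[ci - 1][-1]) < k:
            ls += rowlen(chains[ci - 1][-1])
        if ci + 1 < len(chains) and rowlen(chains[ci + 1][0]) < k:
            rs += rowlen(chains[ci + 1][0])
        exp.append((start, end, ls, rs))
    return exp


def segments_match_provenance(alignments, rows, k=21, tol=4):
    """True when mapper segments equal the expected provenance chains."""
    exp = provenance_chains(rows, k=k, tol=tol)
    got = [(a.ref_start, a.ref_end)
           for a in sorted(alignments, key=lambda a: a.seg_start)]
    if len(got) != len(exp):
        return False
    return all(abs(gs - s) <= ls and abs(ge - e) <= rs
               for (gs, ge), (s, e, ls, rs) in zip(got, exp))


def brute_decompose(read_seq, ref_seq, k=21, cut_offset=4):
    """Exhaustive restriction-cut decomposition oracle.

    Considers every combination of cuts at recognition-site boundaries; a
    piece of length >= k must occur exactly in the reference.  Maximizes
    exactly-placed coverage, then minimizes the number of mappable pieces.
    Returns (coverage, n_mappable_pieces).
    """
    L = len(read_seq)
    cuts = [0] + [m + cut_offset for m in NLAIII.motif_starts(read_seq)
                  if 0 < m + cut_offset < L] + [L]
    n = len(cuts)
    worst = (10 ** 9, 10 ** 9)
    best = [worst] * n
    best[0] = (0, 0)
    for j in range(1, n):
        for i in range(j):
            if best[i] == worst:
                continue
            piece = read_seq[cuts[i]:cuts[j]]
            plen = cuts[j] - cuts[i]
            if plen >= k:
                if ref_seq.find(piece) < 0:
                    continue
                cand = (best[i][0] - plen, best[i][1] + 1)
            else:
                cand = best[i]
            if cand < best[j]:
                best[j] = cand
    cov, pieces = best[-1]
    return -cov, pieces


def make_chimeric_dataset(seed=11, length=18000, n_circles=400, n_reads=500,
                          bounds=(300, 900)):
    """Error-free long-read chimeric dataset on a variant-free locus, with a
    modest-size viewpoint fragment so amplicons stay short."""
    rng = np.random.default_rng(seed)
    locus = synthesize_locus(length, rng, n_het_snvs=0, n_het_indels=0,
                             n_hom_alt=0)
    frags = digest(locus.reference.seq)
    mid = min((f for f in frags[1:-1] if 120 <= len(f) <= 300),
              key=lambda f: abs(f.start - length // 2))
    vp = Viewpoint.at_position(locus.reference, (mid.start + mid.end) // 2)
    cm = ContactModel(min_amplicon_len=bounds[0], max_amplicon_len=bounds[1],
                      mean_extra_fragments=2)
    haps = digest_haplotypes(locus, vp)
    circles = [simulate_circle(haps, cm, rng, circle_id=i)
               for i in range(n_circles)]
    from tlaphase.tla_simulator import amplify
    amps = amplify(circles, vp, haps)
    reads, prov = generate_reads(amps, ReadProfile(platform="long"), rng, n_reads)
    index = build_index({locus.reference.name: locus.reference.seq}, k=21)
    return locus, reads, prov, index


@pytest.fixture(scope="session")
def chimeric_dataset():
    return make_chimeric_dataset()
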