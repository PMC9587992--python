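"""Link extraction and haplotype-block phasing, with a brute-force oracle."""

import numpy as np
import pytest

from tlaphase.io import Read
from tlaphase.locus_model import Reference, ValidationError
from tlaphase.pileup_caller import GenotypeCall
from tlaphase.link_phaser import (PhaseLink, brute_force_phase, extract_links,
                                  phase)
from tlaphase.split_mapper import FragmentAlignment


def _call(pos, ref, alt):
    return GenotypeCall(pos=pos, ref_allele=ref, alt_allele=alt,
                        genotype="0/1", depth=50, alt_fraction=0.5)


def _aln(read_id, seg, ref_iv, mate=0):
    return FragmentAlignment(read_id=read_id, mate=mate, seg_start=seg[0],
                             seg_end=seg[1], ref_name="r", ref_start=ref_iv[0],
                             ref_end=ref_iv[1], strand="+", mismatches=0,
                             ambiguous=False, round=1)


@pytest.fixture()
def phasing_setup():
    rng = np.random.default_rng(4)
    ref = Reference("r", "".join(rng.choice(list("ACGT"), size=120)))
    a_pos, b_pos = 20, 90
    alt = {p: next(b for b in "ACGT" if b != ref.seq[p]) for p in (a_pos, b_pos)}
    calls = [_call(a_pos, ref.seq[a_pos], alt[a_pos]),
             _call(b_pos, ref.seq[b_pos], alt[b_pos])]
    return ref, calls, alt


class TestExtractLinks:
    def test_alt_plus_ref_pair_is_trans(self, phasing_setup):
        ref, calls, alt = phasing_setup
        seq = list(ref.seq)
        seq[20] = alt[20]  # ALT at A, REF at B
        reads = [Read("m1", "".join(seq), "I" * 120)]
        obs, links = extract_links([_aln("m1", (0, 120), (0, 120))],
                                   reads, calls, ref)
        assert [(o.variant_id, o.allele) for o in obs] == [(0, 1), (1, 0)]
        assert len(links) == 1
        assert (links[0].n_cis, links[0].n_trans) == (0, 1)

    def test_single_covered_het_gives_no_link(self, phasing_setup):
        ref, calls, _ = phasing_setup
        reads = [Read("m1", ref.seq[:50], "I" * 50)]
        obs, links = extract_links([_aln("m1", (0, 50), (0, 50))],
                                   reads, calls, ref)
        assert len(obs) == 1 and links == []

    def test_mates_pool_into_one_molecule(self, phasing_setup):
        ref, calls, alt = phasing_setup
        seq = list(ref.seq)
        seq[20] = alt[20]
        seq[90] = alt[90]
        hap = "".join(seq)
        reads = [Read("m1", hap[:50], "I" * 50, mate=1),
                 Read("m1", hap[60:120], "I" * 60, mate=2)]
        alns = [_aln("m1", (0, 50), (0, 50), mate=1),
                _aln("m1", (0, 60), (60, 120), mate=2)]
        obs, links = extract_links(alns, reads, calls, ref)
        assert len(links) == 1
        assert (links[0].n_cis, links[0].n_trans) == (1, 0)

    def test_conflicting_observations_discarded(self, phasing_setup):
        ref, calls, alt = phasing_setup
        seq_alt = list(ref.seq)
        seq_alt[20] = alt[20]
        reads = [Read("m1", "".join(seq_alt)[:50], "I" * 50, mate=1),
                 Read("m1", ref.seq[:50], "I" * 50, mate=2)]
        alns = [_aln("m1", (0, 50), (0, 50), mate=1),
                _aln("m1", (0, 50), (0, 50), mate=2)]
        obs, links = extract_links(alns, reads, calls, ref)
        assert obs == [] and links == []

    def test_error_free_simulation_links_are_pure(self, scenario):
        res = scenario("noise_free_long")
        assert res.links, "expected links in the noise-free run"
        for l in res.links:
            assert l.n_cis == 0 or l.n_trans == 0


class TestPhase:
    def test_majority_rule_two_hets(self):
        calls = [_call(10, "A", "G"), _call(50, "C", "T")]
        blocks = phase([PhaseLink(0, 1, 6, 4)], calls)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.assignment[0] == b.assignment[1]  # cis orientation
        assert b.agreement_score == 6

    def test_zero_links_all_singletons(self):
        calls = [_call(p, "A", "G") for p in (10, 50, 90)]
        blocks = phase([], calls)
        assert len(blocks) == 3
        assert all(not b.phased for b in blocks)

    def test_balanced_link_carries_no_orientation(self):
        calls = [_call(10, "A", "G"), _call(50, "C", "T")]
        blocks = phase([PhaseLink(0, 1, 3, 3)], calls)
        assert all(not b.phased for b in blocks)

    def test_consistent_instance_matches_brute_force(self):
        rng = np.random.default_rng(12)
        calls = [_call(10 * (i + 1), "A", "G") for i in range(5)]
        truth = [int(rng.integers(2)) for _ in range(5)]
        links = []
        for i in range(4):
            for j in range(i + 1, 5):
                if rng.random() < 0.7:
                    cis = truth[i] == truth[j]
                    links.append(PhaseLink(i, j, 5 if cis else 0,
                                           0 if cis else 5))
        blocks = phase(links, calls)
        score = sum(b.agreement_score for b in blocks)
        _, best = brute_force_phase(links, calls)
        assert score == best

    def test_canonical_orientation(self):
        calls = [_call(10, "A", "G"), _call(50, "C", "T")]
        b = phase([PhaseLink(0, 1, 0, 9)], calls)[0]
        assert b.assignment[0] == 0 and b.assignment[1] == 1


class TestBruteForce:
    def test_two_hets_single_cis_link(self):
        calls = [_call(10, "A", "G"), _call(50, "C", "T")]
        sides, score = brute_force_phase([PhaseLink(0, 1, 1, 0)], calls)
        assert score == 1 and sides[0] == sides[1]

    def test_limit_enforced(self):
        calls = [_call(10 * i + 10, "A", "G") for i in range(13)]
        with pytest.raises(ValidationError):
            brute_force_phase([], calls)

    def _random_instance(self, rng, n=8):
        calls = [_call(10 * (i + 1), "A", "G") for i in range(n)]
        links = []
        for i in range(n - 1):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    links.append(PhaseLink(i, j, int(rng.integers(0, 6)),
                                           int(rng.integers(0, 6))))
        return calls, links

    def test_greedy_never_beats_oracle_and_usually_matches(self):
        rng = np.random.default_rng(77)
        equal = total = 0
        for _ in range(60):
            calls, links = self._random_instance(rng)
            blocks = phase(links, calls)
            score = sum(b.agreement_score for b in blocks)
            # add the score of balanced links under the greedy assignment:
            # brute force sees all links, phase() ignores zero-weight ones
            sides = {}
            for b in blocks:
                sides.update(b.assignment)
                for vid in b.variant_ids:
                    sides.setdefault(vid, 0)
            from tlaphase.link_phaser import _score
            score = _score(links, sides)
            _, best = brute_force_phase(links, calls)
            assert score <= best
            equal += score == best
            total += 1
        assert equal / total >= 0.95

    def test_tree_instances_solved_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = 7
            calls = [_call(10 * (i + 1), "A", "G") for i in range(n)]
            links = []
            for j in range(1, n):  # random spanning tree
                i = int(rng.integers(0, j))
                c, t = int(rng.integers(0, 8)), int(rng.integers(0, 8))
                if c == t:
                    c += 1
                links.append(PhaseLink(i, j, c, t))
            blocks = phase(links, calls)
            score = sum(b.agreement_score for b in blocks)
            _, best = brute_force_phase(links, calls)
            assert score == best
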