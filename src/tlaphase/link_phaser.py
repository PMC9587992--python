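"""Link-based haplotype phasing of heterozygous calls.

Every TLA molecule (a ligation circle, hence all split segments of a read
and both mates of a pair) derives from a single homologous chromosome, so the
alleles it exposes at different heterozygous sites lie on the same haplotype.
Co-observed allele pairs become links (cis = same allele class, trans =
opposite); links form a graph whose connected components are phase blocks.
Within a block, relative orientations are fixed along a maximum-weight
spanning tree (weight ``|n_cis - n_trans|``) and sides propagated from the
highest-degree node; a brute-force enumerator over all orientations serves
as the correctness oracle for small instances.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import Read
from .locus_model import Reference, ValidationError, left_normalize
from .pileup_caller import GenotypeCall, aligned_pairs
from .split_mapper import FragmentAlignment

__all__ = [
    "AlleleObservation",
    "PhaseLink",
    "PhaseBlock",
    "extract_links",
    "phase",
    "brute_force_phase",
]


@dataclass(frozen=True)
class AlleleObservation:
    molecule: str
    variant_id: int
    allele: int  # 0 = REF, 1 = ALT


@dataclass(frozen=True)
class PhaseLink:
    var_a: int
    var_b: int
    n_cis: int
    n_trans: int

    @property
    def weight(self) -> int:
        return abs(self.n_cis - self.n_trans)

    @property
    def sign(self) -> int:
        """+1 when the majority pairing is cis (same side), -1 when trans."""
        return 1 if self.n_cis >= self.n_trans else -1


@dataclass
class PhaseBlock:
    """A set of link-connected het variants with haplotype side assignments.

    ``assignment`` maps variant_id → side (the haplotype index carrying the
    ALT allele under this block's orientation); empty for singleton
    (unphased) blocks.  ``block_id`` follows the VCF PS convention: 1-based
    position of the block's first variant.
    """

    block_id: int
    variant_ids: tuple[int, ...]
    assignment: dict[int, int] = field(default_factory=dict)
    agreement_score: int = 0

    @property
    def phased(self) -> bool:
        return len(self.assignment) >= 2


def _indel_span(call: GenotypeCall) -> tuple[int, int]:
    """Reference interval an observation must fully cover, incl. 1-bp anchors."""
    return call.pos - 1, call.pos + len(call.ref_allele) + 1


def extract_links(alignments: list[FragmentAlignment], reads: list[Read],
                  het_calls: list[GenotypeCall], reference: Reference
                  ) -> tuple[list[AlleleObservation], list[PhaseLink]]:
    """Extract per-molecule allele observations and pairwise phase links.

    SNV alleles are read off the match column at the site; indel alleles
    require the segment to span the full allele plus one anchor base on each
    side.  Conflicting observations within one molecule are discarded.
    """
    het_calls = sorted(het_calls, key=lambda c: c.pos)
    snv_pos = {i: c.pos for i, c in enumerate(het_calls) if c.kind == "SNV"}
    per_molecule: dict[str, dict[int, set[int]]] = defaultdict(lambda: defaultdict(set))
    read_seqs = {(r.read_id, r.mate): r.seq for r in reads}
    for a in alignments:
        if a.ref_name != reference.name:
            continue
        ref_pos, bases, indel_events = aligned_pairs(a, read_seqs[(a.read_id, a.mate)])
        norm_events = set()
        for anchor, ref_len, alt_seq in indel_events:
            if anchor < 0:
                continue
            b = reference.seq[anchor]
            ref_tail = reference.seq[anchor + 1:anchor + 1 + ref_len]
            norm_events.add(left_normalize(reference.seq, anchor, b + ref_tail, b + alt_seq))
        covered = set(ref_pos.tolist())
        for vid, call in enumerate(het_calls):
            if call.kind == "SNV":
                if call.pos not in covered:
                    continue
                idx = int(np.searchsorted(ref_pos, call.pos))
                base = chr(bases[idx])
                if base == call.ref_allele:
                    allele = 0
                elif base == call.alt_allele:
                    allele = 1
                else:
                    continue  # third allele (error): no observation
            else:
                lo, hi = _indel_span(call)
                if a.ref_start > lo or a.ref_end < hi:
                    continue
                key = (call.pos, call.ref_allele, call.alt_allele)
                if key in norm_events:
                    allele = 1
                elif not any(ev[0] in range(lo, hi) for ev in norm_events) \
                        and all(p in covered for p in range(max(0, lo), hi)):
                    allele = 0
                else:
                    continue
            per_molecule[a.read_id][vid].add(allele)
    observations: list[AlleleObservation] = []
    pair_counts: dict[tuple[int, int], list[int]] = defaultdict(lambda: [0, 0])
    for mol in sorted(per_molecule):
        clean = {vid: next(iter(s)) for vid, s in per_molecule[mol].items() if len(s) == 1}
        for vid, allele in sorted(clean.items()):
            observations.append(AlleleObservation(mol, vid, allele))
        vids = sorted(clean)
        for i in range(len(vids)):
            for j in range(i + 1, len(vids)):
                a_, b_ = vids[i], vids[j]
                if clean[a_] == clean[b_]:
                    pair_counts[(a_, b_)][0] += 1
                else:
                    pair_counts[(a_, b_)][1] += 1
    links = [PhaseLink(a_, b_, c, t) for (a_, b_), (c, t) in sorted(pair_counts.items())]
    return observations, links


def _score(links: list[PhaseLink], sides: dict[int, int]) -> int:
    s = 0
    for l in links:
        if l.var_a in sides and l.var_b in sides:
            s += l.n_cis if sides[l.var_a] == sides[l.var_b] else l.n_trans
    return s


def phase(links: list[PhaseLink], het_calls: list[GenotypeCall]) -> list[PhaseBlock]:
    """Resolve links into phase blocks; see module docstring.

    Zero-weight links (``n_cis == n_trans``) carry no orientation evidence
    and do not connect variants.  Blocks are canonicalized so their
    lowest-position variant sits on side 0.
    """
    het_calls = sorted(het_calls, key=lambda c: c.pos)
    n = len(het_calls)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for l in links:
        if l.weight > 0:
            G.add_edge(l.var_a, l.var_b, weight=l.weight, sign=l.sign)
    blocks: list[PhaseBlock] = []
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        first_pos = het_calls[comp[0]].pos
        if len(comp) == 1:
            blocks.append(PhaseBlock(block_id=first_pos + 1, variant_ids=(comp[0],)))
            continue
        sub = G.subgraph(comp)
        tree = nx.maximum_spanning_tree(sub, weight="weight")
        root = max(comp, key=lambda v: (sub.degree(v), -v))
        sides = {root: 0}
        for u, v in nx.bfs_edges(tree, root):
            sides[v] = sides[u] if tree[u][v]["sign"] > 0 else 1 - sides[u]
        comp_links = [l for l in links if l.var_a in sides and l.var_b in sides]
        # deterministic single-flip refinement of the tree solution
        by_var: dict[int, list[PhaseLink]] = defaultdict(list)
        for l in comp_links:
            by_var[l.var_a].append(l)
            by_var[l.var_b].append(l)
        def flip_delta(v):
            delta = 0
            for l in by_var[v]:
                other = l.var_b if l.var_a == v else l.var_a
                same = sides[v] == sides[other]
                delta += (l.n_trans - l.n_cis) if same else (l.n_cis - l.n_trans)
            return delta

        def single_flip_pass():
            moved = False
            for _ in range(len(comp)):
                improved = False
                for v in comp:
                    if flip_delta(v) > 0:
                        sides[v] = 1 - sides[v]
                        improved = moved = True
                if not improved:
                    break
            return moved

        single_flip_pass()
        # escape shallow local optima with joint pair flips
        for _ in range(len(comp)):
            improved = False
            for ai in range(len(comp)):
                for bi in range(ai + 1, len(comp)):
                    u, v = comp[ai], comp[bi]
                    base = _score(comp_links, sides)
                    sides[u] = 1 - sides[u]
                    sides[v] = 1 - sides[v]
                    if _score(comp_links, sides) > base:
                        improved = True
                        single_flip_pass()
                    else:
                        sides[u] = 1 - sides[u]
                        sides[v] = 1 - sides[v]
            if not improved:
                break
        if sides[comp[0]] != 0:  # canonical orientation
            sides = {k: 1 - s for k, s in sides.items()}
        blocks.append(PhaseBlock(block_id=first_pos + 1, variant_ids=tuple(comp),
                                 assignment=sides,
                                 agreement_score=_score(comp_links, sides)))
    blocks.sort(key=lambda b: b.block_id)
    return blocks


def brute_force_phase(links: list[PhaseLink], het_calls: list[GenotypeCall],
                      limit: int = 12) -> tuple[dict[int, int], int]:
    """Exhaustive phasing oracle: scores every orientation assignment.

    The first variant's side is fixed to 0 (global flips are equivalent);
    ties break toward the lexicographically smallest assignment.  Refuses
    instances with more than ``limit`` het variants.
    """
    n = len(het_calls)
    if n > limit:
        raise ValidationError(f"brute force limited to {limit} variants, got {n}")
    if n == 0:
        return {}, 0
    best_sides: dict[int, int] = {}
    best = -1
    for mask in range(2 ** max(0, n - 1)):
        sides = {0: 0}
        for i in range(1, n):
            sides[i] = (mask >> (n - 1 - i)) & 1
        s = _score(links, sides)
        if s > best:
            best, best_sides = s, dict(sides)
    return best_sides, best
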