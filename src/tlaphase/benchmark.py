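"""Genotype and phasing concordance against a phased truth set.

Genotype comparison mirrors the usual covered/called/concordant accounting:
a truth variant is *covered* when pileup depth at its position reaches the
platform minimum, *concordant* when a call matches position, alleles and
(unphased) genotype, *missing* when covered but uncalled; calls absent from
the truth set are discordant.  Phasing comparison scores each block under
its best global orientation (phasing is defined up to a flip per block) and
counts switch errors as adjacent changes of the per-variant concordance
state along the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .locus_model import Variant
from .link_phaser import PhaseBlock
from .pileup_caller import CallerConfig, GenotypeCall, Pileup

__all__ = ["GenotypeComparison", "PhasingComparison",
           "compare_genotypes", "compare_phasing"]


@dataclass
class ClassCounts:
    n_in_reference: int = 0
    n_covered: int = 0
    n_called: int = 0
    n_concordant: int = 0
    n_discordant: int = 0
    n_missing: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GenotypeComparison:
    snv: ClassCounts = field(default_factory=ClassCounts)
    indel: ClassCounts = field(default_factory=ClassCounts)

    def by_kind(self, kind: str) -> ClassCounts:
        return self.snv if kind == "SNV" else self.indel

    def as_dict(self) -> dict:
        return {"SNV": self.snv.as_dict(), "INDEL": self.indel.as_dict()}

    @property
    def total_concordant(self) -> int:
        return self.snv.n_concordant + self.indel.n_concordant

    @property
    def total_discordant(self) -> int:
        return self.snv.n_discordant + self.indel.n_discordant


def _truth_gt_string(v: Variant) -> str:
    return "0/1" if v.is_het else "1/1"


def compare_genotypes(calls: list[GenotypeCall], truth: list[Variant],
                      pileup: Pileup, config: CallerConfig) -> GenotypeComparison:
    """Per-class covered / called / concordant / discordant / missing counts."""
    cmp = GenotypeComparison()
    truth_by_key = {(v.pos, v.ref_allele, v.alt_allele): v for v in truth}
    matched: set[tuple] = set()
    for v in truth:
        c = cmp.by_kind(v.kind)
        c.n_in_reference += 1
        if pileup.depth[v.pos] >= config.min_depth:
            c.n_covered += 1
    for call in calls:
        c = cmp.by_kind(call.kind)
        c.n_called += 1
        key = (call.pos, call.ref_allele, call.alt_allele)
        tv = truth_by_key.get(key)
        if tv is not None and _truth_gt_string(tv) == call.genotype:
            c.n_concordant += 1
            matched.add(key)
        else:
            c.n_discordant += 1
    call_pos = {(c.pos, c.ref_allele, c.alt_allele) for c in calls}
    for v in truth:
        key = (v.pos, v.ref_allele, v.alt_allele)
        if pileup.depth[v.pos] >= config.min_depth and key not in call_pos:
            cmp.by_kind(v.kind).n_missing += 1
    return cmp


@dataclass
class BlockDetail:
    block_id: int
    n_variants: int
    n_compared: int
    n_concordant: int
    n_switch_errors: int


@dataclass
class PhasingComparison:
    n_heterozygous: int = 0
    n_phased: int = 0
    n_concordant_phased: int = 0
    n_switch_errors: int = 0
    blocks: list[BlockDetail] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_heterozygous": self.n_heterozygous,
            "n_phased": self.n_phased,
            "n_concordant_phased": self.n_concordant_phased,
            "n_switch_errors": self.n_switch_errors,
            "blocks": [b.__dict__ for b in self.blocks],
        }


def compare_phasing(blocks: list[PhaseBlock], het_calls: list[GenotypeCall],
                    truth: list[Variant]) -> PhasingComparison:
    """Score phased blocks against the phased truth.

    Only call variants that are heterozygous in the truth set are comparable;
    each block is evaluated under the orientation (flipped or not) that
    maximizes per-variant agreement, making all metrics invariant to global
    block flips.  An empty or all-singleton block set yields zero phased
    counters, not an error.
    """
    het_calls = sorted(het_calls, key=lambda c: c.pos)
    truth_side = {(v.pos, v.ref_allele, v.alt_allele): v.alt_side
                  for v in truth if v.is_het}
    out = PhasingComparison(n_heterozygous=len(truth_side))
    for block in blocks:
        if not block.phased:
            continue
        entries = []  # (pos, call_side, truth_side)
        for vid in block.variant_ids:
            call = het_calls[vid]
            side = block.assignment.get(vid)
            if side is None:
                continue
            out.n_phased += 1
            t = truth_side.get((call.pos, call.ref_allele, call.alt_allele))
            if t is None:
                continue
            entries.append((call.pos, side, t))
        if not entries:
            continue
        entries.sort()
        agree = [1 if s == t else 0 for _, s, t in entries]
        n_same = sum(agree)
        flipped = len(agree) - n_same
        n_conc = max(n_same, flipped)
        states = agree if n_same >= flipped else [1 - a for a in agree]
        switches = sum(1 for i in range(1, len(states)) if states[i] != states[i - 1])
        out.n_concordant_phased += n_conc
        out.n_switch_errors += switches
        out.blocks.append(BlockDetail(block_id=block.block_id,
                                      n_variants=len(block.variant_ids),
                                      n_compared=len(entries),
                                      n_concordant=n_conc,
                                      n_switch_errors=switches))
    return out
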