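"""Diploid locus model: reference + phased variants + restriction digestion.

A locus is a small reference sequence together with an ordered set of phased
SNVs and small INDELs.  Applying the variants of one haplotype yields the
haplotype sequence and a monotone coordinate map from reference positions to
haplotype positions; restriction digestion (NlaIII by default) partitions a
haplotype into the ordered fragments that proximity ligation operates on.

Coordinates are 0-based, half-open throughout; VCF input/output is 1-based as
usual (see :mod:`tlaphase.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reference",
    "Variant",
    "DiploidLocus",
    "RestrictionEnzyme",
    "Fragment",
    "NLAIII",
    "NSPI",
    "apply_variants",
    "digest",
    "make_homolog",
    "ValidationError",
]

DNA_ALPHABET = frozenset("ACGT")

#: IUPAC nucleotide codes to the concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a reference, variant set or parameter fails validation."""


@dataclass(frozen=True)
class Reference:
    """A named reference sequence over {A,C,G,T}.

    ``origin`` is a coordinate offset so that a locus excised from a larger
    genome can keep its original coordinates in reports.
    """

    name: str
    seq: str
    origin: int = 0

    def __post_init__(self):
        if not self.seq:
            raise ValidationError("reference sequence must be non-empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(f"reference {self.name!r} contains non-ACGT symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Variant:
    """A phased SNV or small INDEL in VCF-like (pos, ref, alt) form.

    ``genotype`` is a pair of allele indices, one per haplotype, each 0 (ref)
    or 1 (alt); the pair is phased, i.e. ``genotype[h]`` is the allele carried
    by haplotype ``h``.
    """

    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValidationError(f"empty allele at pos {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"ref == alt at pos {self.pos}")
        if any(g not in (0, 1) for g in self.genotype):
            raise ValidationError(f"genotype entries must be 0/1 at pos {self.pos}")

    @property
    def kind(self) -> str:
        """``"SNV"`` if both alleles are single bases, else ``"INDEL"``."""
        return "SNV" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "INDEL"

    @property
    def end(self) -> int:
        """Half-open end of the reference span."""
        return self.pos + len(self.ref_allele)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def alt_side(self) -> int | None:
        """Haplotype index carrying the ALT allele, for het variants."""
        if not self.is_het:
            return None
        return 0 if self.genotype[0] == 1 else 1


def validate_variants(reference: Reference, variants: list[Variant]) -> None:
    """Check variants are sorted, non-overlapping and match the reference."""
    prev_end = -1
    prev_pos = -1
    for v in variants:
        if v.pos < prev_pos:
            raise ValidationError(f"variants not sorted at pos {v.pos}")
        if v.pos < prev_end:
            raise ValidationError(f"overlapping variants at pos {v.pos}")
        if v.end > len(reference):
            raise ValidationError(f"variant at pos {v.pos} extends past reference end")
        obs = reference.seq[v.pos:v.end]
        if obs != v.ref_allele:
            raise ValidationError(
                f"ref allele mismatch at pos {v.pos}: expected {v.ref_allele!r}, reference has {obs!r}"
            )
        prev_pos, prev_end = v.pos, v.end


def apply_variants(
    reference: Reference, variants: list[Variant], hap_index: int
) -> tuple[str, np.ndarray]:
    """Realize one haplotype sequence and its reference→haplotype coordinate map.

    Returns ``(hap_seq, coord_map)`` where ``coord_map`` has length
    ``len(reference) + 1`` (the end sentinel maps too); positions strictly
    inside a replaced reference span map to -1 (deleted), every other entry is
    the haplotype coordinate of that reference base.  The map is monotone on
    its non-negative entries.
    """
    if hap_index not in (0, 1):
        raise ValidationError("hap_index must be 0 or 1")
    validate_variants(reference, variants)
    n = len(reference)
    coord = np.empty(n + 1, dtype=np.int64)
    parts: list[str] = []
    ref_seq = reference.seq
    cursor = 0      # reference position consumed so far
    out_len = 0     # haplotype length emitted so far
    for v in variants:
        if v.genotype[hap_index] == 0:
            continue
        # untouched stretch before the variant
        span = v.pos - cursor
        coord[cursor:v.pos] = np.arange(out_len, out_len + span)
        parts.append(ref_seq[cursor:v.pos])
        out_len += span
        # the variant span: anchor base maps, interior of a deletion does not
        coord[v.pos] = out_len
        if v.end > v.pos + 1:
            coord[v.pos + 1:v.end] = -1
        parts.append(v.alt_allele)
        out_len += len(v.alt_allele)
        cursor = v.end
    span = n - cursor
    coord[cursor:n] = np.arange(out_len, out_len + span)
    parts.append(ref_seq[cursor:n])
    out_len += span
    coord[n] = out_len
    return "".join(parts), coord


def inverse_coord_map(coord_map: np.ndarray, hap_len: int) -> np.ndarray:
    """Haplotype→reference map (length ``hap_len + 1``).

    Inserted haplotype positions (no reference preimage) inherit the reference
    coordinate of the nearest mapped position to their left, so the map stays
    monotone and total.
    """
    inv = np.full(hap_len + 1, -1, dtype=np.int64)
    ref_pos = np.nonzero(coord_map >= 0)[0]
    inv[coord_map[ref_pos]] = ref_pos
    # fill inserted positions from the left
    for i in range(1, hap_len + 1):
        if inv[i] < 0:
            inv[i] = inv[i - 1]
    if inv[0] < 0:
        inv[0] = 0
    return inv


@dataclass(frozen=True)
class DiploidLocus:
    """A reference plus the two realized haplotypes of a diploid individual."""

    reference: Reference
    variants: tuple[Variant, ...]
    hap_seqs: tuple[str, str]
    coord_maps: tuple[np.ndarray, np.ndarray]

    @classmethod
    def from_reference(cls, reference: Reference, variants: list[Variant]) -> "DiploidLocus":
        h0, m0 = apply_variants(reference, variants, 0)
        h1, m1 = apply_variants(reference, variants, 1)
        return cls(reference, tuple(variants), (h0, h1), (m0, m1))

    @property
    def het_variants(self) -> list[Variant]:
        return [v for v in self.variants if v.is_het]

    def hap_position(self, hap: int, ref_pos: int) -> int:
        """Haplotype coordinate of a (non-deleted) reference position."""
        p = int(self.coord_maps[hap][ref_pos])
        if p < 0:
            raise ValidationError(f"reference position {ref_pos} deleted on hap {hap}")
        return p


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a recognition motif plus a cut offset.

    The fragment boundary falls at ``motif_start + cut_offset``.  NlaIII
    (CATG, cut_offset 4) leaves CATG at the 3' end of the upstream fragment,
    matching its 3'-overhang chemistry.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self):
        if len(self.motif) < 4:
            raise ValidationError("motif length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValidationError("cut_offset must lie within the motif")
        if any(b not in IUPAC for b in self.motif):
            raise ValidationError(f"motif {self.motif!r} has non-IUPAC symbols")

    @property
    def regex(self) -> re.Pattern:
        pat = "".join(b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in self.motif)
        return re.compile(f"(?={pat})")  # lookahead: overlapping occurrences

    def motif_starts(self, sequence: str) -> list[int]:
        return [m.start() for m in self.regex.finditer(sequence)]

    def cut_positions(self, sequence: str) -> list[int]:
        """Internal cut positions, strictly inside the sequence, sorted."""
        n = len(sequence)
        return [s + self.cut_offset for s in self.motif_starts(sequence)
                if 0 < s + self.cut_offset < n]


NLAIII = RestrictionEnzyme("NlaIII", "CATG", 4)
NSPI = RestrictionEnzyme("NspI", "RCATGY", 5)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment of one haplotype sequence."""

    start: int
    end: int
    seq: str
    index: int
    hap: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def digest(sequence: str, enzyme: RestrictionEnzyme = NLAIII, hap: int = 0) -> list[Fragment]:
    """Digest a sequence into its ordered restriction fragments.

    Fragments tile the sequence exactly: internal boundaries are the enzyme's
    cut positions, plus the two sequence ends.  A motif-free sequence yields a
    single fragment.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    cuts = enzyme.cut_positions(sequence)
    bounds = [0] + cuts + [len(sequence)]
    return [
        Fragment(start=s, end=e, seq=sequence[s:e], index=i, hap=hap)
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def left_normalize(ref_seq: str, pos: int, ref_allele: str, alt_allele: str
                   ) -> tuple[int, str, str]:
    """Left-align and trim an indel to its canonical VCF representation.

    Repeatedly drops shared trailing bases (extending left through the
    reference when an allele would empty) and then trims shared leading
    bases.  SNVs pass through unchanged.
    """
    r, a = ref_allele, alt_allele
    while True:
        if r and a and r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
            r, a = r[:-1], a[:-1]
            if not r or not a:
                pos -= 1
                b = ref_seq[pos]
                r, a = b + r, b + a
            continue
        break
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        pos += 1
        r, a = r[1:], a[1:]
    return pos, r, a


def make_homolog(sequence: str, identity: float, seed: int) -> str:
    """Mutate a copy of ``sequence`` to a target sequence identity.

    Each position is substituted (to a uniformly chosen different base) with
    probability ``1 - identity``, emulating a diverged paralog such as a
    pseudogene; length is preserved.
    """
    if not 0 < identity <= 1:
        raise ValidationError("identity must lie in (0, 1]")
    if identity == 1.0:
        return sequence
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < (1.0 - identity)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()
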