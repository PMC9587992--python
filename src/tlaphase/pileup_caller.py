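"""Pileup construction, coverage metrics and depth-filtered genotype calling.

Every aligned, non-clipped read base contributes one unit of depth at its
reference position; indels are registered at their left-anchored position in
a parallel table.  Calling applies the platform depth filter first (25X for
short reads, 100X for long reads) and then simple allele-fraction rules:
an ALT fraction inside the heterozygous band yields 0/1, above the
homozygous minimum yields 1/1.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import Read
from .locus_model import Reference, ValidationError, left_normalize, revcomp
from .split_mapper import FragmentAlignment

__all__ = [
    "Pileup",
    "CallerConfig",
    "GenotypeCall",
    "SHORT_CALLER",
    "LONG_CALLER",
    "build_pileup",
    "on_target_stats",
    "coverage_at_depth",
    "call_variants",
]


@dataclass
class Pileup:
    """Per-position depth and allele counts for one reference sequence."""

    reference: Reference
    depth: np.ndarray                      # int64, len(reference)
    base_counts: np.ndarray                # (len, 4) counts of A/C/G/T
    indel_counts: dict[int, Counter] = field(default_factory=dict)
    # indel_counts[pos][(ref_allele, alt_allele)] = supporting reads

    def allele_counts(self, pos: int) -> dict[str, int]:
        """Base allele counts at ``pos`` (sums to ``depth[pos]``)."""
        row = self.base_counts[pos]
        return {b: int(row[i]) for i, b in enumerate("ACGT") if row[i]}


@dataclass(frozen=True)
class CallerConfig:
    """Depth filter plus allele-fraction genotyping rules."""

    min_depth: int = 25
    het_af_band: tuple[float, float] = (0.25, 0.75)
    hom_af_min: float = 0.85
    min_alt_count: int = 5

    def __post_init__(self):
        lo, hi = self.het_af_band
        if not 0 < lo < hi < 1:
            raise ValidationError("het_af_band must satisfy 0 < low < high < 1")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")


SHORT_CALLER = CallerConfig(min_depth=25)
LONG_CALLER = CallerConfig(min_depth=100)


@dataclass(frozen=True)
class GenotypeCall:
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str      # "0/1" or "1/1"
    depth: int
    alt_fraction: float

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "INDEL"

    @property
    def is_het(self) -> bool:
        return self.genotype == "0/1"


_BASE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # ord(A/C/G/T)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops, n = [], 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            ops.append((n, ch))
            n = 0
    return ops


#: indel operations separated by at most this many match columns are merged
#: into one composite event (edit-distance paths fragment multi-base indels
#: arbitrarily; the merged event is normalization-stable)
_INDEL_MERGE_GAP = 3


def aligned_pairs(alignment: FragmentAlignment, read_seq: str
                  ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """Decode one alignment into (ref_positions, read_bases, indel events).

    ``ref_positions``/``read_bases`` cover the match columns only; each indel
    event is ``(anchor, ref_len, alt_seq)``: relative to the anchor position
    the reference carries ``ref_len`` following bases where the read carries
    ``alt_seq``.  Nearby indel operations are merged into one event (see
    ``_INDEL_MERGE_GAP``) so the caller can left-normalize to a canonical
    allele pair.  The segment is oriented to the reference strand first.
    """
    seg = read_seq[alignment.seg_start:alignment.seg_end]
    if alignment.strand == "-":
        seg = revcomp(seg)
    qarr = np.frombuffer(seg.encode(), dtype=np.uint8)
    if alignment.cigar is None:
        ref_pos = np.arange(alignment.ref_start, alignment.ref_end)
        return ref_pos, qarr, []
    # walk the cigar into op records with their start coordinates
    records = []
    rp, qp = alignment.ref_start, 0
    for n, op in _parse_cigar(alignment.cigar):
        records.append((op, n, rp, qp))
        if op in ("M", "=", "X"):
            rp += n
            qp += n
        elif op == "I":
            qp += n
        elif op == "D":
            rp += n
        else:
            raise ValidationError(f"unsupported CIGAR op {op!r}")
    # cluster indel ops separated by short match runs
    events: list[tuple[int, int, str]] = []
    absorbed: set[int] = set()
    i = 0
    while i < len(records):
        op, n, r0, q0 = records[i]
        if op not in ("I", "D"):
            i += 1
            continue
        j = i
        while j + 2 < len(records):
            mid_op, mid_n, _, _ = records[j + 1]
            nxt_op = records[j + 2][0]
            if mid_op in ("M", "=", "X") and mid_n <= _INDEL_MERGE_GAP \
                    and nxt_op in ("I", "D"):
                absorbed.add(j + 1)
                j += 2
            else:
                break
        last_op, last_n, r1, q1 = records[j]
        r_end = r1 + (last_n if last_op == "D" else 0)
        q_end = q1 + (last_n if last_op == "I" else 0)
        events.append((r0 - 1, r_end - r0, seg[q0:q_end]))
        i = j + 1
    ref_cols, q_cols = [], []
    for idx, (op, n, r0, q0) in enumerate(records):
        if op in ("M", "=", "X") and idx not in absorbed:
            ref_cols.append(np.arange(r0, r0 + n))
            q_cols.append(qarr[q0:q0 + n])
    ref_pos = np.concatenate(ref_cols) if ref_cols else np.empty(0, dtype=np.int64)
    bases = np.concatenate(q_cols) if q_cols else np.empty(0, dtype=np.uint8)
    return ref_pos, bases, events


def build_pileup(alignments: list[FragmentAlignment], reference: Reference,
                 reads: list[Read]) -> Pileup:
    """Accumulate depth and allele counts over one reference sequence.

    Depth counts fragments: two segments of the same read overlapping a
    position both count.  Alignments to other references are ignored here.
    """
    n = len(reference)
    ref_arr = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    depth = np.zeros(n, dtype=np.int64)
    base_counts = np.zeros((n, 4), dtype=np.int64)
    indel_counts: dict[int, Counter] = defaultdict(Counter)
    read_seqs = {(r.read_id, r.mate): r.seq for r in reads}
    for a in alignments:
        if a.ref_name != reference.name:
            continue
        if a.ref_start < 0 or a.ref_end > n:
            raise ValidationError(
                f"alignment [{a.ref_start},{a.ref_end}) outside reference {reference.name}")
        ref_pos, bases, indels = aligned_pairs(a, read_seqs[(a.read_id, a.mate)])
        valid = np.isin(bases, (65, 67, 71, 84))
        rp, bs = ref_pos[valid], bases[valid]
        np.add.at(depth, rp, 1)
        cols = np.searchsorted(np.array([65, 67, 71, 84]), bs)
        np.add.at(base_counts, (rp, cols), 1)
        for anchor, ref_len, alt_seq in indels:
            if anchor < 0:
                continue
            anchor_base = reference.seq[anchor]
            ref_tail = reference.seq[anchor + 1:anchor + 1 + ref_len]
            npos, nref, nalt = left_normalize(
                reference.seq, anchor, anchor_base + ref_tail, anchor_base + alt_seq)
            indel_counts[npos][(nref, nalt)] += 1
    return Pileup(reference=reference, depth=depth, base_counts=base_counts,
                  indel_counts=dict(indel_counts))


def on_target_stats(alignments: list[FragmentAlignment],
                    roi: list[tuple[str, int, int]]) -> dict:
    """Fraction of aligned nucleotides inside the regions of interest.

    ``mean_depth_in_roi`` is on-target nucleotides divided by ROI length.
    """
    if not roi:
        raise ValidationError("empty region of interest")
    total_nt = 0
    on_nt = 0
    roi_len = sum(e - s for _, s, e in roi)
    by_ref: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for name, s, e in roi:
        by_ref[name].append((s, e))
    for a in alignments:
        span = a.ref_end - a.ref_start
        total_nt += span
        for s, e in by_ref.get(a.ref_name, ()):
            on_nt += max(0, min(a.ref_end, e) - max(a.ref_start, s))
    return {
        "on_target_nt": on_nt,
        "total_nt": total_nt,
        "fraction": on_nt / total_nt if total_nt else 0.0,
        "mean_depth_in_roi": on_nt / roi_len if roi_len else 0.0,
    }


def coverage_at_depth(pileup: Pileup, min_depth: int,
                      roi: list[tuple[int, int]] | None = None) -> dict:
    """Positions covered at the platform's minimum depth, plus zero-depth runs."""
    if roi is None:
        roi = [(0, len(pileup.reference))]
    mask = np.zeros(len(pileup.reference), dtype=bool)
    for s, e in roi:
        mask[s:e] = True
    sel = pileup.depth[mask]
    covered = int((sel >= min_depth).sum())
    roi_length = int(mask.sum())
    # maximal runs of zero depth inside the ROI
    zero = mask & (pileup.depth == 0)
    intervals = []
    pos = np.nonzero(zero)[0]
    if pos.size:
        breaks = np.nonzero(np.diff(pos) > 1)[0]
        starts = np.concatenate(([pos[0]], pos[breaks + 1]))
        ends = np.concatenate((pos[breaks] + 1, [pos[-1] + 1]))
        intervals = [(int(s), int(e)) for s, e in zip(starts, ends)]
    return {
        "covered_positions": covered,
        "roi_length": roi_length,
        "percent": 100.0 * covered / roi_length if roi_length else 0.0,
        "zero_depth_intervals": intervals,
    }


def call_variants(pileup: Pileup, config: CallerConfig) -> list[GenotypeCall]:
    """Depth-filtered allele-fraction genotype calling.

    Positions below ``min_depth`` emit nothing; the most frequent non-reference
    base (or indel allele) is genotyped by its allele fraction.
    """
    calls: list[GenotypeCall] = []
    ref_seq = pileup.reference.seq
    depth = pileup.depth
    counts = pileup.base_counts
    deep = np.nonzero(depth >= config.min_depth)[0]
    base_of_col = "ACGT"
    for pos in deep:
        pos = int(pos)
        ref_base = ref_seq[pos]
        ref_col = _BASE_IDX[ord(ref_base)]
        row = counts[pos]
        alt_col = -1
        alt_n = 0
        for c in range(4):
            if c != ref_col and row[c] > alt_n:
                alt_col, alt_n = c, int(row[c])
        call = _genotype(ref_base, base_of_col[alt_col] if alt_col >= 0 else None,
                         alt_n, int(depth[pos]), pos, config)
        if call:
            calls.append(call)
        for (ref_a, alt_a), n_sup in sorted(pileup.indel_counts.get(pos, {}).items()):
            c = _genotype_alleles(ref_a, alt_a, int(n_sup), int(depth[pos]), pos, config)
            if c:
                calls.append(c)
    calls.sort(key=lambda c: (c.pos, c.alt_allele))
    return calls


def _genotype(ref_base: str, alt_base: str | None, alt_n: int, dp: int,
              pos: int, config: CallerConfig) -> GenotypeCall | None:
    if alt_base is None:
        return None
    return _genotype_alleles(ref_base, alt_base, alt_n, dp, pos, config)


def _genotype_alleles(ref_a: str, alt_a: str, alt_n: int, dp: int, pos: int,
                      config: CallerConfig) -> GenotypeCall | None:
    if dp <= 0 or alt_n < config.min_alt_count:
        return None
    af = alt_n / dp
    lo, hi = config.het_af_band
    if lo <= af <= hi:
        gt = "0/1"
    elif af >= config.hom_af_min:
        gt = "1/1"
    else:
        return None
    return GenotypeCall(pos=pos, ref_allele=ref_a, alt_allele=alt_a,
                        genotype=gt, depth=dp, alt_fraction=af)
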