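"""Iterative split-read mapping at restriction sites.

TLA reads are chimeric: concatenations of restriction fragments ligated into
one circle.  The mapper aligns each read whole; when a read does not map
cleanly (a soft-clip of at least ``min_segment_len`` remains at an end), the
read is split at the NlaIII recognition sequence closest to the clipping-end
that was still mapped and the parts are mapped again, iterating until every
part is mapped or can no longer be split.

Alignment itself is a k-mer seed-and-extend: seeds nominate diagonals, each
diagonal is scored gaplessly (best-scoring run under match +1 / mismatch -2),
and in long-read mode segments that fail gaplessly are rescued by an
edit-distance-bounded alignment (edlib) that tolerates indels.  Ambiguous
placements (co-optimal hits elsewhere, e.g. on a pseudogene decoy) are
flagged and handled per ``ambiguity_policy``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .io import Read
from .locus_model import NLAIII, RestrictionEnzyme, ValidationError, revcomp

__all__ = [
    "SeedIndex",
    "MapperParams",
    "FragmentAlignment",
    "UnmappedRemnant",
    "build_index",
    "align_segment",
    "split_map",
    "map_reads",
    "alignments_to_df",
    "SHORT_MAPPER",
    "LONG_MAPPER",
]

ALIGNMENT_COLUMNS = ["read_id", "mate", "seg_start", "seg_end", "ref_name",
                     "ref_start", "ref_end", "strand", "mismatches",
                     "ambiguous", "round", "cigar"]


class SeedIndex:
    """Exact k-mer index over one or more reference sequences."""

    def __init__(self, references: dict[str, str], k: int = 21):
        if not references:
            raise ValidationError("no references to index")
        if k < 11:
            raise ValidationError("k must be >= 11")
        if all(len(s) < k for s in references.values()):
            raise ValidationError("k exceeds every reference length")
        self.k = k
        self.refs = {name: seq.upper() for name, seq in references.items()}
        self.arrs = {name: np.frombuffer(seq.encode(), dtype=np.uint8)
                     for name, seq in self.refs.items()}
        table: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.refs):
            seq = self.refs[name]
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i:i + k], []).append((name, i))
        self.table = table

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (reference name, position) occurrences of ``kmer``, sorted."""
        return self.table.get(kmer, [])


def build_index(references: dict[str, str], k: int = 21) -> SeedIndex:
    return SeedIndex(references, k=k)


@dataclass(frozen=True)
class MapperParams:
    k: int = 21
    max_mismatch_rate: float = 0.05
    min_segment_len: int = 15
    ambiguity_policy: str = "keep"    # keep | drop | random
    allow_indels: bool = False        # long-read mode: edlib rescue of indel-bearing segments
    seed_stride: int = 11

    def __post_init__(self):
        if self.ambiguity_policy not in ("keep", "drop", "random"):
            raise ValidationError("ambiguity_policy must be keep, drop or random")


#: Presets mirroring the two sequencing platforms.
SHORT_MAPPER = MapperParams(max_mismatch_rate=0.05, allow_indels=False)
LONG_MAPPER = MapperParams(max_mismatch_rate=0.15, allow_indels=True)


@dataclass(frozen=True)
class FragmentAlignment:
    """One mapped fragment of a (possibly chimeric) read."""

    read_id: str
    mate: int
    seg_start: int
    seg_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int
    ambiguous: bool
    round: int
    cigar: str | None = None  # None = gapless full-length match run


@dataclass(frozen=True)
class UnmappedRemnant:
    read_id: str
    mate: int
    seg_start: int
    seg_end: int
    reason: str


@dataclass(frozen=True)
class _Placement:
    ref_name: str
    strand: str
    read_start: int  # within the segment
    read_end: int
    ref_start: int
    ref_end: int
    mismatches: int
    score: int
    cigar: str | None = None


@dataclass
class AlignResult:
    full: list[_Placement]      # co-optimal full-coverage placements
    best_run: _Placement | None  # best partial run when not fully mapped


def _diagonal_run(qarr: np.ndarray, rarr: np.ndarray, diag: int) -> tuple[int, int, int, int] | None:
    """Best-scoring gapless run of ``qarr`` along ``diag`` (match +1 / mismatch -2).

    Returns (q_start, q_end, score, mismatches) or None when the diagonal has
    no overlap with the reference.
    """
    L = qarr.size
    a = max(0, -diag)
    b = min(L, rarr.size - diag)
    if b - a <= 0:
        return None
    if b - a == L and np.array_equal(qarr, rarr[diag:diag + L]):
        return 0, L, L, 0  # exact full-length match shortcut
    match = qarr[a:b] == rarr[diag + a:diag + b]
    scores = np.where(match, 1, -2).astype(np.int64)
    cs = np.cumsum(scores)
    prefix = np.concatenate(([0], cs))
    pmin = np.minimum.accumulate(prefix)[:-1]
    gains = cs - pmin
    e = int(np.argmax(gains))
    score = int(gains[e])
    if score <= 0:
        return None
    s = int(np.argmax(prefix[:e + 1] == pmin[e]))
    mism = int((~match[s:e + 1]).sum())
    return a + s, a + e + 1, score, mism


#: cap on scored diagonals per segment; seed-vote ordering keeps the true
#: placements while pruning sparse spurious hits (e.g. on a diverged decoy)
_MAX_CANDIDATES = 32


def _candidate_diagonals(seq: str, index: SeedIndex, stride: int
                         ) -> dict[str, list[tuple[str, int]]]:
    """Seed the segment on both strands; returns strand → [(ref, diag)]
    ordered by decreasing seed-hit votes and capped at ``_MAX_CANDIDATES``
    overall."""
    k = index.k
    votes: dict[tuple[str, str, int], int] = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        L = len(s)
        if L < k:
            continue
        positions = list(range(0, L - k + 1, stride))
        if positions[-1] != L - k:
            positions.append(L - k)
        for qpos in positions:
            for ref_name, rpos in index.lookup(s[qpos:qpos + k]):
                key = (strand, ref_name, rpos - qpos)
                votes[key] = votes.get(key, 0) + 1
    ranked = sorted(votes, key=lambda key: (-votes[key], key))[:_MAX_CANDIDATES]
    out: dict[str, list[tuple[str, int]]] = {"+": [], "-": []}
    for strand, ref_name, diag in ranked:
        out[strand].append((ref_name, diag))
    return out


def _same_place(p: _Placement, q: _Placement, slop: int = 8) -> bool:
    return (p.ref_name == q.ref_name and p.strand == q.strand
            and abs(p.ref_start - q.ref_start) <= slop)


def align_segment(seq: str, index: SeedIndex, params: MapperParams,
                  rescue: bool | None = None) -> AlignResult:
    """Seed-and-extend alignment of one segment; see module docstring.

    Segments shorter than ``k`` carry no seeds and are unmappable by
    construction — this is what makes fragments between two nearby NlaIII
    sites invisible to direct alignment.  ``rescue`` controls the long-mode
    indel-tolerant fallback (default: ``params.allow_indels``); the split
    mapper disables it while a segment still contains recognition sites, so
    real ligation junctions are split rather than absorbed as edits.
    """
    if rescue is None:
        rescue = params.allow_indels
    L = len(seq)
    result = AlignResult(full=[], best_run=None)
    if L < index.k:
        return result
    cands = _candidate_diagonals(seq, index, params.seed_stride)
    runs: list[_Placement] = []
    for strand in ("+", "-"):
        q = seq if strand == "+" else revcomp(seq)
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        for ref_name, diag in sorted(cands[strand]):  # stable order
            hit = _diagonal_run(qarr, index.arrs[ref_name], diag)
            if hit is None:
                continue
            qs, qe, score, mism = hit
            if strand == "+":
                rs_read, re_read = qs, qe
            else:
                rs_read, re_read = L - qe, L - qs
            runs.append(_Placement(ref_name=ref_name, strand=strand,
                                   read_start=rs_read, read_end=re_read,
                                   ref_start=diag + qs, ref_end=diag + qe,
                                   mismatches=mism, score=score))
    if not runs:
        return result
    runs.sort(key=lambda p: (-p.score, p.ref_name, p.ref_start, p.strand))
    max_mm = params.max_mismatch_rate

    def is_full(p: _Placement) -> bool:
        run_len = p.read_end - p.read_start
        return (p.read_start < params.min_segment_len
                and L - p.read_end < params.min_segment_len
                and p.mismatches <= max_mm * run_len)

    fulls = [p for p in runs if is_full(p)]
    if fulls:
        best = fulls[0].score
        co = [p for p in fulls if p.score == best]
    elif rescue:
        co = _edlib_rescue(seq, index, params, runs)
    else:
        co = []
    if co:
        dedup: list[_Placement] = []
        for p in co:
            if not any(_same_place(p, q) for q in dedup):
                dedup.append(p)
        result.full = dedup
        return result
    result.best_run = runs[0]
    return result


def _edlib_rescue(seq: str, index: SeedIndex, params: MapperParams,
                  runs: list[_Placement]) -> list[_Placement]:
    """Edit-distance-bounded full-segment alignment around the top diagonals.

    Rescues segments whose gapless run broke at indels (sequencing indel
    errors or small truth indels); the allowance is ``max_mismatch_rate``
    expressed as an edit-distance budget.
    """
    L = len(seq)
    budget = int(params.max_mismatch_rate * L)
    pad = max(16, budget + 8)
    seen: set[tuple[str, str, int]] = set()
    out: list[_Placement] = []
    for p in runs[:8]:
        diag = p.ref_start - (p.read_start if p.strand == "+" else L - p.read_end)
        key = (p.ref_name, p.strand, diag // 16)
        if key in seen:
            continue
        seen.add(key)
        rarr = index.refs[p.ref_name]
        lo = max(0, diag - pad)
        hi = min(len(rarr), diag + L + pad)
        window = rarr[lo:hi]
        query = seq if p.strand == "+" else revcomp(seq)
        res = edlib.align(query, window, mode="HW", task="path", k=budget)
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        out.append(_Placement(ref_name=p.ref_name, strand=p.strand,
                              read_start=0, read_end=L,
                              ref_start=lo + loc[0], ref_end=lo + loc[1] + 1,
                              mismatches=res["editDistance"],
                              score=L - 3 * res["editDistance"],
                              cigar=res["cigar"]))
    if not out:
        return []
    best = min(p.mismatches for p in out)
    return sorted((p for p in out if p.mismatches == best),
                  key=lambda p: (p.ref_name, p.ref_start, p.strand))


def _cut_sites(seq: str, enzyme: RestrictionEnzyme, strand: str) -> list[int]:
    """Restriction cut positions in read space.

    On the forward strand the junction motif stays with the upstream fragment
    (cut at motif start + cut_offset); on a reverse-complemented read the
    fragment order is mirrored, so the cut falls at the motif start.  NlaIII's
    CATG is its own reverse complement, so motif positions are strand-free.
    """
    offset = enzyme.cut_offset if strand == "+" else 0
    n = len(seq)
    return [s + offset for s in enzyme.motif_starts(seq) if 0 < s + offset < n]


def _pick(placements: list[_Placement], policy: str, read_id: str, seg_key: str,
          rng: np.random.Generator | None) -> tuple[_Placement | None, bool]:
    if len(placements) == 1:
        return placements[0], False
    if policy == "drop":
        return None, True
    if policy == "random" and rng is not None:
        return placements[int(rng.integers(len(placements)))], True
    # "keep": stable pseudo-random choice, mirroring an aligner's arbitrary
    # placement of multi-mappers while staying reproducible
    h = zlib.crc32(f"{read_id}:{seg_key}".encode())
    return placements[h % len(placements)], True


def split_map(read: Read, index: SeedIndex, enzyme: RestrictionEnzyme,
              params: MapperParams, rng: np.random.Generator | None = None
              ) -> tuple[list[FragmentAlignment], list[UnmappedRemnant]]:
    """Iteratively split-map one read; see module docstring.

    Emitted alignments and remnants are disjoint and jointly cover the read.
    """
    seq = read.seq
    alignments: list[FragmentAlignment] = []
    remnants: list[UnmappedRemnant] = []
    queue: list[tuple[int, int, int]] = [(0, len(seq), 1)]

    def emit_remnant(s: int, e: int, reason: str):
        if e > s:
            remnants.append(UnmappedRemnant(read.read_id, read.mate, s, e, reason))

    while queue:
        s, e, rnd = queue.pop()
        sub = seq[s:e]
        if e - s < params.min_segment_len:
            emit_remnant(s, e, "too_short")
            continue
        res = align_segment(sub, index, params, rescue=False)
        if res.full:
            p, amb = _pick(res.full, params.ambiguity_policy, read.read_id, f"{s}-{e}", rng)
            if p is None:
                emit_remnant(s, e, "ambiguous")
                continue
            alignments.append(FragmentAlignment(
                read_id=read.read_id, mate=read.mate,
                seg_start=s + p.read_start, seg_end=s + p.read_end,
                ref_name=p.ref_name, ref_start=p.ref_start, ref_end=p.ref_end,
                strand=p.strand, mismatches=p.mismatches,
                ambiguous=amb, round=rnd, cigar=p.cigar))
            emit_remnant(s, s + p.read_start, "clip")
            emit_remnant(s + p.read_end, e, "clip")
            continue
        run = res.best_run
        if run is not None and (run.read_end - run.read_start) >= params.min_segment_len:
            clip_left = run.read_start
            clip_right = (e - s) - run.read_end
            # a run extends through the junction motif on the side where the
            # motif adjoins the fragment in the reference ('+': left, '-':
            # right); correct the clip boundary by the cut offset there
            if clip_right >= clip_left:
                boundary = run.read_end - (enzyme.cut_offset if run.strand == "-" else 0)
            else:
                boundary = run.read_start + (enzyme.cut_offset if run.strand == "+" else 0)
            sites = _cut_sites(sub, enzyme, run.strand)
            if sites:
                cut = min(sites, key=lambda c: (abs(c - boundary), c))
                queue.append((s, s + cut, rnd + 1))
                queue.append((s + cut, e, rnd + 1))
                continue
            # recognition motifs inside a read occur (only) at ligation
            # junctions; with none left under the mapped strand's convention
            # the remaining clip is likely an indel, so try the rescue
            if params.allow_indels:
                res2 = align_segment(sub, index, params, rescue=True)
                if res2.full:
                    p, amb = _pick(res2.full, params.ambiguity_policy,
                                   read.read_id, f"{s}-{e}", rng)
                    if p is not None:
                        alignments.append(FragmentAlignment(
                            read_id=read.read_id, mate=read.mate,
                            seg_start=s + p.read_start, seg_end=s + p.read_end,
                            ref_name=p.ref_name, ref_start=p.ref_start,
                            ref_end=p.ref_end, strand=p.strand,
                            mismatches=p.mismatches, ambiguous=amb,
                            round=rnd, cigar=p.cigar))
                        continue
            # mapped run but no motif to split at: emit the run and give the
            # clipped parts their own chance to map
            if run.mismatches <= params.max_mismatch_rate * (run.read_end - run.read_start):
                alignments.append(FragmentAlignment(
                    read_id=read.read_id, mate=read.mate,
                    seg_start=s + run.read_start, seg_end=s + run.read_end,
                    ref_name=run.ref_name, ref_start=run.ref_start,
                    ref_end=run.ref_end, strand=run.strand,
                    mismatches=run.mismatches, ambiguous=False, round=rnd))
                for a0, b0 in ((s, s + run.read_start), (s + run.read_end, e)):
                    if b0 - a0 >= params.min_segment_len:
                        queue.append((a0, b0, rnd + 1))
                    else:
                        emit_remnant(a0, b0, "clip")
            else:
                emit_remnant(s, e, "unmapped")
            continue
        # no usable alignment: split blind at the site nearest the middle
        sites = _cut_sites(sub, enzyme, "+")
        if sites:
            mid = (e - s) // 2
            cut = min(sites, key=lambda c: (abs(c - mid), c))
            queue.append((s, s + cut, rnd + 1))
            queue.append((s + cut, e, rnd + 1))
        else:
            emit_remnant(s, e, "unmapped")
    alignments.sort(key=lambda a: a.seg_start)
    remnants.sort(key=lambda r: r.seg_start)
    return alignments, remnants


def map_reads(reads: list[Read], index: SeedIndex,
              enzyme: RestrictionEnzyme = NLAIII,
              params: MapperParams = SHORT_MAPPER,
              rng: np.random.Generator | None = None
              ) -> tuple[list[FragmentAlignment], list[UnmappedRemnant]]:
    """Split-map a batch of reads (paired mates are mapped independently)."""
    alns: list[FragmentAlignment] = []
    rems: list[UnmappedRemnant] = []
    for read in reads:
        a, r = split_map(read, index, enzyme, params, rng)
        alns.extend(a)
        rems.extend(r)
    return alns, rems


def alignments_to_df(alignments: list[FragmentAlignment]) -> pd.DataFrame:
    rows = [(a.read_id, a.mate, a.seg_start, a.seg_end, a.ref_name, a.ref_start,
             a.ref_end, a.strand, a.mismatches, a.ambiguous, a.round,
             a.cigar or "")
            for a in alignments]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def df_to_alignments(df: pd.DataFrame) -> list[FragmentAlignment]:
    out = []
    for row in df.itertuples(index=False):
        cig = getattr(row, "cigar", "")
        cig = None if (not isinstance(cig, str) or not cig) else cig
        out.append(FragmentAlignment(
            read_id=str(row.read_id), mate=int(row.mate),
            seg_start=int(row.seg_start), seg_end=int(row.seg_end),
            ref_name=str(row.ref_name), ref_start=int(row.ref_start),
            ref_end=int(row.ref_end), strand=str(row.strand),
            mismatches=int(row.mismatches), ambiguous=bool(row.ambiguous),
            round=int(row.round), cigar=cig))
    return out


def write_sam(path: str, alignments: list[FragmentAlignment],
              reads: list[Read], references: dict[str, str]) -> None:
    """Minimal SAM export: one record per fragment alignment, soft-clips in
    the CIGAR, supplementary flag on every segment after a read's first."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": len(s)} for n, s in sorted(references.items())]}
    read_seqs = {(r.read_id, r.mate): r.seq for r in reads}
    seen: set[tuple[str, int]] = set()
    names = {n: i for i, n in enumerate(sorted(references))}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in alignments:
            seq = read_seqs[(a.read_id, a.mate)]
            rec = pysam.AlignedSegment()
            rec.query_name = a.read_id if a.mate == 0 else f"{a.read_id}/{a.mate}"
            rec.reference_id = names[a.ref_name]
            rec.reference_start = a.ref_start
            flag = 0
            if a.strand == "-":
                flag |= 16
            if (a.read_id, a.mate) in seen:
                flag |= 2048
            seen.add((a.read_id, a.mate))
            rec.flag = flag
            seg = seq[a.seg_start:a.seg_end]
            if a.strand == "-":
                seg = revcomp(seg)
                pre, post = len(seq) - a.seg_end, a.seg_start
            else:
                pre, post = a.seg_start, len(seq) - a.seg_end
            cig = ""
            if pre:
                cig += f"{pre}S"
            cig += a.cigar.replace("=", "M").replace("X", "M") if a.cigar else f"{len(seg)}M"
            if post:
                cig += f"{post}S"
            rec.cigarstring = cig
            rec.query_sequence = (seq if a.strand == "+" else revcomp(seq))
            rec.mapping_quality = 0 if a.ambiguous else 60
            out.write(rec)
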